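"""End-to-end performance measurements on simulated ground truth.

Each function regenerates synthetic data under the package's study
conditions (30 x 30 grid, ~5,000 UMIs per spot, 300 + 300 genes,
bleed-through 0.005 unless stated), runs the corresponding pipeline stage,
and scores it against the generator's recorded truth.  They back both the
statistical test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (
    CohortSimConfig,
    InterfaceConfig,
    PoolingConfig,
    ProfileSimConfig,
    QCConfig,
    XenoSimConfig,
    apply_gene_qc,
    classify_spots,
    compute_species_scores,
    deconvolve,
    find_interfaced_spots,
    fit_spot_weights,
    load_table1_fixture,
    headline_correlations,
    run_pseudobulk_de,
    simulate_reference_profiles,
    simulate_xenograft_dataset,
)
from .cohort import group_summary
from .io import SpotLabelTable


def classification_performance(n_seeds: int = 10, base_seed: int = 0) -> dict:
    """Species-call accuracy vs ground truth, aggregated over seeds."""
    tot_h = hit_h = tot_p = hit_p = 0
    for i in range(n_seeds):
        ds, truth = simulate_xenograft_dataset(XenoSimConfig(seed=base_seed + i))
        ds_qc = apply_gene_qc(ds, QCConfig())
        labels = classify_spots(compute_species_scores(ds_qc))
        is_h = truth.labels == "human"
        called_h = labels.table["label"].to_numpy() == "human"
        tot_h += is_h.sum()
        hit_h += (is_h & called_h).sum()
        tot_p += (~is_h).sum()
        hit_p += (~is_h & ~called_h).sum()
    return {
        "human_sensitivity_pct": 100.0 * hit_h / tot_h,
        "pig_specificity_pct": 100.0 * hit_p / tot_p,
        "n_truth_human": int(tot_h),
        "n_truth_pig": int(tot_p),
        "n_seeds": n_seeds,
    }


def truth_table_mismatches(tau_h: float = 30, tau_p: float = 700) -> int:
    """Exhaustive check of the threshold rule on the (h, p) integer grid."""
    h, p = np.meshgrid(np.arange(41), np.arange(801), indexing="ij")
    scores = pd.DataFrame(
        {"h": h.ravel(), "p": p.ravel(),
         "n_human_genes_detected": 10_000, "n_pig_genes_detected": 10_000},
        index=pd.Index([f"b{i}" for i in range(h.size)], name="barcode"),
    )
    from .species import SpeciesThresholds

    labels = classify_spots(scores, SpeciesThresholds(tau_h, tau_p),
                            QCConfig(min_human_genes_per_human_spot=0))
    oracle = np.where((h.ravel() > tau_h) & (p.ravel() < tau_p), "human", "pig")
    return int((labels.table["label"].to_numpy() != oracle).sum())


def _interface_brute_force(xy, labs, barcodes, k, d_max):
    out = set()
    for i, lab in enumerate(labs):
        if lab != "human":
            continue
        cand = [j for j in range(len(labs)) if j != i]
        ranked = sorted(cand, key=lambda j: (float(np.linalg.norm(xy[j] - xy[i])), j))
        for j in ranked[:k]:
            if labs[j] == "pig" and np.linalg.norm(xy[j] - xy[i]) < d_max:
                out.add(barcodes[j])
    return out


def interface_oracle_agreement(
    n_geometries: int = 10, n_spots: int = 500, base_seed: int = 0
) -> dict:
    """Exact-set agreement with the all-pairs oracle, plus monotonicity."""
    mismatches = 0
    monotone_ok = True
    for g in range(n_geometries):
        rng = np.random.default_rng(base_seed + g)
        xy = rng.uniform(0, 10_000, size=(n_spots, 2))
        labs = list(rng.choice(["human", "pig"], size=n_spots, p=[0.1, 0.9]))
        barcodes = [f"s{i:04d}" for i in range(n_spots)]
        positions = pd.DataFrame(
            {"in_tissue": 1, "array_row": 0, "array_col": range(n_spots),
             "x_px": xy[:, 0], "y_px": xy[:, 1]},
            index=pd.Index(barcodes, name="barcode"),
        )
        table = pd.DataFrame({"h": 0, "p": 0, "label": labs},
                             index=pd.Index(barcodes, name="barcode"))
        labels = SpotLabelTable(table)
        got = find_interfaced_spots(positions, labels, InterfaceConfig(k=20, d_max=1500))
        want = _interface_brute_force(xy, labs, barcodes, 20, 1500)
        mismatches += len(got ^ want)
        bigger_k = find_interfaced_spots(positions, labels, InterfaceConfig(k=30, d_max=1500))
        bigger_d = find_interfaced_spots(positions, labels, InterfaceConfig(k=20, d_max=3000))
        monotone_ok &= got <= bigger_k and got <= bigger_d
    return {"n_mismatched_spots": mismatches, "monotone": monotone_ok,
            "n_geometries": n_geometries}


def deconvolution_recovery(n_seeds: int = 10, base_seed: int = 100) -> dict:
    """Weight RMSE on simulated grafts and predominant-type accuracy on
    single-type spots (depth 5,000, 4 cell types)."""
    rmses = []
    for i in range(n_seeds):
        seed = base_seed + i
        ds, truth = simulate_xenograft_dataset(XenoSimConfig(seed=seed))
        prof = simulate_reference_profiles(ProfileSimConfig(seed=seed))
        labels = classify_spots(compute_species_scores(ds))
        weights = deconvolve(ds, labels, prof)
        w_est = weights[prof.cell_types].to_numpy()
        w_true = truth.weights.loc[weights.index, prof.cell_types].to_numpy()
        rmses.append(np.sqrt(((w_est - w_true) ** 2).mean(axis=1)).mean())

    prof = simulate_reference_profiles(ProfileSimConfig(seed=base_seed))
    rng = np.random.default_rng(base_seed)
    n_single, correct = 400, 0
    for i in range(n_single):
        k = i % len(prof.cell_types)
        y = rng.poisson(5000 * prof.pi[k])
        correct += fit_spot_weights(y, prof).predominant_type == prof.cell_types[k]
    return {
        "mean_weight_rmse": float(np.mean(rmses)),
        "predominant_type_accuracy_pct": 100.0 * correct / n_single,
        "n_seeds": n_seeds,
        "n_single_type_spots": n_single,
    }


def em_objective_monotone(n_spots: int = 25, seed: int = 0) -> bool:
    """Assert the EM objective never decreases across iterations."""
    prof = simulate_reference_profiles(ProfileSimConfig(seed=seed))
    rng = np.random.default_rng(seed)
    for _ in range(n_spots):
        w = rng.dirichlet(np.ones(len(prof.cell_types)))
        y = rng.multinomial(5000, w @ prof.pi)
        res = fit_spot_weights(y, prof, track_objective=True)
        if not np.all(np.diff(res.objective_path) >= -1e-9):
            return False
    return True


def _human_spots(ds, truth):
    return [b for b, l in zip(ds.barcodes, truth.labels) if l == "human"]


def de_false_discovery(n_replicates: int = 50, base_seed: int = 0) -> dict:
    """All-null pseudobulk simulation: fraction of genes flagged at q < 0.05.

    Both conditions are drawn from the same generative settings, so every
    discovery is false; with 3 vs 3 pools the flagged fraction should stay
    within the nominal level plus binomial noise.
    """
    prof = simulate_reference_profiles(ProfileSimConfig(seed=base_seed + 999))
    flagged = tested = 0
    for rep in range(n_replicates):
        ds_a, t_a = simulate_xenograft_dataset(
            XenoSimConfig(seed=base_seed + 2 * rep), profiles=prof)
        ds_b, t_b = simulate_xenograft_dataset(
            XenoSimConfig(seed=base_seed + 2 * rep + 1), profiles=prof)
        de = run_pseudobulk_de(ds_a, ds_b, _human_spots(ds_a, t_a),
                               _human_spots(ds_b, t_b), PoolingConfig(seed=rep))
        flagged += int(de["significant"].sum())
        tested += int(de["pvalue"].notna().sum())
    frac = flagged / tested
    se = np.sqrt(0.05 * 0.95 / tested)
    return {
        "false_discovery_fraction": frac,
        "bound": 0.05 + 2 * se,
        "n_replicates": n_replicates,
        "n_genes_tested": tested,
    }


def de_power(n_replicates: int = 10, base_seed: int = 0, log2fc: float = 2.0) -> dict:
    """Detection rate of genes planted with a known fold change."""
    prof = simulate_reference_profiles(ProfileSimConfig(seed=base_seed + 777))
    planted = [(g, "RA", log2fc) for g in prof.genes[50:60]]
    genes = [g for g, _, _ in planted]
    hit = tot = 0
    for rep in range(n_replicates):
        ds_a, t_a = simulate_xenograft_dataset(
            XenoSimConfig(seed=base_seed + 2 * rep, condition="standard",
                          de_planted=planted), profiles=prof)
        ds_b, t_b = simulate_xenograft_dataset(
            XenoSimConfig(seed=base_seed + 2 * rep + 1, condition="RA",
                          de_planted=planted), profiles=prof)
        de = run_pseudobulk_de(ds_a, ds_b, _human_spots(ds_a, t_a),
                               _human_spots(ds_b, t_b), PoolingConfig(seed=rep))
        hit += int(de.loc[genes, "significant"].sum())
        tot += len(genes)
    return {"power_pct": 100.0 * hit / tot, "n_planted": tot,
            "n_replicates": n_replicates, "log2fc": log2fc}


def cohort_reproduction() -> dict:
    """Headline correlations and mean +/- s.e.m. rows from the packaged
    per-subject cohort table."""
    t1 = load_table1_fixture()
    corrs = headline_correlations(t1)
    out = {
        "r_pscm_cd200pos": corrs["pscm_cd200pos"].r,
        "r_pscm_cd200neg": corrs["pscm_cd200neg"].r,
        "r_combined_cd200pos": corrs["combined_cd200pos"].r,
        "r_combined_cd200neg": corrs["combined_cd200neg"].r,
    }
    for grp, key in (("PSC-CM", "pscm"), ("PSC-CM+AA", "aa"),
                     ("PSC-CM+CA", "ca"), ("RA-PSC-CM", "ra")):
        s = group_summary(t1, "burden_h_per_day", grp)
        out[f"burden_mean_{key}"] = s.mean
        out[f"burden_sem_{key}"] = s.sem
    for grp, key in (("PSC-CM", "pscm"), ("PSC-CM+AA", "aa"), ("RA-PSC-CM", "ra")):
        s = group_summary(t1, "graft_pct_scar", grp)
        out[f"graft_pct_scar_mean_{key}"] = s.mean
    return out


def cohort_slope_recovery(n_replicates: int = 200, base_seed: int = 0) -> dict:
    """Recovery of the simulated composition -> burden slope."""
    from .cohort import composition_effect_recovery

    out = composition_effect_recovery(
        CohortSimConfig(noise_sd=1.0, n_subjects={"PSC-CM": 6, "RA-PSC-CM": 6}),
        n_replicates=n_replicates, seed=base_seed)
    return {"true_slope": out["true_slope"], "mean_estimate": out["mean_estimate"]}
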