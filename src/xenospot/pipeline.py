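"""End-to-end orchestration: QC -> species scores -> classification ->
interface -> deconvolution -> pseudobulk DE -> cohort report.

A pipeline run is driven by a single config (YAML-loadable dict or
``PipelineConfig``), executes the stages in order for a pair of conditions,
writes every result CSV plus a JSON manifest (seeds, thresholds, per-stage
counts, pool memberships) sufficient to reproduce the run exactly, and
returns the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cohort import headline_correlations
from .deconvolution import cluster_spots, consistency_check, deconvolve
from .interface import InterfaceConfig, annotate_interfaced, find_interfaced_spots, interface_summary
from .io import (
    SpotDataset,
    read_spot_dataset,
    write_de_table,
    write_labels,
    write_spot_dataset,
    write_weights,
)
from .pseudobulk import PoolingConfig, run_pseudobulk_de
from .simulate import (
    ProfileSimConfig,
    XenoSimConfig,
    load_table1_fixture,
    simulate_reference_profiles,
    simulate_xenograft_dataset,
)
from .species import (
    QCConfig,
    SpeciesThresholds,
    apply_gene_qc,
    classify_spots,
    compute_species_scores,
    species_pca_check,
    suggest_pig_threshold,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full two-condition run needs.

    ``tau_p`` may be a number or "auto" (density-based suggestion, which
    aborts if the pig-score distribution is unimodal).  One master seed
    drives every random stage through a fixed counter scheme
    (stage seed = master seed + stage counter).
    """

    out_dir: str = "xenospot_run"
    seed: int = 0
    tau_h: float = 30.0
    tau_p: float | str = 700.0
    qc: QCConfig = field(default_factory=QCConfig)
    interface: InterfaceConfig = field(default_factory=InterfaceConfig)
    n_pools: int = 3
    fdr: float = 0.05
    deconv_tol: float = 1e-6
    deconv_max_iter: int = 500
    n_clusters: int = 2
    simulate: dict = field(default_factory=dict)  # per-condition XenoSimConfig overrides
    inputs: dict = field(default_factory=dict)    # per-condition file paths

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCConfig(**raw["qc"])
        if "interface" in raw and isinstance(raw["interface"], dict):
            raw["interface"] = InterfaceConfig(**raw["interface"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# stage seed offsets under the master seed
_SEED_SIM_A, _SEED_SIM_B, _SEED_POOL, _SEED_CLUSTER = 11, 12, 13, 14


def _load_or_simulate(config: PipelineConfig) -> dict[str, tuple[SpotDataset, object]]:
    """Two conditions, from files when paths are given, simulated otherwise."""
    conditions = {}
    if config.inputs:
        for name, paths in config.inputs.items():
            ds = read_spot_dataset(
                paths["matrix"], paths["features"], paths["barcodes"], paths["positions"]
            )
            conditions[name] = (ds, None)
        return conditions
    profiles = simulate_reference_profiles(ProfileSimConfig(seed=config.seed))
    for name, seed_off, planted in (
        ("standard", _SEED_SIM_A, []),
        ("RA", _SEED_SIM_B, [(g, "RA", 2.0) for g in profiles.genes[:5]]),
    ):
        overrides = dict(config.simulate.get(name, {}))
        sim = XenoSimConfig(
            condition=name,
            seed=config.seed + seed_off,
            de_planted=planted,
            **overrides,
        )
        conditions[name] = simulate_xenograft_dataset(sim, profiles=profiles) + (profiles,)
    return conditions


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for a two-condition run; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    conditions = _load_or_simulate(config)
    names = list(conditions)
    per_condition: dict[str, dict] = {}

    for name in names:
        entry = conditions[name]
        ds, profiles = entry[0], (entry[2] if len(entry) > 2 else None)
        stage = f"classify[{name}]"
        try:
            ds_qc = apply_gene_qc(ds, config.qc)
            scores = compute_species_scores(ds_qc)
            if config.tau_p == "auto":
                tau_p = suggest_pig_threshold(scores)
                if tau_p is None:
                    raise ValueError(
                        "tau_p='auto' but the pig-score distribution is unimodal; "
                        "supply tau_p explicitly"
                    )
            else:
                tau_p = float(config.tau_p)
            thresholds = SpeciesThresholds(tau_h=config.tau_h, tau_p=tau_p)
            labels = classify_spots(scores, thresholds, config.qc)
            interfaced = find_interfaced_spots(ds_qc.positions, labels, config.interface)
            labels = annotate_interfaced(labels, interfaced)
            summary = interface_summary(labels, interfaced)
            pca = species_pca_check(ds_qc, labels)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        label_path = out / f"labels_{name}.csv"
        write_labels(labels, label_path)
        manifest["stages"][stage] = {
            "tau_h": config.tau_h,
            "tau_p": tau_p,
            "n_genes_after_qc": ds_qc.n_genes,
            "counts": summary,
            "pca_silhouette": pca["silhouette"],
        }
        manifest["outputs"][f"labels_{name}"] = str(label_path)
        per_condition[name] = {"dataset": ds_qc, "labels": labels, "profiles": profiles}

    # deconvolution + clustering consistency where a reference is available
    for name in names:
        info = per_condition[name]
        if info["profiles"] is None:
            continue
        stage = f"deconvolve[{name}]"
        try:
            prof = info["profiles"]
            usable = [g for g in prof.genes if g in set(info["dataset"].features["feature_name"])]
            prof_sub = _subset_profiles(prof, usable)
            weights = deconvolve(
                info["dataset"], info["labels"], prof_sub,
                tol=config.deconv_tol, max_iter=config.deconv_max_iter,
            )
            human_spots = list(weights.index)
            clusters = cluster_spots(
                info["dataset"], human_spots, config.n_clusters, seed=config.seed + _SEED_CLUSTER
            )
            agree = consistency_check(weights["predominant_type"], clusters)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        wpath = out / f"weights_{name}.csv"
        write_weights(weights, wpath)
        manifest["stages"][stage] = {
            "n_spots": len(weights),
            "consistency_ari": agree["ari"],
        }
        manifest["outputs"][f"weights_{name}"] = str(wpath)

    # pseudobulk DE between the two conditions' human spots
    if len(names) == 2:
        a, b = names
        stage = f"pseudobulk_de[{a}-vs-{b}]"
        try:
            spots_a = [s for s in per_condition[a]["labels"].table.index
                       if per_condition[a]["labels"].table.loc[s, "label"] == "human"]
            spots_b = [s for s in per_condition[b]["labels"].table.index
                       if per_condition[b]["labels"].table.loc[s, "label"] == "human"]
            pooling = PoolingConfig(n_pools=config.n_pools, seed=config.seed + _SEED_POOL)
            de = run_pseudobulk_de(
                per_condition[a]["dataset"], per_condition[b]["dataset"],
                spots_a, spots_b, pooling, condition_names=(a, b), fdr=config.fdr,
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        de_path = out / f"de_{a}_vs_{b}.csv"
        write_de_table(de, de_path)
        manifest["stages"][stage] = {
            "n_genes_tested": int(de["pvalue"].notna().sum()),
            "n_significant": int(de["significant"].sum()),
            "pooling": de.attrs["pooling"],
        }
        manifest["outputs"]["de_table"] = str(de_path)

    # cohort correlations from the packaged per-subject table
    stage = "cohort"
    try:
        cohort = load_table1_fixture()
        corrs = headline_correlations(cohort)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    manifest["stages"][stage] = {
        key: {"r": round(res.r, 4), "n": res.n, "p": round(res.p, 6)}
        for key, res in corrs.items()
    }

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def _subset_profiles(profiles, genes):
    from .simulate import ReferenceProfiles

    idx = [profiles.genes.index(g) for g in genes]
    pi = profiles.pi[:, idx]
    pi = pi / pi.sum(axis=1, keepdims=True)
    return ReferenceProfiles(list(profiles.cell_types), list(genes), pi).validate()


def make_demo(out_dir, seed: int = 0) -> dict:
    """Write a ready-to-run demo workspace.

    Simulates a seeded "standard" and "RA-like" dataset pair sharing one
    reference (the RA condition carries planted 2-fold marker shifts),
    writes them in the on-disk triplet format, copies the packaged cohort
    table, and emits a pipeline config pointing at it all.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = simulate_reference_profiles(ProfileSimConfig(seed=seed))
    planted = [(g, "RA", 2.0) for g in profiles.genes[:5]]
    paths = {}
    for name, seed_off in (("standard", _SEED_SIM_A), ("RA", _SEED_SIM_B)):
        sim = XenoSimConfig(condition=name, seed=seed + seed_off, de_planted=planted)
        ds, _ = simulate_xenograft_dataset(sim, profiles=profiles)
        paths[name] = {k: str(v) for k, v in write_spot_dataset(ds, out / name).items()}
    profiles.to_frame().to_csv(out / "reference_profiles.csv")
    load_table1_fixture().to_csv(out / "cohort_table1.csv", index=False)
    cfg = {
        "out_dir": str(out / "results"),
        "seed": seed,
        "tau_h": 30.0,
        "tau_p": 700.0,
        "inputs": paths,
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return {"config": str(out / "config.yaml"), "inputs": paths}
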