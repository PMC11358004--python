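"""Species scoring, gene QC, threshold classification and PCA check."""

import numpy as np
import pandas as pd
import pytest

import xenospot as xs
from conftest import make_tiny_dataset


def _scores(h, p, n_hg=300, n_pg=300):
    return pd.DataFrame(
        {"h": h, "p": p, "n_human_genes_detected": n_hg, "n_pig_genes_detected": n_pg},
        index=pd.Index([f"b{i}" for i in range(len(h))], name="barcode"),
    )


class TestSpeciesScores:
    def test_scores_are_per_species_sums(self, tiny_dataset):
        scores = xs.compute_species_scores(tiny_dataset)
        # spot BC0: human counts {3,2}, pig counts {10}
        assert scores.loc["BC0", "h"] == 5
        assert scores.loc["BC0", "p"] == 10

    def test_all_zero_spot_scores_zero(self, tiny_dataset):
        scores = xs.compute_species_scores(tiny_dataset)
        assert scores.loc["BC1", "h"] == 0
        assert scores.loc["BC1", "p"] == 0
        assert scores.loc["BC1", "n_human_genes_detected"] == 0

    def test_scores_partition_grand_total(self, sim_dataset):
        ds, _ = sim_dataset
        scores = xs.compute_species_scores(ds)
        assert (scores["h"] + scores["p"]).sum() == ds.counts.sum()
        totals = np.asarray(ds.counts.sum(axis=0)).ravel()
        np.testing.assert_array_equal((scores["h"] + scores["p"]).to_numpy(), totals)


class TestGeneQC:
    def test_rare_gene_removed(self):
        counts = np.zeros((2, 12), dtype=int)
        counts[0, :] = 1          # detected everywhere
        counts[1, 0] = 5          # detected in 1 of 12 spots
        ds = make_tiny_dataset(counts, ["human", "pig"])
        out = xs.apply_gene_qc(ds, xs.QCConfig(min_spots_per_gene=10))
        assert out.n_genes == 1
        assert out.features["species"].tolist() == ["human"]

    def test_threshold_zero_is_identity(self, sim_dataset):
        ds, _ = sim_dataset
        out = xs.apply_gene_qc(ds, xs.QCConfig(min_spots_per_gene=0))
        assert out.n_genes == ds.n_genes

    def test_matches_brute_force_column_count(self, sim_dataset):
        ds, _ = sim_dataset
        out = xs.apply_gene_qc(ds, xs.QCConfig(min_spots_per_gene=10))
        dense = ds.counts.toarray()
        keep = (dense > 0).sum(axis=1) >= 10
        assert out.n_genes == keep.sum()
        assert out.features["feature_id"].tolist() == ds.features.loc[keep, "feature_id"].tolist()

    def test_all_genes_removed_errors(self, tiny_dataset):
        with pytest.raises(ValueError, match="every gene"):
            xs.apply_gene_qc(tiny_dataset, xs.QCConfig(min_spots_per_gene=100))


class TestClassification:
    def test_strict_inequalities(self):
        scores = _scores([31, 30], [349, 100])
        labels = xs.classify_spots(
            scores, xs.SpeciesThresholds(tau_h=30, tau_p=350),
            xs.QCConfig(min_human_genes_per_human_spot=0),
        )
        assert labels.table["label"].tolist() == ["human", "pig"]

    def test_matches_truth_table_oracle_on_grid(self):
        h, p = np.meshgrid(np.arange(41), np.arange(801), indexing="ij")
        scores = _scores(h.ravel(), p.ravel())
        labels = xs.classify_spots(scores, xs.SpeciesThresholds(tau_h=30, tau_p=700),
                                   xs.QCConfig(min_human_genes_per_human_spot=0))
        oracle = np.where((h.ravel() > 30) & (p.ravel() < 700), "human", "pig")
        np.testing.assert_array_equal(labels.table["label"].to_numpy(), oracle)

    def test_human_gene_floor_gates_human_label(self):
        scores = _scores([100, 100], [10, 10], n_hg=[79, 80])
        labels = xs.classify_spots(scores, xs.SpeciesThresholds(),
                                   xs.QCConfig(min_human_genes_per_human_spot=80))
        assert labels.table["label"].tolist() == ["pig", "human"]

    def test_all_spots_mode_excludes_low_gene_spots(self):
        scores = _scores([100, 5], [10, 5000], n_hg=[10, 10])
        labels = xs.classify_spots(
            scores, xs.SpeciesThresholds(),
            xs.QCConfig(min_human_genes_per_human_spot=80, apply_to="all_spots"),
        )
        assert labels.table["label"].tolist() == ["excluded", "excluded"]

    @pytest.mark.parametrize("tau_h,tau_p", [(30, 700), (10, 350), (0, 100)])
    def test_monotone_in_thresholds(self, tau_h, tau_p):
        rng = np.random.default_rng(0)
        scores = _scores(rng.integers(0, 200, 500), rng.integers(0, 2000, 500))
        base = xs.classify_spots(scores, xs.SpeciesThresholds(tau_h, tau_p)).mask("human")
        wider = xs.classify_spots(scores, xs.SpeciesThresholds(tau_h, tau_p * 2)).mask("human")
        assert (base <= wider).all()          # raising tau_p never removes a human
        stricter = xs.classify_spots(scores, xs.SpeciesThresholds(tau_h + 20, tau_p)).mask("human")
        assert (stricter <= base).all()       # raising tau_h never adds one


class TestPigThresholdSuggestion:
    def test_bimodal_valley_between_modes(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([
            10 ** rng.normal(np.log10(50), 0.2, 200),
            10 ** rng.normal(np.log10(5000), 0.2, 200),
        ])
        tau = xs.suggest_pig_threshold(_scores(np.zeros_like(p), p))
        assert 150 <= tau <= 1500

    def test_unimodal_returns_none(self):
        rng = np.random.default_rng(2)
        p = 10 ** rng.normal(2.0, 0.2, 300)
        assert xs.suggest_pig_threshold(_scores(np.zeros_like(p), p)) is None

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([
            10 ** rng.normal(np.log10(50), 0.2, 200),
            10 ** rng.normal(np.log10(5000), 0.2, 200),
        ])
        tau1 = xs.suggest_pig_threshold(_scores(np.zeros_like(p), p))
        tau10 = xs.suggest_pig_threshold(_scores(np.zeros_like(p), 10 * p))
        assert tau10 / tau1 == pytest.approx(10.0, rel=0.25)

    def test_too_few_spots_errors(self):
        with pytest.raises(ValueError, match="[Ii]nsufficient"):
            xs.suggest_pig_threshold(_scores(np.zeros(10), np.ones(10)))


@pytest.fixture(scope="module")
def clean_dataset():
    ds, truth = xs.simulate_xenograft_dataset(xs.XenoSimConfig(seed=21, bleed_rate=0.0))
    labels = xs.classify_spots(xs.compute_species_scores(ds))
    return ds, labels


class TestPCACheck:
    def test_clean_separation_has_high_silhouette(self, clean_dataset):
        ds, labels = clean_dataset
        report = xs.species_pca_check(ds, labels)
        assert report["silhouette"] > 0.5

    def test_permuted_labels_have_near_zero_silhouette(self, clean_dataset):
        ds, labels = clean_dataset
        rng = np.random.default_rng(0)
        sils = []
        for _ in range(20):
            perm = labels.table.copy()
            perm["label"] = rng.permutation(perm["label"].to_numpy())
            sils.append(xs.species_pca_check(ds, xs.SpotLabelTable(perm))["silhouette"])
        assert abs(np.mean(sils)) < 0.1

    def test_invariant_to_gene_order(self, clean_dataset):
        ds, labels = clean_dataset
        rng = np.random.default_rng(4)
        perm = rng.permutation(ds.n_genes)
        shuffled = xs.SpotDataset(
            counts=ds.counts[perm].tocsr(),
            features=ds.features.iloc[perm].reset_index(drop=True),
            barcodes=list(ds.barcodes),
            positions=ds.positions,
        )
        a = xs.species_pca_check(ds, labels)["silhouette"]
        b = xs.species_pca_check(shuffled, labels)["silhouette"]
        assert a == pytest.approx(b, abs=1e-6)

    def test_absent_label_errors(self, clean_dataset):
        ds, labels = clean_dataset
        allpig = labels.table.copy()
        allpig["label"] = "pig"
        with pytest.raises(ValueError, match="human"):
            xs.species_pca_check(ds, xs.SpotLabelTable(allpig))
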