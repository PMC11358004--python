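"""EM weight recovery, predominant-type calls and clustering consistency."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import xenospot as xs
from xenospot.simulate import ReferenceProfiles


def orthogonal_profiles():
    pi = np.zeros((2, 10))
    pi[0, :5] = 0.2
    pi[1, 5:] = 0.2
    return ReferenceProfiles(["t1", "t2"], [f"g{i}" for i in range(10)], pi).validate()


class TestFitSpotWeights:
    def test_vertex_mle_for_pure_profile(self):
        prof = orthogonal_profiles()
        y = 1000 * prof.pi[0]
        res = xs.fit_spot_weights(y, prof)
        np.testing.assert_allclose(res.weights, [1.0, 0.0], atol=1e-6)
        assert res.predominant_type == "t1"

    def test_even_mixture_recovered(self):
        prof = orthogonal_profiles()
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.multinomial(10_000, 0.5 * prof.pi[0] + 0.5 * prof.pi[1])
            res = xs.fit_spot_weights(y, prof)
            errs.append(abs(res.weights[0] - 0.5))
        assert max(errs) < 0.02

    def test_single_type_returns_unit_weight(self):
        pi = np.full((1, 5), 0.2)
        prof = ReferenceProfiles(["only"], [f"g{i}" for i in range(5)], pi)
        res = xs.fit_spot_weights(np.array([3, 1, 0, 2, 9.0]), prof)
        assert res.weights.tolist() == [1.0]

    def test_empty_spot_errors(self):
        with pytest.raises(ValueError, match="empty spot"):
            xs.fit_spot_weights(np.zeros(10), orthogonal_profiles())

    def test_objective_non_decreasing(self, profiles):
        rng = np.random.default_rng(3)
        for _ in range(5):
            w = rng.dirichlet(np.ones(len(profiles.cell_types)))
            y = rng.multinomial(5000, w @ profiles.pi)
            res = xs.fit_spot_weights(y, profiles, track_objective=True)
            assert np.all(np.diff(res.objective_path) >= -1e-9)

    def test_type_permutation_equivariance(self, profiles):
        rng = np.random.default_rng(4)
        y = rng.multinomial(5000, np.array([0.4, 0.3, 0.2, 0.1]) @ profiles.pi)
        res = xs.fit_spot_weights(y, profiles)
        perm = [2, 0, 3, 1]
        prof_perm = ReferenceProfiles(
            [profiles.cell_types[i] for i in perm], list(profiles.genes), profiles.pi[perm]
        )
        res_perm = xs.fit_spot_weights(y, prof_perm)
        np.testing.assert_allclose(res_perm.weights, res.weights[perm], atol=1e-4)

    def test_bias_shrinks_with_depth(self, profiles):
        w_true = np.array([0.4, 0.3, 0.2, 0.1])
        mix = w_true @ profiles.pi
        errs = {}
        for depth in (1_000, 10_000, 100_000):
            rng = np.random.default_rng(int(depth))
            est = np.mean(
                [xs.fit_spot_weights(rng.multinomial(depth, mix), profiles).weights
                 for _ in range(20)],
                axis=0,
            )
            errs[depth] = np.abs(est - w_true).max()
        assert errs[100_000] < errs[1_000]
        assert errs[100_000] < 0.01


class TestDeconvolve:
    def test_weights_rows_sum_to_one(self, sim_dataset, profiles):
        ds, truth = sim_dataset
        prof = xs.simulate_reference_profiles(xs.ProfileSimConfig(seed=11))
        labels = xs.classify_spots(xs.compute_species_scores(ds))
        weights = xs.deconvolve(ds, labels, prof)
        w = weights[prof.cell_types].to_numpy()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-8)

    def test_recovers_true_weights(self, sim_dataset):
        ds, truth = sim_dataset
        prof = xs.simulate_reference_profiles(xs.ProfileSimConfig(seed=11))
        labels = xs.classify_spots(xs.compute_species_scores(ds))
        weights = xs.deconvolve(ds, labels, prof)
        w_est = weights[prof.cell_types].to_numpy()
        w_true = truth.weights.loc[weights.index, prof.cell_types].to_numpy()
        rmse = np.sqrt(((w_est - w_true) ** 2).mean(axis=1)).mean()
        assert rmse < 0.05

    def test_no_human_spots_errors(self, sim_dataset):
        ds, _ = sim_dataset
        prof = xs.simulate_reference_profiles(xs.ProfileSimConfig(seed=11))
        labels = xs.classify_spots(
            xs.compute_species_scores(ds), xs.SpeciesThresholds(tau_h=1e9, tau_p=1))
        with pytest.raises(ValueError, match="no human spots"):
            xs.deconvolve(ds, labels, prof)


class TestClustering:
    def test_separated_blocks_recovered_exactly(self):
        # two disjoint expression blocks over 40 spots -> perfect 2-clustering
        rng = np.random.default_rng(31)
        counts = np.zeros((10, 40), dtype=int)
        counts[:5, :20] = rng.poisson(50, size=(5, 20))
        counts[5:, 20:] = rng.poisson(50, size=(5, 20))
        from conftest import make_tiny_dataset

        ds = make_tiny_dataset(counts, ["human"] * 5 + ["pig"] * 5)
        truth_lab = np.repeat([0, 1], 20)
        clusters = xs.cluster_spots(ds, list(ds.barcodes), 2, seed=0)
        assert adjusted_rand_score(truth_lab, clusters) == pytest.approx(1.0)

    def test_single_cluster_disallowed(self, sim_dataset):
        ds, _ = sim_dataset
        with pytest.raises(ValueError, match="n_clusters"):
            xs.cluster_spots(ds, list(ds.barcodes), 1)

    def test_fewer_spots_than_clusters_errors(self, sim_dataset):
        ds, _ = sim_dataset
        with pytest.raises(ValueError, match="clusters"):
            xs.cluster_spots(ds, ds.barcodes[:2], 3)

    def test_seeded_determinism(self, sim_dataset):
        ds, _ = sim_dataset
        a = xs.cluster_spots(ds, ds.barcodes[:100], 3, seed=5)
        b = xs.cluster_spots(ds, ds.barcodes[:100], 3, seed=5)
        assert a.equals(b)


class TestConsistencyCheck:
    def test_identical_partitions_score_one(self):
        idx = pd.Index([f"s{i}" for i in range(60)])
        types = pd.Series(["a", "b", "c"] * 20, index=idx)
        clusters = pd.Series([0, 1, 2] * 20, index=idx)
        assert xs.consistency_check(types, clusters)["ari"] == pytest.approx(1.0)

    def test_independent_partitions_score_near_zero(self):
        rng = np.random.default_rng(0)
        scores = []
        for _ in range(100):
            idx = pd.Index([f"s{i}" for i in range(200)])
            types = pd.Series(rng.choice(["a", "b"], 200), index=idx)
            clusters = pd.Series(rng.choice([0, 1], 200), index=idx)
            scores.append(xs.consistency_check(types, clusters)["ari"])
        assert abs(np.mean(scores)) < 0.05

    def test_coarse_graining_maximises_agreement(self):
        # 4 types that collapse pairwise onto 2 clusters
        idx = pd.Index([f"s{i}" for i in range(80)])
        types = pd.Series((["a"] * 20 + ["b"] * 20 + ["c"] * 20 + ["d"] * 20), index=idx)
        clusters = pd.Series([0] * 40 + [1] * 40, index=idx)
        out = xs.consistency_check(types, clusters)
        assert out["ari"] == pytest.approx(1.0)
        assert out["grouping"]["a"] == out["grouping"]["b"]
        assert out["grouping"]["c"] == out["grouping"]["d"]

    def test_synthetic_graft_agreement(self):
        ds, truth = xs.simulate_xenograft_dataset(
            xs.XenoSimConfig(
                seed=33,
                cell_types={"ventricular_CM": 0.5, "atrial_pacemaker_CM": 0.5},
                celltype_concentration=0.3,  # spots dominated by one of two types
            )
        )
        prof = xs.simulate_reference_profiles(
            xs.ProfileSimConfig(cell_types=["ventricular_CM", "atrial_pacemaker_CM"], seed=33)
        )
        labels = xs.classify_spots(xs.compute_species_scores(ds))
        weights = xs.deconvolve(ds, labels, prof)
        human = list(weights.index)
        clusters = xs.cluster_spots(ds.subset_genes(ds.species_mask("human")), human, 2, seed=0)
        out = xs.consistency_check(weights["predominant_type"], clusters)
        assert out["ari"] > 0.5
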