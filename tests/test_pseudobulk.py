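"""Pooling, normalisation, the NB test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest

import xenospot as xs
from xenospot.pseudobulk import PseudoReplicateSet, _nb_deviance, _nb_fit_eta


def make_reps(values, condition="A", aggregation="sum", pool_sizes=None):
    values = np.asarray(values, float)
    g, m = values.shape
    sizes = pool_sizes or [1] * m
    members = [[f"{condition}{i}_{j}" for j in range(s)] for i, s in enumerate(sizes)]
    df = pd.DataFrame(values, index=pd.Index([f"g{i}" for i in range(g)], name="gene"),
                      columns=[f"{condition}{i}" for i in range(m)])
    return PseudoReplicateSet(condition, df, members, aggregation)


class TestPooling:
    @pytest.fixture
    def dataset(self):
        ds, _ = xs.simulate_xenograft_dataset(
            xs.XenoSimConfig(seed=41, grid_rows=6, grid_cols=6))
        return ds

    def test_nine_spots_three_equal_pools(self, dataset):
        reps = xs.pool_spots(dataset, dataset.barcodes[:9], xs.PoolingConfig(seed=0))
        sizes = sorted(len(m) for m in reps.pool_members)
        assert sizes == [3, 3, 3]
        flat = [s for pool in reps.pool_members for s in pool]
        assert sorted(flat) == sorted(dataset.barcodes[:9])

    def test_ten_spots_sizes_differ_by_one(self, dataset):
        reps = xs.pool_spots(dataset, dataset.barcodes[:10], xs.PoolingConfig(seed=0))
        assert sorted((len(m) for m in reps.pool_members), reverse=True) == [4, 3, 3]

    def test_seed_reproducibility_and_distinctness(self, dataset):
        spots = dataset.barcodes[:30]
        a = xs.pool_spots(dataset, spots, xs.PoolingConfig(seed=1))
        b = xs.pool_spots(dataset, spots, xs.PoolingConfig(seed=1))
        c = xs.pool_spots(dataset, spots, xs.PoolingConfig(seed=2))
        assert a.pool_members == b.pool_members
        assert a.pool_members != c.pool_members

    def test_mean_aggregation_matches_pool_average(self, dataset):
        reps = xs.pool_spots(dataset, dataset.barcodes[:9], xs.PoolingConfig(seed=3))
        col_of = {b: j for j, b in enumerate(dataset.barcodes)}
        dense = dataset.counts.toarray()
        for i, pool in enumerate(reps.pool_members):
            manual = dense[:, [col_of[b] for b in pool]].mean(axis=1)
            np.testing.assert_allclose(reps.values.iloc[:, i], manual)

    def test_too_few_spots_errors(self, dataset):
        with pytest.raises(ValueError, match="pools"):
            xs.pool_spots(dataset, dataset.barcodes[:2], xs.PoolingConfig(n_pools=3))


class TestNormalization:
    def test_equal_totals_give_unit_factors(self):
        vals = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 2.0]})
        _, sf = xs.normalize_libsize(vals)
        np.testing.assert_allclose(sf, [1.0, 1.0])

    def test_scaled_pool_gets_scaled_factor(self):
        vals = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 6.0]})
        _, sf = xs.normalize_libsize(vals)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_normalised_totals_equal(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.poisson(50, size=(100, 3)).astype(float))
        norm, _ = xs.normalize_libsize(vals)
        totals = norm.sum(axis=0).to_numpy()
        np.testing.assert_allclose(totals, totals[0])

    def test_zero_total_pool_errors(self):
        vals = pd.DataFrame({"a": [1.0], "b": [0.0]})
        with pytest.raises(ValueError, match="non-positive"):
            xs.normalize_libsize(vals)


def bh_step_up_oracle(pvals, alpha=0.05):
    """Literal step-up definition: reject the largest k with p(k) <= k/m*alpha,
    adjusted p = min over j >= rank of m*p(j)/j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        adj[idx] = running
    return adj


class TestBHAdjustment:
    def test_property_matches_step_up_oracle(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st
        from statsmodels.stats.multitest import multipletests

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
        def check(pvals):
            p = np.asarray(pvals)
            _, q, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, bh_step_up_oracle(p), atol=1e-12)

        check()

    @pytest.mark.parametrize("n", [10, 137, 1000])
    def test_matches_step_up_oracle(self, n):
        rng = np.random.default_rng(n)
        p = rng.uniform(size=n) ** 2
        # compare through the same statsmodels call used by fit_nb_test
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh_step_up_oracle(p), atol=1e-12)


class TestNBTest:
    def test_identical_inputs_give_null_table(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(40, size=(50, 3)).astype(float)
        de = xs.fit_nb_test(make_reps(vals, "A"), make_reps(vals, "B"))
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-8)
        assert not de["significant"].any()

    def test_condition_swap_flips_log2fc(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(30, size=(40, 3)).astype(float)
        b = rng.poisson(45, size=(40, 3)).astype(float)
        de_ab = xs.fit_nb_test(make_reps(a, "A"), make_reps(b, "B"))
        de_ba = xs.fit_nb_test(make_reps(b, "B"), make_reps(a, "A"))
        np.testing.assert_allclose(de_ab["log2fc"], -de_ba["log2fc"], atol=1e-6)
        np.testing.assert_allclose(de_ab["pvalue"], de_ba["pvalue"], atol=1e-8)

    def test_all_zero_gene_gets_na_and_no_rank(self):
        a = np.array([[10.0, 12, 11], [0, 0, 0]])
        b = np.array([[9.0, 13, 10], [0, 0, 0]])
        de = xs.fit_nb_test(make_reps(a, "A"), make_reps(b, "B"))
        assert np.isnan(de.loc["g1", "pvalue"])
        assert np.isnan(de.loc["g1", "qvalue"])
        assert not de.loc["g1", "significant"]

    def test_nb_degenerates_to_poisson_at_tiny_dispersion(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(30, size=(20, 3)).astype(float)
        s = np.array([0.9, 1.0, 1.1])
        r = np.full(20, 1.0 / 1e-10)
        eta = _nb_fit_eta(y, s, r)
        eta_pois = np.log(y.sum(axis=1) / s.sum())
        np.testing.assert_allclose(eta, eta_pois, atol=1e-6)
        mu = s[None, :] * np.exp(eta)[:, None]
        dev_nb = _nb_deviance(y, mu, r)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_pois = (2 * (np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))).sum(axis=1)
        np.testing.assert_allclose(dev_nb, dev_pois, atol=1e-6)

    def test_planted_genes_rank_in_top_percentile(self, profiles):
        planted = [(g, "RA", 2.0) for g in profiles.genes[50:60]]
        ds_a, t_a = xs.simulate_xenograft_dataset(
            xs.XenoSimConfig(seed=43, condition="standard", de_planted=planted),
            profiles=profiles)
        ds_b, t_b = xs.simulate_xenograft_dataset(
            xs.XenoSimConfig(seed=44, condition="RA", de_planted=planted),
            profiles=profiles)
        spots_a = [b for b, l in zip(ds_a.barcodes, t_a.labels) if l == "human"]
        spots_b = [b for b, l in zip(ds_b.barcodes, t_b.labels) if l == "human"]
        de = xs.run_pseudobulk_de(ds_a, ds_b, spots_a, spots_b, xs.PoolingConfig(seed=0))
        cutoff = de["pvalue"].quantile(0.05)
        assert (de.loc[[g for g, _, _ in planted], "pvalue"] <= cutoff).all()
        assert (de.loc[[g for g, _, _ in planted], "log2fc"] > 1).all()

    def test_rerun_with_recorded_seed_reproduces_table(self, profiles):
        ds_a, t_a = xs.simulate_xenograft_dataset(
            xs.XenoSimConfig(seed=45, condition="standard"), profiles=profiles)
        ds_b, t_b = xs.simulate_xenograft_dataset(
            xs.XenoSimConfig(seed=46, condition="RA"), profiles=profiles)
        spots_a = [b for b, l in zip(ds_a.barcodes, t_a.labels) if l == "human"]
        spots_b = [b for b, l in zip(ds_b.barcodes, t_b.labels) if l == "human"]
        cfg = xs.PoolingConfig(seed=7)
        de1 = xs.run_pseudobulk_de(ds_a, ds_b, spots_a, spots_b, cfg)
        de2 = xs.run_pseudobulk_de(ds_a, ds_b, spots_a, spots_b, cfg)
        pd.testing.assert_frame_equal(de1, de2)
        assert de1.attrs["pooling"]["seed"] == 7
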