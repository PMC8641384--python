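"""Fold construction, the mean-R metric, inner tuning, and the nested-CV,
cross-population and mixed-population designs on simulated genes."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twasbench import (SimConfig, cross_population_eval, inner_tune, make_folds,
                       mixed_population_counts, mixed_population_cv, nested_cv,
                       pearson_r, simulate_cohort)
from twasbench.crossval import gene_design, train_gene_model


class TestPearsonR:
    def test_affine_invariance(self, rng):
        obs = rng.standard_normal(50)
        assert pearson_r(2 * obs + 1, obs) == pytest.approx(1.0)
        assert pearson_r(-obs, obs) == pytest.approx(-1.0)

    def test_constant_prediction_is_zero_by_convention(self, rng):
        assert pearson_r(np.full(20, 3.0), rng.standard_normal(20)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.zeros(5), np.zeros(6))


class TestMakeFolds:
    def test_373_samples_split_as_in_the_ten_fold_design(self):
        folds = make_folds(373, 10, seed=1)
        sizes = sorted(np.bincount(folds.fold_of))
        assert sizes == [37] * 7 + [38] * 3
        assert np.array_equal(np.sort(np.unique(folds.fold_of)), np.arange(10))

    def test_same_seed_same_assignment(self):
        a = make_folds(100, 10, seed=7)
        b = make_folds(100, 10, seed=7)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)

    def test_leave_one_out_limit(self):
        folds = make_folds(10, 10, seed=0)
        assert sorted(np.bincount(folds.fold_of)) == [1] * 10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_folds(9, 10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(10, 400), st.integers(2, 10), st.integers(0, 1000))
    def test_partition_property(self, n, k, seed):
        folds = make_folds(n, k, seed)
        counts = np.bincount(folds.fold_of, minlength=k)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1


class TestInnerTune:
    def test_single_point_grid_returned(self, small_cohort):
        _, panel, expr, _ = small_cohort
        cis, y = gene_design(panel, expr, "gene0")
        out = inner_tune("lasso", cis.dosages, y, grid=[0.42], seed=0)
        assert out["lambda"] == 0.42

    def test_empty_grid_rejected(self, small_cohort):
        _, panel, expr, _ = small_cohort
        cis, y = gene_design(panel, expr, "gene0")
        with pytest.raises(ValueError):
            inner_tune("lasso", cis.dosages, y, grid=[], seed=0)

    def test_untunable_method_rejected(self):
        with pytest.raises(ValueError):
            inner_tune("blup", np.zeros((20, 2)), np.zeros(20))

    def test_tuned_alpha_leans_sparse_on_sparse_genes(self):
        hits, reps = 0, 12
        for rep in range(reps):
            cfg = SimConfig(n_samples=(150,), n_snps=30, n_genes=1, h2_cis=0.6,
                            architecture="sparse", n_causal=2, seed=100 + rep)
            panel, expr, _ = simulate_cohort(cfg)
            cis, y = gene_design(panel, expr, "gene0")
            out = inner_tune("enet-cv", cis.dosages, y, seed=rep)
            hits += out["alpha"] >= 0.5
        assert hits / reps >= 0.7


class TestNestedCv:
    def test_noiseless_sparse_gene_is_recovered(self):
        cfg = SimConfig(n_samples=(300,), n_snps=40, n_genes=1, h2_cis=0.99,
                        architecture="sparse", n_causal=1, maf_range=(0.2, 0.5),
                        seed=31)
        panel, expr, _ = simulate_cohort(cfg)
        cis, y = gene_design(panel, expr, "gene0")
        res = nested_cv("lasso", cis.dosages, y, seed=2, snps=cis.snps)
        assert res.mean_r > 0.95

    def test_null_genes_centre_on_zero(self):
        cfg = SimConfig(n_samples=(150,), n_snps=30, n_genes=15, h2_cis=0.0, seed=32)
        panel, expr, _ = simulate_cohort(cfg)
        means = [nested_cv("enet", *_xy(panel, expr, g), seed=3).mean_r
                 for g in expr.gene_ids]
        assert abs(np.mean(means)) < 0.1

    def test_small_training_fraction_reduces_accuracy(self):
        cfg = SimConfig(n_samples=(300,), n_snps=40, n_genes=10, h2_cis=0.4,
                        architecture="sparse", n_causal=2, seed=33)
        panel, expr, _ = simulate_cohort(cfg)
        lo, hi = [], []
        for g in expr.gene_ids:
            X, y = _xy(panel, expr, g)
            from twasbench.crossval import make_folds as mf

            folds = mf(len(y), 10, seed=4)
            hi.append(nested_cv("enet", X, y, train_folds=9, folds=folds).mean_r)
            lo.append(nested_cv("enet", X, y, train_folds=1, folds=folds).mean_r)
        assert np.mean(lo) < np.mean(hi)

    def test_sparse_vs_polygenic_ordering_flips(self):
        # ridge should close the gap (or win) when every SNP is causal
        sp = SimConfig(n_samples=(250,), n_snps=40, n_genes=8, h2_cis=0.5,
                       architecture="sparse", n_causal=1, seed=34)
        po = SimConfig(n_samples=(250,), n_snps=40, n_genes=8, h2_cis=0.5,
                       architecture="polygenic", seed=35)
        gaps = {}
        for name, cfg in [("sparse", sp), ("polygenic", po)]:
            panel, expr, _ = simulate_cohort(cfg)
            lasso = np.mean([nested_cv("lasso", *_xy(panel, expr, g), seed=5).mean_r
                             for g in expr.gene_ids])
            ridge = np.mean([nested_cv("ridge", *_xy(panel, expr, g), seed=5).mean_r
                             for g in expr.gene_ids])
            gaps[name] = lasso - ridge
        assert gaps["sparse"] > 0.03
        assert gaps["polygenic"] < gaps["sparse"]

    def test_invalid_train_folds(self):
        with pytest.raises(ValueError):
            nested_cv("enet", np.zeros((50, 3)), np.zeros(50), train_folds=10)


def _xy(panel, expr, gene):
    cis, y = gene_design(panel, expr, gene)
    return cis.dosages, y


class TestCrossPopulation:
    def test_identical_panels_reproduce_in_sample_r(self, small_cohort):
        _, panel, expr, _ = small_cohort
        df = cross_population_eval("enet", panel, expr, panel, expr, seed=6)
        cis, y = gene_design(panel, expr, "gene0")
        model = train_gene_model("enet", cis.dosages, y, gene="gene0", seed=6)
        expected = pearson_r(model.predict(cis.dosages), y)
        got = df.set_index("gene").loc["gene0", "r"]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_two_population_eval_runs_and_reports_shared_snps(self, two_pop_cohort):
        _, panel, expr, _ = two_pop_cohort
        pa = panel.population("popA")
        pb = panel.population("popB")
        ea = expr.subset_samples(pd.Index(expr.sample_ids).get_indexer(pa.sample_ids))
        eb = expr.subset_samples(pd.Index(expr.sample_ids).get_indexer(pb.sample_ids))
        df = cross_population_eval("lasso", pa, ea, pb, eb, seed=7)
        assert len(df) == len(expr.gene_ids)
        assert (df["n_snps"] > 0).all()


class TestMixedPopulation:
    def test_proportional_downsampling_arithmetic(self):
        take = mixed_population_counts({"EUR": 373, "YRI": 89}, 373)
        assert take["EUR"] + take["YRI"] == 373
        assert take["EUR"] in (301, 302)
        assert take["YRI"] in (71, 72)

    def test_oversized_request_rejected(self, two_pop_cohort):
        _, panel, expr, _ = two_pop_cohort
        with pytest.raises(ValueError):
            mixed_population_cv(panel, expr, panel.n_samples + 1, "enet")
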