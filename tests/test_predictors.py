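"""Solver correctness against independent oracles: closed-form normal
equations, orthonormal soft-thresholding, FISTA proximal gradient, grid
search, and Henderson's mixed-model equations."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twasbench import (ForestSpec, fit_blup, fit_elastic_net, fit_lasso,
                       fit_random_forest, fit_ridge, predict_blup,
                       predict_from_weights, standardize)
from twasbench.genio import EmptyPanelError
from twasbench.predictors import (ModelFitError, enet_objective,
                                  lasso_objective, ridge_objective)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fista(X, y, lam, alpha, n_iter=20_000):
    """Proximal-gradient minimizer of the elastic-net objective
    (y-Xb)^2 + lam*(0.5*(1-alpha)*||b||^2 + alpha*||b||_1)."""
    n, p = X.shape
    L = 2 * np.linalg.norm(X, 2) ** 2 + lam * (1 - alpha) + 1e-12
    b = np.zeros(p)
    z = b.copy()
    t = 1.0
    thr = lam * alpha / L
    for _ in range(n_iter):
        grad = 2 * X.T @ (X @ z - y) + lam * (1 - alpha) * z
        w = z - grad / L
        b_new = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        z = b_new + (t - 1) / t_new * (b_new - b)
        b, t = b_new, t_new
    return b


def grid_min_objective(X, y, lam, alpha, lo=-3.0, hi=3.0, step=0.05):
    """Brute-force minimum of the elastic-net objective over a cubic grid
    (p = 3 only)."""
    Q = X.T @ X
    c = X.T @ y
    yy = float(y @ y)
    axis = np.arange(lo, hi + step / 2, step)
    best = np.inf
    B23 = np.stack(np.meshgrid(axis, axis, indexing="ij"), axis=-1).reshape(-1, 2)
    pen23 = lam * (0.5 * (1 - alpha) * (B23 ** 2).sum(1) + alpha * np.abs(B23).sum(1))
    quad23 = (B23 * (B23 @ Q[1:, 1:])).sum(1) - 2 * B23 @ c[1:]
    cross = 2 * B23 @ Q[1:, 0]
    for b1 in axis:
        obj = (yy + quad23 + b1 * cross + Q[0, 0] * b1 * b1 - 2 * c[0] * b1
               + pen23 + lam * (0.5 * (1 - alpha) * b1 * b1 + alpha * abs(b1)))
        m = obj.min()
        if m < best:
            best = m
    return best


def henderson_mme(X, y, sigma_u2, sigma_e2):
    """Henderson's mixed-model equations for y = 1 mu + u + e,
    u ~ N(0, sigma_u2 G), G = X X^T / p (requires G nonsingular)."""
    n, p = X.shape
    G = X @ X.T / p
    Ginv = np.linalg.inv(G)
    C = np.block([
        [np.array([[n]]), np.ones((1, n))],
        [np.ones((n, 1)), np.eye(n) + (sigma_e2 / sigma_u2) * Ginv],
    ])
    rhs = np.concatenate([[y.sum()], y])
    sol = np.linalg.solve(C, rhs)
    return sol[0], sol[1:]


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------

class TestRidge:
    def test_identity_design_closed_form(self):
        model = fit_ridge(np.eye(2), np.array([2.0, 0.0]), 1.0)
        np.testing.assert_allclose(model.weights_std, [1.0, 0.0])

    def test_lambda_zero_equals_ols(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        model = fit_ridge(X, y, 0.0)
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.weights_std, ols, atol=1e-8)

    def test_huge_lambda_shrinks_to_zero(self, rng):
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        model = fit_ridge(X, y, 1e12)
        assert np.max(np.abs(model.weights_std)) < 1e-6

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_ridge(np.eye(2), np.zeros(2), -1.0)


# ---------------------------------------------------------------------------
# lasso / elastic net
# ---------------------------------------------------------------------------

class TestLassoEnet:
    def test_orthonormal_soft_threshold(self):
        q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((6, 2)))
        y = q @ np.array([3.0, 0.4])
        model = fit_lasso(q, y, 2.0)
        np.testing.assert_allclose(model.weights_std, [2.0, 0.0], atol=1e-7)

    def test_null_model_threshold(self, rng):
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        lam = 2.0 * np.max(np.abs(X.T @ y))
        assert np.all(fit_lasso(X, y, lam).weights_std == 0.0)
        assert np.any(fit_lasso(X, y, 0.9 * lam).weights_std != 0.0)

    def test_lasso_beats_grid_oracle(self, rng):
        X = rng.standard_normal((10, 3))
        y = X @ np.array([1.5, -0.8, 0.0]) + 0.3 * rng.standard_normal(10)
        lam = 2.0
        model = fit_lasso(X, y, lam)
        assert lasso_objective(X, y, model.weights_std, lam) <= \
            grid_min_objective(X, y, lam, alpha=1.0) + 1e-3

    def test_enet_beats_grid_oracle(self, rng):
        X = rng.standard_normal((20, 3))
        y = X @ np.array([1.0, 0.5, -0.5]) + 0.5 * rng.standard_normal(20)
        lam = 3.0
        model = fit_elastic_net(X, y, lam, 0.5)
        assert enet_objective(X, y, model.weights_std, lam, 0.5) <= \
            grid_min_objective(X, y, lam, alpha=0.5) + 1e-3

    def test_alpha_one_equals_lasso(self, rng):
        X = rng.standard_normal((15, 5))
        y = rng.standard_normal(15)
        np.testing.assert_allclose(fit_elastic_net(X, y, 2.0, 1.0).weights_std,
                                   fit_lasso(X, y, 2.0).weights_std, atol=1e-7)

    def test_alpha_zero_equals_ridge_at_half_lambda(self, rng):
        X = rng.standard_normal((15, 5))
        y = rng.standard_normal(15)
        np.testing.assert_allclose(fit_elastic_net(X, y, 4.0, 0.0).weights_std,
                                   fit_ridge(X, y, 2.0).weights_std, atol=1e-8)

    def test_fista_oracle_on_random_instances(self, rng):
        for _ in range(5):
            n, p = int(rng.integers(10, 30)), int(rng.integers(3, 8))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            lam = float(rng.uniform(0.5, 5.0))
            alpha = float(rng.uniform(0.1, 1.0))
            model = fit_elastic_net(X, y, lam, alpha)
            gap = enet_objective(X, y, model.weights_std, lam, alpha) - \
                enet_objective(X, y, fista(X, y, lam, alpha), lam, alpha)
            assert gap < 1e-3

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            fit_elastic_net(np.eye(2), np.zeros(2), 1.0, 1.5)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0), st.floats(0.0, 10.0))
    def test_penalized_objective_never_exceeds_null(self, seed, alpha, lam):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        model = fit_elastic_net(X, y, lam, alpha)
        assert enet_objective(X, y, model.weights_std, lam, alpha) <= \
            enet_objective(X, y, np.zeros(4), lam, alpha) + 1e-9

    def test_shift_invariance_up_to_intercept(self, rng):
        # fits on centered y: adding a constant to y only moves the intercept
        from twasbench.crossval import train_gene_model

        D = rng.integers(0, 3, size=(40, 6)).astype(float)
        y = rng.standard_normal(40)
        hyper = {"lambda": 2.0, "alpha": 0.5}
        m1 = train_gene_model("enet", D, y, seed=0, hyper=hyper)
        m2 = train_gene_model("enet", D, y + 7.5, seed=0, hyper=hyper)
        np.testing.assert_allclose(m1.weights_std, m2.weights_std, atol=1e-8)
        np.testing.assert_allclose(m2.predict(D), m1.predict(D) + 7.5, atol=1e-7)


# ---------------------------------------------------------------------------
# BLUP
# ---------------------------------------------------------------------------

class TestBlup:
    def test_null_heritability_recovered(self, rng):
        X, _, _ = standardize(rng.standard_normal((500, 50)))
        y = rng.standard_normal(500)
        fit = fit_blup(X, y)
        assert fit.sigma_u2 / (fit.sigma_u2 + fit.sigma_e2) < 0.1

    def test_prediction_is_kernel_ridge_identity(self, rng):
        X, _, _ = standardize(rng.standard_normal((60, 30)))
        y = X @ rng.standard_normal(30) * 0.3 + rng.standard_normal(60)
        fit = fit_blup(X, y)
        X_new, _, _ = standardize(rng.standard_normal((10, 30)))
        G11 = X @ X.T / 30
        G21 = X_new @ X.T / 30
        ratio = fit.sigma_e2 / max(fit.sigma_u2, 1e-12)
        oracle = fit.mu + G21 @ np.linalg.solve(
            G11 + ratio * np.eye(60) + 1e-10 * np.eye(60), y - fit.mu)
        np.testing.assert_allclose(predict_blup(fit, X_new), oracle, atol=1e-6)

    def test_matches_henderson_mme_oracle(self, rng):
        # p >= n keeps G nonsingular (columns deliberately left uncentered);
        # data built with an interior variance ratio so REML stays off the
        # boundary and the MME system is well posed
        X = rng.standard_normal((40, 80))
        G = X @ X.T / 80
        u = np.linalg.cholesky(G + 1e-10 * np.eye(40)) @ rng.standard_normal(40)
        y = 1.5 + u + rng.standard_normal(40)
        fit = fit_blup(X, y)
        assert fit.sigma_e2 > 1e-6 and fit.sigma_u2 > 1e-6
        mu_o, u_o = henderson_mme(X, y, fit.sigma_u2, fit.sigma_e2)
        assert abs(fit.mu - mu_o) < 1e-6
        np.testing.assert_allclose(fit.u, u_o, atol=1e-5)

    def test_degenerate_phenotype_signals(self, rng):
        X, _, _ = standardize(rng.standard_normal((30, 5)))
        with pytest.raises(ModelFitError):
            fit_blup(X, np.ones(30))


# ---------------------------------------------------------------------------
# Random Forests
# ---------------------------------------------------------------------------

class TestRandomForest:
    def test_single_training_sample_predicts_constant(self):
        model = fit_random_forest(np.array([[1.0, 0.0]]), np.array([5.0]),
                                  ForestSpec(n_trees=20, seed=1))
        np.testing.assert_allclose(model.predict(np.zeros((4, 2))), 5.0)

    def test_recovers_step_function_of_binary_snp(self, rng):
        x = rng.integers(0, 2, 400).astype(float)
        X = np.column_stack([x, rng.standard_normal(400)])
        y = np.where(x > 0.5, 3.0, -3.0)
        model = fit_random_forest(X[:300], y[:300], ForestSpec(n_trees=100, seed=2))
        preds = model.predict(X[300:])
        assert np.corrcoef(preds, y[300:])[0, 1] > 0.99

    def test_null_signal_gives_near_zero_r(self, rng):
        X = rng.standard_normal((800, 10))
        y = rng.standard_normal(800)
        model = fit_random_forest(X[:400], y[:400], ForestSpec(n_trees=150, seed=3))
        r = np.corrcoef(model.predict(X[400:]), y[400:])[0, 1]
        assert abs(r) < 0.15

    def test_seed_reproducibility_and_errors(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        p1 = fit_random_forest(X, y, ForestSpec(n_trees=30, seed=5)).predict(X)
        p2 = fit_random_forest(X, y, ForestSpec(n_trees=30, seed=5)).predict(X)
        np.testing.assert_array_equal(p1, p2)
        with pytest.raises(ModelFitError):
            fit_random_forest(np.zeros((0, 3)), np.zeros(0))
        with pytest.raises(ValueError):
            fit_random_forest(X, y, ForestSpec(mtry=10))


# ---------------------------------------------------------------------------
# stored-weight prediction
# ---------------------------------------------------------------------------

class TestPredictFromWeights:
    def test_zero_weights_give_constant_intercept(self, small_cohort):
        _, panel, _, _ = small_cohort
        from twasbench.predictors import _wrap_linear

        model = _wrap_linear(np.zeros(panel.n_snps), "enet",
                             snp_ids=panel.snp_ids, alt=panel.snps["alt"].to_numpy(),
                             y_mean=1.25)
        np.testing.assert_allclose(predict_from_weights(model, panel), 1.25)

    def test_intersection_matches_manual_dot_product(self, small_cohort):
        _, panel, expr, _ = small_cohort
        from twasbench.crossval import gene_design, train_gene_model

        cis, y = gene_design(panel, expr, "gene0")
        model = train_gene_model("enet", cis.dosages, y, snps=cis.snps,
                                 gene="gene0", seed=1)
        half = cis.subset_snps(np.arange(0, cis.n_snps, 2))
        got = predict_from_weights(model, half)
        keep = np.arange(0, cis.n_snps, 2)
        oracle = model.intercept_dosage + half.dosages @ model.weights_dosage[keep]
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_empty_intersection_signals(self, small_cohort):
        _, panel, expr, _ = small_cohort
        from twasbench.predictors import _wrap_linear

        model = _wrap_linear(np.ones(2), "enet",
                             snp_ids=np.array(["absent1", "absent2"]))
        with pytest.raises(EmptyPanelError):
            predict_from_weights(model, panel)
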