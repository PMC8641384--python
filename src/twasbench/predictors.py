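"""The seven cis-expression prediction methods behind one fit/predict contract.

Methods
-------
ridge / lasso / elastic net
    Penalized least squares with the objective
    ``(y - X b)^2 + lambda * (0.5*(1-alpha)*sum b^2 + alpha*sum |b|)``
    (pure-L2 ridge omits the 1/2 factor; pure-L1 lasso uses ``lambda*sum|b|``).
    Ridge is solved in closed form; the L1-containing objectives map exactly
    onto scikit-learn's coordinate descent via ``alpha_sk = lambda/(2n)``,
    ``l1_ratio = alpha``.
blup
    Polygenic random-effect model ``y = mu + u + e`` with
    ``u ~ N(0, sigma_u^2 G)``, ``G = X X^T / p``; variance components by
    spectral REML, prediction through the cross-relationship matrix.
bslmm
    Spike-and-slab sparse effects plus the polygenic random effect,
    ``y = mu + X b + u + e`` with ``b ~ pi N(0, sigma_a^2/tau) + (1-pi) d0``
    and ``u ~ N(0, sigma_b^2/tau K)``.  Fitted by Metropolis-within-Gibbs:
    inclusion indicators move by add/remove/swap proposals with the sparse
    effects and residual precision integrated out; the hyperparameters
    (pi, PVE, PGE) move by reflected random walks.
random forest
    Bagged regression trees with feature subsampling (scikit-learn ensemble).

All fitters assume the design is column-standardized with training-set
statistics and the phenotype centered; weights are back-transformed to the
dosage scale for storage (see :class:`~twasbench.genio.GeneModel`).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .genio import EmptyPanelError, GeneModel, GenotypePanel
from .heritability import HeritabilityError, RemlFit, make_grm, reml_h2
from .mcmc_diag import TraceSet

logger = logging.getLogger("twasbench")

N_LAMBDA = 100
LAMBDA_EPS = 1e-3
ALPHA_GRID = np.round(np.linspace(0.0, 1.0, 21), 2)  # tuned elastic net


class ModelFitError(RuntimeError):
    """A model could not be fitted (degenerate input, failed variance search)."""


# ---------------------------------------------------------------------------
# standardization and shared plumbing
# ---------------------------------------------------------------------------

def standardize(X: np.ndarray):
    """Column-center and scale to unit variance; constant columns get scale 1
    (their centered values, and hence weights, are exactly zero)."""
    X = np.asarray(X, dtype=float)
    c = X.mean(axis=0)
    s = X.std(axis=0)
    s = np.where(s < 1e-12, 1.0, s)
    return (X - c) / s, c, s


def _wrap_linear(beta, method, lam=np.nan, alpha=np.nan, snp_ids=None,
                 alt=None, gene="", center=None, scale=None, y_mean=0.0,
                 extra=None) -> GeneModel:
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(p)])
    if alt is None:
        alt = np.array(["B"] * p)
    tuning = {"lambda": lam, "alpha": alpha}
    if extra:
        tuning.update(extra)
    return GeneModel(
        gene=gene, method=method, snp_ids=np.asarray(snp_ids), alt=np.asarray(alt),
        weights_std=beta,
        center=np.zeros(p) if center is None else np.asarray(center, dtype=float),
        scale=np.ones(p) if scale is None else np.asarray(scale, dtype=float),
        y_mean=float(y_mean), tuning=tuning,
    )


# ---------------------------------------------------------------------------
# penalized regression
# ---------------------------------------------------------------------------

def lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambda: int = N_LAMBDA, eps: float = LAMBDA_EPS) -> np.ndarray:
    """100 log-spaced penalties from ``lambda_max = 2 max|X'y| / max(alpha, 1e-3)``
    down to ``lambda_max * 1e-3`` (descending)."""
    lam_max = 2.0 * float(np.max(np.abs(X.T @ y), initial=0.0)) / max(alpha, 1e-3)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def ridge_objective(X, y, beta, lam):
    r = y - X @ beta
    return float(r @ r + lam * beta @ beta)


def lasso_objective(X, y, beta, lam):
    r = y - X @ beta
    return float(r @ r + lam * np.abs(beta).sum())


def enet_objective(X, y, beta, lam, alpha):
    r = y - X @ beta
    return float(r @ r + lam * (0.5 * (1 - alpha) * beta @ beta + alpha * np.abs(beta).sum()))


def _ridge_solve(X, y, l2):
    """argmin (y-Xb)^2 + l2 * sum b^2, closed form."""
    p = X.shape[1]
    if l2 == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    A = X.T @ X + l2 * np.eye(p)
    return np.linalg.solve(A, X.T @ y)


def fit_ridge(X, y, lam) -> GeneModel:
    """L2-penalized least squares, objective ``(y-Xb)^2 + lam * sum b^2``."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return _wrap_linear(_ridge_solve(X, y, lam), "ridge", lam=lam, alpha=0.0)


def fit_elastic_net(X, y, lam, alpha) -> GeneModel:
    """Elastic net, objective
    ``(y-Xb)^2 + lam*(0.5*(1-alpha)*sum b^2 + alpha*sum|b|)``.

    ``alpha = 1`` reduces to the lasso; ``alpha = 0`` reduces to ridge with
    L2 weight ``lam/2`` (the printed 1/2 factor on the L2 term).
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if alpha == 0.0 or lam == 0.0:
        beta = _ridge_solve(X, y, lam * 0.5 * (1 - alpha))
    else:
        from sklearn.exceptions import ConvergenceWarning
        from sklearn.linear_model import ElasticNet

        est = ElasticNet(alpha=lam / (2.0 * n), l1_ratio=alpha,
                         fit_intercept=False, max_iter=100_000, tol=1e-8)
        with warnings.catch_warnings():
            # near-zero penalties on p > n designs stop on max_iter; the
            # remaining duality gap is far below the R-scale resolution used
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X, y)
        beta = est.coef_.copy()
    return _wrap_linear(beta, "enet", lam=lam, alpha=alpha)


def fit_lasso(X, y, lam) -> GeneModel:
    """L1-penalized least squares, objective ``(y-Xb)^2 + lam * sum |b|``.

    Coefficients are exactly zero whenever ``lam >= 2 max|X'y|``.
    """
    model = fit_elastic_net(X, y, lam, alpha=1.0)
    model.method = "lasso"
    return model


def enet_coef_path(X, y, lambdas, alpha) -> np.ndarray:
    """Coefficients for a descending penalty grid, shape ``(p, n_lambda)``.

    Warm-started coordinate descent for L1-containing penalties; SVD closed
    form for the pure-L2 limit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    lambdas = np.asarray(lambdas, dtype=float)
    if alpha == 0.0:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        uty = U.T @ y
        # ridge limit of the elastic-net objective: L2 weight lam/2
        shrink = s[:, None] / (s[:, None] ** 2 + lambdas[None, :] / 2.0)
        return Vt.T @ (shrink * uty[:, None])
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import enet_path

    # inputs are package-controlled: skip sklearn's per-call validation and
    # hand over a Fortran-ordered design (order of magnitude faster paths)
    Xf = np.asfortranarray(X, dtype=np.float64)
    yc = np.ascontiguousarray(y, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        _, coefs, _ = enet_path(Xf, yc, l1_ratio=alpha,
                                alphas=lambdas / (2.0 * n), check_input=False)
    return coefs


# ---------------------------------------------------------------------------
# BLUP
# ---------------------------------------------------------------------------

@dataclass
class BlupFit:
    """Fitted polygenic random-effect model on standardized training genotypes."""

    mu: float
    sigma_u2: float
    sigma_e2: float
    h2: float
    alpha: np.ndarray          # sigma_u^2 * V^{-1} (y - mu); prediction kernel weights
    u: np.ndarray              # training random effects G alpha
    X_train: np.ndarray        # standardized training design (for G_new,train)
    p: int
    loglik: float
    converged: bool
    reml: RemlFit = field(repr=False, default=None)

    @property
    def snp_weights_std(self) -> np.ndarray:
        """Equivalent per-SNP weights: X_new w reproduces the kernel prediction."""
        return self.X_train.T @ self.alpha / self.p


def fit_blup(X, y) -> BlupFit:
    """REML variance components and training random effects for the BLUP.

    ``X`` must be column-standardized (training statistics); raises
    :class:`ModelFitError` on a degenerate phenotype.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 1:
        raise ModelFitError("BLUP requires at least one SNP")
    if y.std() < 1e-12:
        raise ModelFitError("phenotype has zero variance")
    G = make_grm(X)
    try:
        reml = reml_h2(y, G, n_snps=p)
    except HeritabilityError as exc:
        raise ModelFitError(str(exc)) from exc
    su2, se2 = reml.sigma_u2, reml.sigma_e2
    V = su2 * G + (se2 + 1e-10 * (su2 + se2)) * np.eye(n)
    c, low = cho_factor(V)
    ones = np.ones(n)
    vi1 = cho_solve((c, low), ones)
    mu = float(vi1 @ y) / float(vi1 @ ones)
    alpha = su2 * cho_solve((c, low), y - mu)
    return BlupFit(mu=mu, sigma_u2=su2, sigma_e2=se2, h2=reml.h2, alpha=alpha,
                   u=G @ alpha, X_train=X, p=p, loglik=reml.loglik,
                   converged=reml.converged and not reml.at_boundary, reml=reml)


def predict_blup(fit: BlupFit, X_new) -> np.ndarray:
    """``y_hat = mu + G_new,train alpha`` with ``G_new,train = X_new X_train^T / p``;
    ``X_new`` standardized with the training statistics."""
    X_new = np.asarray(X_new, dtype=float)
    return fit.mu + (X_new @ fit.X_train.T / fit.p) @ fit.alpha


# ---------------------------------------------------------------------------
# BSLMM
# ---------------------------------------------------------------------------

@dataclass
class BslmmFit:
    """Posterior summaries and hyperparameter traces of one BSLMM run."""

    traces: TraceSet
    pip: np.ndarray            # posterior inclusion probability per SNP
    beta_mean: np.ndarray      # posterior-mean sparse effects (standardized scale)
    w_u: np.ndarray            # per-SNP representation of the polygenic effect
    mu_mean: float
    acceptance: dict
    n_burnin: int
    n_iter: int
    seed: int

    @property
    def weights_std(self) -> np.ndarray:
        return self.beta_mean + self.w_u


def _move_probs(k: int, p: int, kmax: int):
    """(add, remove, swap) proposal probabilities at sparse-set size k."""
    add = 0.4 if k < kmax else 0.0
    rem = 0.4 if k > 0 else 0.0
    swp = 0.2 if 0 < k < p else 0.0
    tot = add + rem + swp
    return add / tot, rem / tot, swp / tot


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
        if span <= 0:
            return lo
    return x


def _derive_variances(pi: float, pve: float, pge: float, p: int):
    """Map (pi, PVE, PGE) to (sigma_a^2, sigma_b^2) on the residual-variance
    scale, assuming unit-variance standardized SNPs and mean diag(K) = 1."""
    v = pve / (1.0 - pve)
    sb2 = max(v * (1.0 - pge), 1e-8)
    sa2 = max(v * pge / (pi * p), 1e-8)
    return sa2, sb2


def _gamma_logml(idx, Gram, Xr1, r1sq, sa2, n, m, c_u):
    """Collapsed log score of an inclusion set: sparse effects and residual
    precision integrated out, polygenic effects conditioned on."""
    k = len(idx)
    if k == 0:
        s = r1sq
        logdet = 0.0
    else:
        ii = np.asarray(idx)
        A = Gram[np.ix_(ii, ii)] + np.eye(k) / sa2
        b = Xr1[ii]
        try:
            c, low = cho_factor(A)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ModelFitError("singular design in sparse-set update") from exc
        Ab = cho_solve((c, low), b)
        s = r1sq - float(b @ Ab)
        logdet = 2.0 * float(np.log(np.diag(c[0] if isinstance(c, tuple) else c)).sum())
    s = max(s, 1e-12)
    return -0.5 * k * math.log(sa2) - 0.5 * logdet - 0.5 * (n + m) * math.log(s + c_u), s


def fit_bslmm(X, y, n_burnin: int = 1000, n_iter: int = 10_000, seed: int | None = None,
              mode: str = "default", n_gamma_moves: int = 10,
              max_gamma: int = 300) -> BslmmFit:
    """Metropolis-within-Gibbs sampler for the Bayesian sparse linear mixed model.

    Parameters
    ----------
    X, y
        Standardized design and centered-or-raw phenotype (the intercept is
        sampled, so centering is not required).
    n_burnin, n_iter
        Burn-in and retained sampling iterations (defaults 1,000 / 10,000).
    seed
        Mandatory: the sampler is bit-reproducible given the seed.
    mode
        ``"default"``; ``"ridge_limit"`` forces every SNP into the sparse set
        (pi = 1) with the polygenic effect disabled — a Bayesian ridge;
        ``"lmm_limit"`` forces the sparse set empty — a pure linear mixed
        model whose predictions approach the BLUP.

    Priors: uniform PVE and PGE on (0,1); log pi uniform on [log(1/p), 0];
    improper 1/tau on the residual precision (the original model's defaults).
    """
    if seed is None:
        raise ValueError("fit_bslmm requires an explicit seed")
    if mode not in ("default", "ridge_limit", "lmm_limit"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3 or p < 1:
        raise ModelFitError("BSLMM needs n >= 3 samples and p >= 1 SNPs")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ModelFitError("non-finite values in BSLMM input")
    kmax = min(p, max_gamma)

    use_u = mode != "ridge_limit"
    if use_u:
        K = make_grm(X)
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0.0, None)
        pos = d > 1e-10
        m = int(pos.sum())
        dpos = d[pos]
    else:
        m = 0

    Gram = X.T @ X
    log_pi_lo = math.log(1.0 / p) if p > 1 else -1e-3
    pi = math.exp(max(log_pi_lo, math.log(0.01))) if mode == "default" else None
    pve, pge = 0.5, 0.5
    if mode == "ridge_limit":
        pi, pge = 1.0, 1.0
        gamma = list(range(p))
    elif mode == "lmm_limit":
        pi, pge = math.exp(log_pi_lo), 0.0
        gamma = []
    else:
        gamma = [int(np.argmax(np.abs(X.T @ (y - y.mean()))))]
    in_gamma = np.zeros(p, dtype=bool)
    in_gamma[gamma] = True

    mu = float(y.mean())
    tau = 1.0 / max(float(y.var()), 1e-12)
    beta = np.zeros(len(gamma))
    ut = np.zeros(m)  # polygenic effect in the GRM eigenbasis (d > 0 components)

    total = n_burnin + n_iter
    tr_pi = np.empty(total)
    tr_pve = np.empty(total)
    tr_pge = np.empty(total)
    beta_sum = np.zeros(p)
    gamma_sum = np.zeros(p)
    ut_sum = np.zeros(m)
    mu_sum = 0.0
    acc = {"gamma_prop": 0, "gamma_acc": 0, "hyper_prop": 0, "hyper_acc": 0}

    sa2, sb2 = _derive_variances(max(pi, 1e-12), pve, max(pge, 1e-12), p)
    fixed_gamma = mode != "default"

    for t in range(total):
        u_full = U[:, pos] @ ut if use_u else 0.0
        r1 = y - mu - u_full
        r1sq = float(r1 @ r1)
        Xr1 = X.T @ r1
        c_u = float(np.sum(ut ** 2 / (sb2 * dpos))) if use_u and m else 0.0

        # -- inclusion-set Metropolis-Hastings (beta, tau integrated out) ----
        cur_ml, cur_s = _gamma_logml(gamma, Gram, Xr1, r1sq, sa2, n, m, c_u)
        if not fixed_gamma:
            log_pi_v, log_1mpi = math.log(pi), math.log1p(-pi) if pi < 1 else 0.0
            for _ in range(n_gamma_moves):
                k = len(gamma)
                padd, prem, pswp = _move_probs(k, p, kmax)
                r = rng.random()
                prop = list(gamma)
                if r < padd:
                    j = int(rng.integers(p - k))
                    cand = np.flatnonzero(~in_gamma)[j]
                    prop.append(int(cand))
                    padd2, prem2, _ = _move_probs(k + 1, p, kmax)
                    log_h = math.log(prem2 / (k + 1)) - math.log(padd / (p - k))
                    d_prior = log_pi_v - log_1mpi
                elif r < padd + prem:
                    j = int(rng.integers(k))
                    cand = prop.pop(j)
                    padd2, _, _ = _move_probs(k - 1, p, kmax)
                    log_h = math.log(padd2 / (p - k + 1)) - math.log(prem / k)
                    d_prior = log_1mpi - log_pi_v
                else:  # swap: symmetric proposal, prior unchanged
                    j = int(rng.integers(k))
                    out = int(rng.integers(p - k))
                    prop[j] = int(np.flatnonzero(~in_gamma)[out])
                    log_h = 0.0
                    d_prior = 0.0
                new_ml, new_s = _gamma_logml(prop, Gram, Xr1, r1sq, sa2, n, m, c_u)
                acc["gamma_prop"] += 1
                if math.log(rng.random() + 1e-300) < new_ml - cur_ml + d_prior + log_h:
                    acc["gamma_acc"] += 1
                    in_gamma[gamma] = False
                    gamma = prop
                    in_gamma[gamma] = True
                    cur_ml, cur_s = new_ml, new_s

        # -- residual precision (sparse effects integrated out) -------------
        tau = rng.gamma(0.5 * (n + m), 2.0 / max(cur_s + c_u, 1e-12))
        if not np.isfinite(tau) or tau <= 0:
            raise ModelFitError("non-finite residual precision in BSLMM chain")

        # -- sparse effects --------------------------------------------------
        k = len(gamma)
        if k:
            ii = np.asarray(gamma)
            A = Gram[np.ix_(ii, ii)] + np.eye(k) / sa2
            c, low = cho_factor(A)
            mean = cho_solve((c, low), Xr1[ii])
            # cho_factor returns upper U with A = U^T U; U^{-1} z has
            # covariance A^{-1}
            dev = solve_triangular(c, rng.standard_normal(k), lower=low)
            beta = mean + dev / math.sqrt(tau)
            Xb = X[:, ii] @ beta
        else:
            beta = np.zeros(0)
            Xb = np.zeros(n)

        # -- polygenic effect (eigenbasis) -----------------------------------
        if use_u and m:
            r2t = U[:, pos].T @ (y - mu - Xb)
            shrink = sb2 * dpos / (sb2 * dpos + 1.0)
            ut = shrink * r2t + rng.standard_normal(m) * np.sqrt(shrink / tau)
            u_full = U[:, pos] @ ut
        else:
            u_full = 0.0

        # -- intercept --------------------------------------------------------
        r3 = y - Xb - u_full
        mu = float(rng.normal(r3.mean(), 1.0 / math.sqrt(n * tau)))

        # -- hyperparameters (pi, PVE, PGE) -----------------------------------
        for _ in range(2):
            acc["hyper_prop"] += 1
            new_pve = _reflect(pve + rng.uniform(-0.05, 0.05), 1e-3, 0.999)
            if mode == "default":
                new_pge = _reflect(pge + rng.uniform(-0.05, 0.05), 1e-3, 0.999)
                new_logpi = _reflect(math.log(pi) + rng.uniform(-0.4, 0.4), log_pi_lo, 0.0)
                new_pi = math.exp(new_logpi)
            else:
                new_pge, new_pi = pge, pi
            nsa2, nsb2 = _derive_variances(max(new_pi, 1e-12), new_pve,
                                           max(new_pge, 1e-12), p)
            delta = 0.0
            k = len(gamma)
            if k:
                bb = float(beta @ beta)
                delta += -0.5 * k * (math.log(nsa2) - math.log(sa2))
                delta += -0.5 * tau * bb * (1.0 / nsa2 - 1.0 / sa2)
            if use_u and m:
                uu = float(np.sum(ut ** 2 / dpos))
                delta += -0.5 * m * (math.log(nsb2) - math.log(sb2))
                delta += -0.5 * tau * uu * (1.0 / nsb2 - 1.0 / sb2)
            if mode == "default":
                delta += k * (math.log(new_pi) - math.log(pi))
                delta += (p - k) * (math.log1p(-new_pi) - math.log1p(-pi)) if p > k else 0.0
            if math.log(rng.random() + 1e-300) < delta:
                acc["hyper_acc"] += 1
                pve, pge, pi = new_pve, new_pge, new_pi
                sa2, sb2 = nsa2, nsb2

        tr_pi[t], tr_pve[t], tr_pge[t] = pi, pve, pge
        if t >= n_burnin:
            if len(gamma):
                beta_sum[np.asarray(gamma)] += beta
                gamma_sum[np.asarray(gamma)] += 1.0
            if use_u and m:
                ut_sum += ut
            mu_sum += mu

    traces = TraceSet(pi=tr_pi[n_burnin:], pve=tr_pve[n_burnin:],
                      pge=tr_pge[n_burnin:], burn_in=n_burnin)
    beta_mean = beta_sum / n_iter
    ut_mean = ut_sum / n_iter
    if use_u and m:
        w_u = X.T @ (U[:, pos] @ (ut_mean / dpos)) / p
    else:
        w_u = np.zeros(p)
    acc_rates = {
        "gamma": acc["gamma_acc"] / max(acc["gamma_prop"], 1),
        "hyper": acc["hyper_acc"] / max(acc["hyper_prop"], 1),
    }
    logger.debug("bslmm acceptance rates: %s", acc_rates)
    return BslmmFit(traces=traces, pip=gamma_sum / n_iter, beta_mean=beta_mean,
                    w_u=w_u, mu_mean=mu_sum / n_iter, acceptance=acc_rates,
                    n_burnin=n_burnin, n_iter=n_iter, seed=seed)


def predict_bslmm(fit: BslmmFit, X_new) -> np.ndarray:
    """Posterior-mean prediction ``mu + X_new beta + u_new``; the polygenic
    part enters through its exact per-SNP representation ``w_u`` (so only
    ``X_new``, standardized with training statistics, is needed)."""
    X_new = np.asarray(X_new, dtype=float)
    return fit.mu_mean + X_new @ fit.weights_std


# ---------------------------------------------------------------------------
# Random Forests
# ---------------------------------------------------------------------------

@dataclass
class ForestSpec:
    """Regression-forest settings: 500 trees, mtry = max(1, p//3), leaves >= 5."""

    n_trees: int = 500
    mtry: int | None = None
    min_node: int = 5
    seed: int = 0


def fit_random_forest(X, y, spec: ForestSpec | None = None) -> GeneModel:
    """Bagged regression trees with per-split feature subsampling; the
    prediction is the average over the forest.  The fitted ensemble is kept
    as an opaque handle (not weight-representable)."""
    from sklearn.ensemble import RandomForestRegressor

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ModelFitError("random forest requires at least one training sample")
    spec = spec or ForestSpec()
    p = X.shape[1]
    mtry = spec.mtry if spec.mtry is not None else max(1, p // 3)
    if not 1 <= mtry <= p:
        raise ValueError(f"mtry must lie in [1, {p}]")
    est = RandomForestRegressor(
        n_estimators=spec.n_trees, max_features=mtry,
        min_samples_leaf=spec.min_node, bootstrap=True,
        random_state=np.random.SeedSequence(spec.seed).generate_state(1)[0] % 2**31,
        n_jobs=1,
    )
    est.fit(X, y)
    model = _wrap_linear(np.zeros(p), "rf", extra={"n_trees": spec.n_trees, "mtry": mtry})
    model.weights_std = None
    model.estimator = est
    model.weight_representable = False
    return model


# ---------------------------------------------------------------------------
# applying stored weights
# ---------------------------------------------------------------------------

def predict_from_weights(model: GeneModel, panel: GenotypePanel) -> np.ndarray:
    """``y_hat = intercept + sum dosage * weight`` over the SNPs shared between
    the weight table and the panel (mismatched alleles and absent SNPs are
    dropped with a logged count)."""
    panel_idx = {s: j for j, s in enumerate(panel.snp_ids)}
    panel_alt = panel.snps["alt"].to_numpy()
    keep_model, keep_panel = [], []
    for i, (s, a) in enumerate(zip(model.snp_ids, model.alt)):
        j = panel_idx.get(s)
        if j is None:
            continue
        if str(panel_alt[j]) != str(a):
            logger.warning("allele mismatch at %s: model %s vs panel %s; dropped",
                           s, a, panel_alt[j])
            continue
        keep_model.append(i)
        keep_panel.append(j)
    n_dropped = len(model.snp_ids) - len(keep_model)
    if n_dropped:
        logger.info("predict_from_weights(%s/%s): dropped %d/%d SNPs absent from panel",
                    model.gene, model.method, n_dropped, len(model.snp_ids))
    if not keep_model:
        raise EmptyPanelError(
            f"no overlap between {model.gene} weights and the target panel"
        )
    w = model.weights_dosage[keep_model]
    D = panel.dosages[:, keep_panel]
    return model.intercept_dosage + D @ w
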