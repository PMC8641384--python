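"""Nested cross-validation engine and the mean-R accuracy metric.

The outer 10-fold loop evaluates prediction performance; the inner 10-fold
loop (penalized methods only) tunes the penalty ``lambda`` — and, for the
tuned elastic net, the mixing weight ``alpha`` — by maximizing the mean
per-inner-fold Pearson R between predicted and observed expression.  A
gene's accuracy is the arithmetic mean of its outer-fold R values.

Variant designs: reduced training fractions (train on ``train_folds`` of the
10 groups, test on the rest), cross-population application (train on all of
population A, tune within A, predict population B), and composition-matched
mixed-population CV.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import (EmptyPanelError, ExpressionPanel, GeneModel, GenotypePanel,
                    extract_cis, qc_filter, CIS_WINDOW, MAF_MIN)
from .predictors import (ALPHA_GRID, ModelFitError, enet_coef_path, fit_blup,
                         fit_bslmm, fit_elastic_net, fit_random_forest,
                         lambda_grid, standardize, ForestSpec, _ridge_solve,
                         _wrap_linear, predict_blup)

logger = logging.getLogger("twasbench")

METHODS = ("ridge", "lasso", "enet", "enet-cv", "blup", "bslmm", "rf")
TUNED_METHODS = ("ridge", "lasso", "enet", "enet-cv")
MIN_TEST_SIZE = 3  # a fold R over fewer samples is undefined; the fold is skipped


# ---------------------------------------------------------------------------
# metric and folds
# ---------------------------------------------------------------------------

def pearson_r(pred, obs) -> float:
    """Pearson correlation between predicted and observed expression.

    Zero-variance predictions return 0 by convention (a constant predictor
    carries no information); negative correlations are preserved.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if pred.size < MIN_TEST_SIZE:
        raise ValueError(f"need at least {MIN_TEST_SIZE} pairs")
    sp, so = pred.std(), obs.std()
    if sp < 1e-12 or so < 1e-12:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def _pearson_columns(P: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """pearson_r of each column of P against obs, with the same zero-variance
    convention (vectorized for penalty paths)."""
    obs_c = obs - obs.mean()
    so = np.sqrt(obs_c @ obs_c)
    Pc = P - P.mean(axis=0)
    sp = np.sqrt((Pc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Pc.T @ obs_c) / (sp * so)
    r[~np.isfinite(r)] = 0.0
    if so < 1e-12:
        r[:] = 0.0
    return r


@dataclass
class FoldAssignment:
    """Seeded partition of n samples into k near-equal folds."""

    fold_of: np.ndarray
    k: int
    seed: int

    def mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold


def make_folds(n: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle then near-equal split; fold sizes differ by at most 1
    and every sample appears in the test set exactly once across folds."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        fold_of[chunk] = f
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


# ---------------------------------------------------------------------------
# inner tuning
# ---------------------------------------------------------------------------

def inner_tune(method: str, X_train, y_train, grid=None, k: int = 10,
               seed: int = 0) -> dict:
    """Choose hyperparameters by k-fold CV inside the training set.

    The score of a grid point is the arithmetic mean over inner folds of the
    Pearson R between its predictions and the held-out expression; ties are
    broken toward the sparser model (larger lambda, then larger alpha).
    Only the penalized methods have an inner loop.
    """
    if method not in TUNED_METHODS:
        raise ValueError(f"method {method!r} has no tunable hyperparameters")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n = X_train.shape[0]
    alphas = {"ridge": (0.0,), "lasso": (1.0,), "enet": (0.5,)}.get(method, tuple(ALPHA_GRID))
    if grid is not None and len(np.atleast_1d(grid)) == 0:
        raise ValueError("empty hyperparameter grid")
    folds = make_folds(n, k, seed)
    Xs_full, _, _ = standardize(X_train)
    yc_full = y_train - y_train.mean()

    best = None  # (score, alpha, lambda)
    for alpha in alphas:
        lambdas = np.asarray(grid, dtype=float) if grid is not None \
            else lambda_grid(Xs_full, yc_full, alpha)
        scores = np.zeros((k, lambdas.size))
        for f in range(k):
            te = folds.mask(f)
            tr = ~te
            if te.sum() < MIN_TEST_SIZE:
                scores[f] = np.nan
                continue
            Xs, _, _ = standardize(X_train[tr])
            ym = y_train[tr].mean()
            coefs = enet_coef_path(Xs, y_train[tr] - ym, lambdas, alpha)
            c = X_train[tr].mean(axis=0)
            s = X_train[tr].std(axis=0)
            s = np.where(s < 1e-12, 1.0, s)
            preds = ym + ((X_train[te] - c) / s) @ coefs
            scores[f] = _pearson_columns(preds, y_train[te])
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_scores = np.nanmean(scores, axis=0)
        if np.isnan(mean_scores).all():
            # training set too small for any inner fold: fall back to the
            # strongest penalty (null model), deterministically
            mean_scores = np.zeros_like(mean_scores)
            logger.warning("inner_tune(%s): no usable inner fold; defaulting to "
                           "the largest penalty", method)
        j = int(np.argmax(mean_scores))  # first max = largest lambda (descending grid)
        cand = (float(mean_scores[j]), float(alpha), float(lambdas[j]))
        if best is None or cand[0] >= best[0]:  # >= : later (larger) alpha wins ties
            best = cand
    return {"alpha": best[1], "lambda": best[2], "score": best[0]}


# ---------------------------------------------------------------------------
# single-gene training front end
# ---------------------------------------------------------------------------

def train_gene_model(method: str, dosages, y, snps: pd.DataFrame | None = None,
                     gene: str = "", seed: int = 0, tune: bool = True,
                     inner_k: int = 10, hyper: dict | None = None,
                     bslmm_burnin: int = 1000, bslmm_iter: int = 10_000,
                     rf_spec: ForestSpec | None = None) -> GeneModel:
    """Standardize a raw dosage design, tune where applicable, and fit.

    ``hyper`` may pin ``{"lambda": ..., "alpha": ...}`` to skip the inner
    loop for penalized methods.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    D = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    Xs, center, scale = standardize(D)
    y_mean = float(y.mean())
    yc = y - y_mean
    snp_ids = snps["id"].to_numpy() if snps is not None else None
    alt = snps["alt"].to_numpy() if snps is not None else None

    if method in TUNED_METHODS:
        if hyper is not None:
            lam, alpha = float(hyper["lambda"]), float(hyper.get("alpha", 0.5))
        elif tune:
            chosen = inner_tune(method, D, y, k=inner_k, seed=seed)
            lam, alpha = chosen["lambda"], chosen["alpha"]
        else:
            alpha = {"ridge": 0.0, "lasso": 1.0, "enet": 0.5, "enet-cv": 0.5}[method]
            lam = float(lambda_grid(Xs, yc, alpha)[N_LAMBDA_DEFAULT // 2])
        if method == "ridge":
            beta = _ridge_solve(Xs, yc, lam)
        else:
            beta = fit_elastic_net(Xs, yc, lam, alpha).weights_std
        model = _wrap_linear(beta, method, lam=lam, alpha=alpha, snp_ids=snp_ids,
                             alt=alt, gene=gene, center=center, scale=scale,
                             y_mean=y_mean)
    elif method == "blup":
        fit = fit_blup(Xs, y)
        model = _wrap_linear(fit.snp_weights_std, "blup", snp_ids=snp_ids, alt=alt,
                             gene=gene, center=center, scale=scale, y_mean=fit.mu,
                             extra={"h2": fit.h2})
    elif method == "bslmm":
        fit = fit_bslmm(Xs, y, n_burnin=bslmm_burnin, n_iter=bslmm_iter, seed=seed)
        model = _wrap_linear(fit.weights_std, "bslmm", snp_ids=snp_ids, alt=alt,
                             gene=gene, center=center, scale=scale, y_mean=fit.mu_mean)
        model.tuning["bslmm_fit"] = fit
    else:  # rf
        spec = rf_spec or ForestSpec(seed=seed)
        if rf_spec is not None and rf_spec.seed == 0:
            spec = ForestSpec(rf_spec.n_trees, rf_spec.mtry, rf_spec.min_node, seed)
        model = fit_random_forest(Xs, y, spec)
        model.gene = gene
        model.center, model.scale = center, scale
        if snp_ids is not None:
            model.snp_ids, model.alt = snp_ids, alt
    return model


N_LAMBDA_DEFAULT = 100


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-gene nested-CV outcome: fold R values and their arithmetic mean."""

    gene: str
    method: str
    fold_rs: np.ndarray
    fold_params: list = field(default_factory=list)
    skipped: np.ndarray | None = None
    fold_rs_secondary: np.ndarray | None = None

    @property
    def mean_r(self) -> float:
        ok = ~np.isnan(self.fold_rs)
        return float(self.fold_rs[ok].mean()) if ok.any() else np.nan

    @property
    def mean_r_secondary(self) -> float:
        if self.fold_rs_secondary is None:
            return np.nan
        ok = ~np.isnan(self.fold_rs_secondary)
        return float(self.fold_rs_secondary[ok].mean()) if ok.any() else np.nan


def nested_cv(method: str, X, y, k: int = 10, train_folds: int = 9, seed: int = 0,
              gene: str = "", y_secondary=None, folds: FoldAssignment | None = None,
              **train_kw) -> CvResult:
    """Nested k-fold cross-validation of one gene.

    Each outer fold trains (with inner tuning for penalized methods) on
    ``train_folds`` of the k groups and evaluates the Pearson R on the
    complementary groups; ``train_folds = 9`` is the standard design and
    ``train_folds = 1`` the reduced-training variant.  Passing a shared
    ``folds`` assignment pairs results across designs.  ``y_secondary``
    scores the same predictions against a second phenotype (cross-tissue
    evaluation).
    """
    if not 1 <= train_folds <= k - 1:
        raise ValueError("train_folds must lie in 1..k-1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if folds is None:
        folds = make_folds(n, k, seed)
    fold_rs = np.full(k, np.nan)
    fold_rs2 = np.full(k, np.nan)
    skipped = np.zeros(k, dtype=bool)
    params: list = []
    for f in range(k):
        groups = [(f + i) % k for i in range(train_folds)]
        tr = np.isin(folds.fold_of, groups)
        te = ~tr
        assert not (tr & te).any()
        if te.sum() < MIN_TEST_SIZE or tr.sum() < MIN_TEST_SIZE:
            skipped[f] = True
            params.append({})
            continue
        fold_seed = (seed * 1_000_003 + f) % 2**31
        try:
            model = train_gene_model(method, X[tr], y[tr], gene=gene,
                                     seed=fold_seed, **train_kw)
        except (ModelFitError, EmptyPanelError) as exc:
            logger.warning("gene %s fold %d (%s): fit failed (%s); fold skipped",
                           gene, f, method, exc)
            skipped[f] = True
            params.append({})
            continue
        preds = model.predict(X[te])
        fold_rs[f] = pearson_r(preds, y[te])
        if y_secondary is not None:
            fold_rs2[f] = pearson_r(preds, np.asarray(y_secondary)[te])
        params.append({kk: vv for kk, vv in model.tuning.items()
                       if kk in ("lambda", "alpha", "h2", "bslmm_fit")})
    return CvResult(gene=gene, method=method, fold_rs=fold_rs, fold_params=params,
                    skipped=skipped,
                    fold_rs_secondary=fold_rs2 if y_secondary is not None else None)


# ---------------------------------------------------------------------------
# panel-level drivers
# ---------------------------------------------------------------------------

def gene_design(panel: GenotypePanel, expr: ExpressionPanel, gene_id: str,
                window: int = CIS_WINDOW, maf_min: float = MAF_MIN):
    """(cis genotype sub-panel after QC, expression vector) for one gene;
    panels must already be sample-aligned."""
    rec = expr.gene_record(gene_id)
    cis = qc_filter(extract_cis(panel, rec, window), maf_min)
    return cis, expr.expression(gene_id)


def cv_all_genes(panel: GenotypePanel, expr: ExpressionPanel, method: str,
                 k: int = 10, train_folds: int = 9, seed: int = 0,
                 expr_secondary: ExpressionPanel | None = None,
                 folds: FoldAssignment | None = None, **train_kw) -> list[CvResult]:
    """Nested CV for every gene of an expression panel; genes whose cis
    window is empty after QC are reported missing (logged), not fatal."""
    results = []
    for gene_id in expr.gene_ids:
        try:
            cis, y = gene_design(panel, expr, gene_id)
        except EmptyPanelError as exc:
            logger.warning("gene %s skipped: %s", gene_id, exc)
            continue
        y2 = expr_secondary.expression(gene_id) if expr_secondary is not None else None
        results.append(
            nested_cv(method, cis.dosages, y, k=k, train_folds=train_folds,
                      seed=seed, gene=gene_id, y_secondary=y2, folds=folds,
                      snps=cis.snps, **train_kw)
        )
    return results


def cross_population_eval(method: str, panel_a: GenotypePanel, expr_a: ExpressionPanel,
                          panel_b: GenotypePanel, expr_b: ExpressionPanel,
                          seed: int = 0, train_fraction: float = 1.0,
                          n_test: int | None = None, inner_k: int = 10,
                          **train_kw) -> pd.DataFrame:
    """Train per-gene models on population A (hyperparameters tuned by k-fold
    CV within A), apply them to population B, and return the per-gene R.

    ``train_fraction`` < 1 and ``n_test`` subsample the two populations to
    match the fold geometry of a within-population CV design.
    """
    rng = np.random.default_rng(seed)
    if train_fraction < 1.0:
        keep = rng.permutation(panel_a.n_samples)[: int(round(train_fraction * panel_a.n_samples))]
        keep.sort()
        panel_a = panel_a.subset_samples(keep)
        expr_a = expr_a.subset_samples(keep)
    if n_test is not None and n_test < panel_b.n_samples:
        keep = rng.permutation(panel_b.n_samples)[:n_test]
        keep.sort()
        panel_b = panel_b.subset_samples(keep)
        expr_b = expr_b.subset_samples(keep)
    rows = []
    shared_genes = [g for g in expr_a.gene_ids if g in set(expr_b.gene_ids)]
    for gene_id in shared_genes:
        try:
            cis_a, y_a = gene_design(panel_a, expr_a, gene_id)
        except EmptyPanelError:
            continue
        rec = expr_b.gene_record(gene_id)
        try:
            cis_b = extract_cis(panel_b, rec)
        except EmptyPanelError:
            continue
        shared = pd.Index(cis_a.snp_ids).intersection(cis_b.snp_ids)
        if len(shared) == 0:
            logger.warning("gene %s: no shared SNPs across populations; skipped", gene_id)
            continue
        ia = pd.Index(cis_a.snp_ids).get_indexer(shared)
        ib = pd.Index(cis_b.snp_ids).get_indexer(shared)
        D_a = cis_a.dosages[:, ia]
        D_b = cis_b.dosages[:, ib]
        model = train_gene_model(method, D_a, y_a, gene=gene_id, seed=seed,
                                 inner_k=inner_k, **train_kw)
        r = pearson_r(model.predict(D_b), expr_b.expression(gene_id))
        rows.append((gene_id, r, len(shared)))
    return pd.DataFrame(rows, columns=["gene", "r", "n_snps"])


def mixed_population_cv(panel: GenotypePanel, expr: ExpressionPanel, n_total: int,
                        method: str, seed: int = 0, k: int = 10,
                        **cv_kw) -> list[CvResult]:
    """Down-sample a merged two-population panel to ``n_total`` preserving the
    population proportions (largest-remainder rounding), then run nested CV."""
    pops = panel.samples["population"]
    if panel.n_samples < n_total:
        raise ValueError("n_total exceeds the merged panel size")
    counts = pops.value_counts()
    exact = counts / counts.sum() * n_total
    take = exact.astype(int)
    rem = n_total - int(take.sum())
    for lab in exact.sub(take).sort_values(ascending=False).index[:rem]:
        take[lab] += 1
    rng = np.random.default_rng(seed)
    keep = []
    for lab, cnt in take.items():
        idx = np.flatnonzero((pops == lab).to_numpy())
        keep.append(rng.permutation(idx)[:cnt])
    keep = np.sort(np.concatenate(keep))
    sub_panel = panel.subset_samples(keep)
    gidx = pd.Index(expr.sample_ids).get_indexer(sub_panel.sample_ids)
    sub_expr = expr.subset_samples(gidx)
    return cv_all_genes(sub_panel, sub_expr, method, k=k, seed=seed, **cv_kw)


def mixed_population_counts(n_by_pop: dict[str, int], n_total: int) -> dict[str, int]:
    """Largest-remainder allocation of ``n_total`` across populations."""
    tot = sum(n_by_pop.values())
    exact = {k: v / tot * n_total for k, v in n_by_pop.items()}
    take = {k: int(v) for k, v in exact.items()}
    rem = n_total - sum(take.values())
    order = sorted(exact, key=lambda k: exact[k] - take[k], reverse=True)
    for lab in order[:rem]:
        take[lab] += 1
    return take


def results_frame(results: list[CvResult]) -> pd.DataFrame:
    """Tidy per-fold table: gene, method, fold, R, mean_R, lambda, alpha."""
    rows = []
    for res in results:
        for f, r in enumerate(res.fold_rs):
            par = res.fold_params[f] if f < len(res.fold_params) else {}
            rows.append((res.gene, res.method, f, r, res.mean_r,
                         par.get("lambda", np.nan), par.get("alpha", np.nan)))
    return pd.DataFrame(rows, columns=["gene", "method", "fold", "R", "mean_R",
                                       "lambda", "alpha"])
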