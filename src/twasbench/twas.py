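"""Gene-level association of imputed expression with a binary trait.

Trained per-gene models are applied to case/control genotype dosages to
impute expression; each gene's imputed expression (standardized, so effect
sizes are comparable across methods) is tested against the trait by
maximum-likelihood logistic regression with no covariates.  Wald z and
two-sided p values are reported along with the Bonferroni threshold
0.05 / (number of genes actually tested).  Perfect separation falls back to
Firth-penalized logistic regression, flagged in the output.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .genio import EmptyPanelError, GeneModel, GenotypePanel
from .predictors import predict_from_weights

logger = logging.getLogger("twasbench")

ALPHA_LEVEL = 0.05


def impute_expression(models: dict[str, GeneModel], gwas_panel: GenotypePanel) -> pd.DataFrame:
    """Per-gene predicted expression on a GWAS panel (samples x genes).

    Genes with no SNP overlap between weight table and panel are reported
    absent (logged), not crashed on.
    """
    cols = {}
    for gene, model in models.items():
        try:
            if model.weight_representable:
                cols[gene] = predict_from_weights(model, gwas_panel)
            else:  # opaque ensemble: needs the model's own SNP columns
                idx = pd.Index(gwas_panel.snp_ids).get_indexer(model.snp_ids)
                if (idx < 0).any():
                    raise EmptyPanelError(f"panel lacks SNPs of {gene} ensemble model")
                cols[gene] = model.predict(gwas_panel.dosages[:, idx])
        except EmptyPanelError as exc:
            logger.warning("gene %s absent from imputed expression: %s", gene, exc)
    return pd.DataFrame(cols, index=gwas_panel.sample_ids)


def _firth_logistic(x: np.ndarray, status: np.ndarray, max_iter: int = 50):
    """Firth-penalized logistic regression of status on (1, x); returns
    (beta, se) for the slope."""
    X = np.column_stack([np.ones_like(x), x])
    b = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ b
        p = expit(eta)
        W = p * (1 - p)
        XWX = X.T @ (W[:, None] * X)
        XWX_inv = np.linalg.inv(XWX)
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], XWX_inv,
                      X * np.sqrt(W)[:, None])
        U = X.T @ (status - p + h * (0.5 - p))
        step = XWX_inv @ U
        b = b + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = X @ b
    p = expit(eta)
    W = p * (1 - p)
    cov = np.linalg.inv(X.T @ (W[:, None] * X))
    return float(b[1]), float(np.sqrt(cov[1, 1]))


def associate(imputed: pd.DataFrame, status) -> pd.DataFrame:
    """Logistic-regression TWAS of every imputed-expression column.

    Returns one row per gene: effect estimate (per SD of imputed
    expression), SE, Wald z, two-sided p, sample counts, and whether the
    gene clears the Bonferroni threshold over the genes actually tested.
    """
    import statsmodels.api as sm

    status = np.asarray(status, dtype=float)
    if imputed.shape[0] != status.size:
        raise ValueError("status length does not match imputed expression rows")
    classes = np.unique(status)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("status must contain both classes coded 0/1")
    n_cases = int(status.sum())
    n_controls = int(status.size - n_cases)
    rows = []
    for gene in imputed.columns:
        x = imputed[gene].to_numpy(dtype=float)
        if x.std() < 1e-12:
            logger.warning("gene %s: constant imputed expression; skipped", gene)
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, "constant"))
            continue
        xs = (x - x.mean()) / x.std()
        flag = "ok"
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(status, sm.add_constant(xs)).fit(disp=0, maxiter=100)
            beta, se = float(fit.params[1]), float(fit.bse[1])
            if not np.isfinite(se) or se > 50:
                raise np.linalg.LinAlgError("unstable SE")
        except Exception:
            beta, se = _firth_logistic(xs, status)
            flag = "firth"
        z = beta / se
        p = 2.0 * norm.sf(abs(z))
        rows.append((gene, beta, se, z, p, flag))
    df = pd.DataFrame(rows, columns=["gene", "beta", "se", "z", "p", "flag"])
    n_tested = int(df["p"].notna().sum())
    df["n_cases"] = n_cases
    df["n_controls"] = n_controls
    df["bonferroni_threshold"] = ALPHA_LEVEL / max(n_tested, 1)
    df["bonferroni_sig"] = df["p"] < df["bonferroni_threshold"]
    return df


def compare_methods(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlation of TWAS z scores across methods, over the
    genes tested by every method."""
    if len(results) < 2:
        raise ValueError("need at least two methods to compare")
    zs = {}
    shared = None
    for method, df in results.items():
        ok = df.dropna(subset=["z"]).set_index("gene")["z"]
        zs[method] = ok
        shared = ok.index if shared is None else shared.intersection(ok.index)
    if shared is None or len(shared) == 0:
        raise ValueError("no genes shared across all methods")
    mat = pd.DataFrame({m: z.loc[shared] for m, z in zs.items()})
    return mat.corr()
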