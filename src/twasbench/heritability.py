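"""GRM construction and spectral REML estimation of cis-heritability.

The model is the single-component mixed model
``y ~ N(mu 1, sigma_u^2 G + sigma_e^2 I)`` with ``G = X X^T / p`` built from
column-standardized cis genotypes.  Writing ``sigma_u^2 = h sigma^2`` and
``sigma_e^2 = (1-h) sigma^2``, the restricted likelihood is a 1-D function of
the heritability ratio ``h`` once G is eigendecomposed; ``sigma^2`` and the
intercept are profiled out in closed form.  ``h`` is maximized on a 50-point
grid followed by bounded Brent refinement; boundary estimates are flagged and
clamped into [0, 1] post hoc.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

H_EPS = 1e-6
N_GRID = 50


class HeritabilityError(ValueError):
    """Degenerate input to variance-component estimation."""


@dataclass
class RemlFit:
    h2: float
    sigma_u2: float
    sigma_e2: float
    loglik: float
    converged: bool
    at_boundary: bool
    n_snps: int


def make_grm(X: np.ndarray) -> np.ndarray:
    """Genetic relationship matrix ``G = X X^T / p`` from standardized genotypes."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise HeritabilityError("GRM requires a samples x SNPs matrix with p >= 1")
    return X @ X.T / X.shape[1]


def _profile_restricted_loglik(h: float, d: np.ndarray, yt: np.ndarray, ot: np.ndarray):
    """Restricted log-likelihood at heritability ratio h, with the overall
    scale and intercept profiled out.  ``d`` are GRM eigenvalues, ``yt``/``ot``
    are y and the all-ones vector rotated into the eigenbasis."""
    n = yt.size
    w = h * d + (1.0 - h)
    iw = 1.0 / w
    oto = float(ot * iw @ ot)
    oty = float(ot * iw @ yt)
    mu = oty / oto
    r = yt - mu * ot
    q = float(r * iw @ r)
    if q <= 0:
        return -np.inf, mu, 0.0
    sigma2 = q / (n - 1)
    ll = -0.5 * ((n - 1) * (np.log(sigma2) + 1.0) + np.log(w).sum() + np.log(oto))
    return ll, mu, sigma2


def reml_h2(y: np.ndarray, G: np.ndarray, d: np.ndarray | None = None,
            U: np.ndarray | None = None, n_snps: int | None = None) -> RemlFit:
    """REML estimate of the fraction of variance attributable to the GRM.

    ``d``/``U`` may carry a precomputed eigendecomposition of G.  Raises
    :class:`HeritabilityError` on (near-)constant phenotypes.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise HeritabilityError("need at least 3 samples")
    if y.std() < 1e-12:
        raise HeritabilityError("phenotype has zero variance")
    if d is None or U is None:
        d, U = np.linalg.eigh(G)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    ot = U.T @ np.ones(n)

    grid = np.linspace(H_EPS, 1.0 - H_EPS, N_GRID)
    lls = np.array([_profile_restricted_loglik(h, d, yt, ot)[0] for h in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, N_GRID - 1)]
    res = minimize_scalar(
        lambda h: -_profile_restricted_loglik(h, d, yt, ot)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": H_EPS},
    )
    h = float(res.x)
    ll, _, sigma2 = _profile_restricted_loglik(h, d, yt, ot)
    at_boundary = h <= 2 * H_EPS or h >= 1.0 - 2 * H_EPS
    if h <= 2 * H_EPS:
        h = 0.0
    elif h >= 1.0 - 2 * H_EPS:
        h = 1.0
    return RemlFit(
        h2=h,
        sigma_u2=h * sigma2,
        sigma_e2=(1.0 - h) * sigma2,
        loglik=float(ll),
        converged=bool(res.success),
        at_boundary=at_boundary,
        n_snps=int(n_snps) if n_snps is not None else G.shape[0],
    )


def reml_h2_from_genotypes(dosages: np.ndarray, y: np.ndarray) -> RemlFit:
    """Convenience wrapper: standardize dosages, build the GRM, run REML."""
    X = np.asarray(dosages, dtype=float)
    c = X.mean(axis=0)
    s = X.std(axis=0)
    s[s < 1e-12] = 1.0
    Xs = (X - c) / s
    return reml_h2(y, make_grm(Xs), n_snps=X.shape[1])
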