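"""Chain-mixing diagnostics for BSLMM hyperparameter traces.

A chain is judged well mixed when its sample autocorrelation at lag 100 lies
strictly inside (-0.1, 0.1); a model is flagged poorly mixed when any of the
three hyperparameter chains (pi, PVE, PGE) fails the rule.  Autocorrelations
are computed on the raw post-burn-in samples, mean-centered and normalized by
the lag-0 variance, with the lag-k sum divided by the number of overlapping
pairs (so an exactly periodic chain scores 1 at a matching lag).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIXING_LAG = 100
MIXING_BOUND = 0.1

#: returned for zero-variance chains; compares as "poor" under the rule
POOR_MIXING_SENTINEL = np.inf


@dataclass
class TraceSet:
    """Post-burn-in hyperparameter chains of one BSLMM run."""

    pi: np.ndarray
    pve: np.ndarray
    pge: np.ndarray
    burn_in: int

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"pi": self.pi, "pve": self.pve, "pge": self.pge}


def autocorrelation(chain, lag: int) -> float:
    """Sample autocorrelation of ``chain`` at the given lag.

    Mean-centered and normalized by the lag-0 variance; the lag-k cross term
    averages over its n-k overlapping pairs.  A zero-variance chain returns
    :data:`POOR_MIXING_SENTINEL`.
    """
    x = np.asarray(chain, dtype=float)
    n = x.size
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if lag >= n:
        raise ValueError(f"lag {lag} >= chain length {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("chain contains non-finite values")
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    if c0 < 1e-30:
        return POOR_MIXING_SENTINEL
    if lag == 0:
        return 1.0
    ck = float(xc[:-lag] @ xc[lag:]) / (n - lag)
    return ck / c0


def is_good_mixing(ac: float, bound: float = MIXING_BOUND) -> bool:
    """Good iff the lag-100 autocorrelation is strictly inside (-bound, bound)."""
    return bool(np.isfinite(ac) and -bound < ac < bound)


def assess_mixing(traces: TraceSet, lag: int = MIXING_LAG) -> dict:
    """Per-hyperparameter good/poor flags plus an overall flag.

    The overall flag is poor when at least one hyperparameter chain mixes
    poorly.
    """
    out: dict[str, bool | float] = {}
    flags = []
    for name, chain in traces.as_dict().items():
        ac = autocorrelation(chain, lag)
        good = is_good_mixing(ac)
        out[f"{name}_autocorr"] = ac
        out[f"{name}_good"] = good
        flags.append(good)
    out["overall_good"] = all(flags)
    return out


def mixing_table(per_gene: dict, lag: int = MIXING_LAG) -> pd.DataFrame:
    """Tidy diagnostics table: gene, fold, hyperparameter, lag autocorr, flag."""
    rows = []
    for (gene, fold), traces in per_gene.items():
        for name, chain in traces.as_dict().items():
            ac = autocorrelation(chain, lag)
            rows.append((gene, fold, name, ac, "good" if is_good_mixing(ac) else "poor"))
    return pd.DataFrame(
        rows, columns=["gene", "fold", "hyperparameter", f"lag{lag}_autocorr", "flag"]
    )
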