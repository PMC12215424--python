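"""Coupling-coordination-degree (CCD) model linking ecosystem services and
tourism urbanization, plus Spearman correlation and decline statistics.

For one city-year and one service, with w ∈ [0,1] the normalized ES value and
u ∈ [0,1] the TU index:

* coupling degree   C = 2·√(w·u / (w+u)²) ∈ [0,1], maximal iff w = u > 0;
* comprehensive index T = α·w + β·u (defaults α = β = 0.5);
* coordination degree D = √(C·T).

D is banded either on the five-level methods scale
(0.2/0.4/0.6/0.8 cuts) or the four-level display scale (0.3/0.5/0.7 cuts);
both labelings are emitted because source conventions differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import (AlignmentError, ConfigurationError, DegenerateIndicatorError,
                     DomainError, UndefinedCouplingError)

LEVELS5 = ("verge of disorder", "passive coordination", "low-level coordination",
           "middle-level coordination", "high-level coordination")
LEVELS4 = ("severely imbalanced", "marginally coordinated",
           "moderately coordinated", "highly coordinated")
_CUTS5 = (0.2, 0.4, 0.6, 0.8)
_CUTS4 = (0.3, 0.5, 0.7)


@dataclass(frozen=True)
class CouplingParams:
    """Subsystem weights in the comprehensive index T = α·w + β·u."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ConfigurationError("alpha and beta must be nonnegative")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ConfigurationError(
                f"alpha + beta must equal 1, got {self.alpha + self.beta}")


def coupling_degree(wi, u):
    """C = 2·√(w·u/(w+u)²); symmetric, 1 iff w = u > 0, 0 if one side is 0."""
    w, v = np.asarray(wi, dtype=float), np.asarray(u, dtype=float)
    if (w < 0).any() or (v < 0).any():
        raise DomainError("coupling inputs must be nonnegative")
    both_zero = (w == 0) & (v == 0)
    if both_zero.any():
        raise UndefinedCouplingError("coupling degree is 0/0 when wi = u = 0")
    c = 2.0 * np.sqrt(w * v) / (w + v)
    return float(c) if c.ndim == 0 else c


def comprehensive_index(wi, u, params: CouplingParams = CouplingParams()):
    """T = α·w + β·u, the weighted development level of the two subsystems."""
    w, v = np.asarray(wi, dtype=float), np.asarray(u, dtype=float)
    if ((w < 0) | (w > 1)).any() or ((v < 0) | (v > 1)).any():
        raise DomainError("comprehensive index inputs must lie in [0, 1]")
    t = params.alpha * w + params.beta * v
    return float(t) if t.ndim == 0 else t


def coupling_coordination(wi, u, params: CouplingParams = CouplingParams()):
    """D = √(C·T).  Returns (c, t, d) as scalars or arrays matching the input."""
    c = coupling_degree(wi, u)
    t = comprehensive_index(wi, u, params)
    d = np.sqrt(np.asarray(c) * np.asarray(t))
    d = float(d) if np.ndim(d) == 0 else d
    return c, t, d


def classify_ccd(d, scheme: str = "five"):
    """Band a coordination degree.  Bands are left-closed/right-open, the last
    band closed, so every d ∈ [0, 1] gets exactly one label."""
    arr = np.asarray(d, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise DomainError("CCD values must lie in [0, 1]")
    if scheme == "five":
        cuts, labels = _CUTS5, LEVELS5
    elif scheme == "four":
        cuts, labels = _CUTS4, LEVELS4
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    idx = np.searchsorted(cuts, arr, side="right")
    out = np.asarray(labels)[idx]
    return str(out) if arr.ndim == 0 else out


def es_normalize(es: pd.Series) -> pd.Series:
    """Min-max an ES series onto [0, 1] over its pooling window (all '+')."""
    x = es.astype(float)
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        raise DegenerateIndicatorError(
            f"ES series {es.name!r} is constant; min-max undefined")
    return (x - lo) / (hi - lo)


def coupling_records(wi: pd.Series, u: pd.Series, es_name: str,
                     params: CouplingParams = CouplingParams()) -> pd.DataFrame:
    """CCD table for one service: index-aligned wi and u Series keyed by
    (city_id, year)."""
    if not wi.index.equals(u.index):
        raise AlignmentError(f"wi and u indices differ for {es_name}")
    c, t, d = coupling_coordination(wi.to_numpy(), u.to_numpy(), params)
    out = pd.DataFrame({"es_name": es_name, "wi": wi.to_numpy(),
                        "u": u.to_numpy(), "c": c, "t": t, "d": d},
                       index=wi.index)
    out["level5"] = classify_ccd(out["d"].to_numpy(), "five")
    out["level4"] = classify_ccd(out["d"].to_numpy(), "four")
    return out.reset_index()


def spearman_matrix(columns: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman ρ with two-sided p-values, long format.

    Ties get average ranks.  Pairs involving a constant column are flagged
    (ρ and p NaN, ``defined`` False) rather than dropped.
    """
    cols = list(columns.columns)
    if len(columns) < 3:
        raise DomainError("Spearman matrix needs at least 3 observations")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            x, y = columns[a].to_numpy(float), columns[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((a, b, np.nan, np.nan, False))
                continue
            if a == b:
                rows.append((a, b, 1.0, 0.0, True))
                continue
            rho, p = spearmanr(x, y)
            rows.append((a, b, float(rho), float(p), True))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p_value",
                                       "defined"])


def ccd_change_stats(records_t0: pd.DataFrame, records_t1: pd.DataFrame) -> dict:
    """Decline share and group moments of D between two record sets.

    Both frames need ``city_id`` and ``d`` columns covering the same cities.
    """
    a = records_t0.set_index("city_id")["d"]
    b = records_t1.set_index("city_id")["d"]
    if set(a.index) != set(b.index):
        raise AlignmentError("record sets cover different city sets")
    b = b.reindex(a.index)
    declining = (b < a).sum()
    return {
        "n_cities": int(len(a)),
        "share_declining_pct": 100.0 * float(declining) / len(a),
        "mean_d_t0": float(a.mean()), "sd_d_t0": float(a.std(ddof=1)),
        "mean_d_t1": float(b.mean()), "sd_d_t1": float(b.std(ddof=1)),
    }
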