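"""Tourism-urbanization composite index.

Pipeline: directional min-max normalization of the 22-indicator city × year
panel → entropy weights (indicators with more cross-unit dispersion, i.e.
lower Shannon entropy, get more weight) → entropy-weighted subsystem scores →
state-space integration, where the TU index is the Euclidean norm of the
(urbanization, tourism, eco-environment) score vector.

Entropy of indicator j over n observation units:
``E_j = −(1/ln n) Σ_i p_ij ln p_ij`` with ``p_ij = r_ij / Σ_i r_ij``;
weights ``ω_j = (1 − E_j) / Σ_j (1 − E_j)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import indicators as ind
from .errors import (ConfigurationError, DegenerateIndicatorError, DomainError)

SUBSYSTEM_COLS = {"tourism": "s_tourism", "urbanization": "s_urban",
                  "eco": "s_eco"}


def panel_to_wide(panel: pd.DataFrame) -> pd.DataFrame:
    """Long panel (city_id, year, indicator_code, value) → wide (rows = city-year)."""
    required = {"city_id", "year", "indicator_code", "value"}
    missing = required - set(panel.columns)
    if missing:
        raise ConfigurationError(f"panel missing columns {sorted(missing)}")
    dup = panel.duplicated(["city_id", "year", "indicator_code"])
    if dup.any():
        raise ConfigurationError("duplicate (city, year, indicator) observations")
    wide = panel.pivot(index=["city_id", "year"], columns="indicator_code",
                       values="value")
    unknown = set(wide.columns) - set(ind.INDICATOR_CODES)
    if unknown:
        raise ConfigurationError(f"unknown indicator codes {sorted(unknown)}")
    return wide[[c for c in ind.INDICATOR_CODES if c in wide.columns]]


def normalize_indicators(panel: pd.DataFrame, pooling: str = "global",
                         epsilon: float = 1e-4) -> pd.DataFrame:
    """Directional min-max onto [ε, 1].

    "+" indicators map x → (x − min)/(max − min); "−" indicators reverse.
    The result is affinely squeezed onto [ε, 1] so every value is strictly
    positive for the entropy logarithm.  ``pooling`` chooses the window over
    which min/max run: all city-years jointly ("global") or within each year
    ("per_year").
    """
    if pooling not in ("global", "per_year"):
        raise ConfigurationError(f"pooling must be 'global' or 'per_year', got {pooling!r}")
    if not 0 < epsilon < 0.5:
        raise ConfigurationError("epsilon must be a small positive number")
    wide = panel if isinstance(panel.index, pd.MultiIndex) else panel_to_wide(panel)

    def _norm(block: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for code in block.columns:
            x = block[code].astype(float)
            lo, hi = x.min(), x.max()
            if hi - lo <= 0:
                raise DegenerateIndicatorError(
                    f"indicator {code} is constant over its pooling window")
            r = (x - lo) / (hi - lo)
            if ind.DIRECTIONS.get(code, "+") == "-":
                r = 1.0 - r
            out[code] = epsilon + (1.0 - epsilon) * r
        return pd.DataFrame(out, index=block.index)

    if pooling == "global":
        return _norm(wide)
    parts = [_norm(g) for _, g in wide.groupby(level="year")]
    return pd.concat(parts).sort_index()


def entropy_weights(normalized: pd.DataFrame) -> pd.Series:
    """Entropy weights over the columns of a strictly positive wide panel."""
    r = normalized.to_numpy(dtype=float)
    n, m = r.shape
    if n < 2:
        raise DomainError("entropy weights need at least 2 observation units")
    if (r <= 0).any():
        raise DomainError("normalized values must be strictly positive")
    p = r / r.sum(axis=0, keepdims=True)
    entropy = -(p * np.log(p)).sum(axis=0) / np.log(n)
    dispersion = 1.0 - entropy
    dispersion = np.clip(dispersion, 0.0, None)   # guard fp just above E=1
    total = dispersion.sum()
    if total <= 0:
        raise DomainError(
            "all indicators are uniform across units; entropy weights undefined "
            "(zero denominator)")
    weights = pd.Series(dispersion / total, index=normalized.columns,
                        name="weight")
    weights.index.name = "indicator_code"
    return weights


def column_entropy(p: np.ndarray) -> float:
    """Shannon entropy E = −(1/ln n)·Σ p ln p of one probability column."""
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise DomainError("probability column must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def subsystem_scores(normalized: pd.DataFrame, weights: pd.Series,
                     renormalize: bool = True) -> pd.DataFrame:
    """Entropy-weighted subsystem scores per city-year.

    With ``renormalize`` (default) weights are rescaled to sum to 1 within
    each subsystem so every axis spans [0, 1]; otherwise global weights are
    used directly and each axis is bounded by its subsystem's weight mass.
    """
    missing = set(normalized.columns) - set(weights.index)
    if missing:
        raise ConfigurationError(f"indicators missing a weight: {sorted(missing)}")
    out = pd.DataFrame(index=normalized.index)
    for sub, col in SUBSYSTEM_COLS.items():
        codes = [c for c in normalized.columns if ind.SUBSYSTEMS.get(c) == sub]
        if not codes:
            out[col] = 0.0
            continue
        w = weights[codes].to_numpy(float)
        if renormalize:
            if w.sum() <= 0:
                raise ConfigurationError(f"subsystem {sub} has zero total weight")
            w = w / w.sum()
        out[col] = normalized[codes].to_numpy(float) @ w
    return out


def tu_state_space(scores: pd.DataFrame, rescale: bool = True) -> pd.DataFrame:
    """TU = ‖(S_urban, S_tourism, S_eco)‖₂; rescaled by √3 onto [0, 1] if asked.

    Returns the input with ``tu_raw`` and (if ``rescale``) ``tu`` columns added.
    """
    cols = list(SUBSYSTEM_COLS.values())
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ConfigurationError(f"scores missing columns {missing}")
    out = scores.copy()
    out["tu_raw"] = np.sqrt((scores[cols].to_numpy(float) ** 2).sum(axis=1))
    if rescale:
        out["tu"] = out["tu_raw"] / np.sqrt(3.0)
    return out


def compute_tu(panel: pd.DataFrame, pooling: str = "global",
               epsilon: float = 1e-4, renormalize: bool = True,
               rescale: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Convenience: panel → (scores table with TU, entropy weights)."""
    normalized = normalize_indicators(panel, pooling=pooling, epsilon=epsilon)
    weights = entropy_weights(normalized)
    scores = subsystem_scores(normalized, weights, renormalize=renormalize)
    return tu_state_space(scores, rescale=rescale), weights


def coefficient_of_variation(values) -> float:
    """Sample standard deviation over mean; scale-free dispersion."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("CV needs at least 2 values")
    mean = x.mean()
    if np.isclose(mean, 0.0):
        raise DomainError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)
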