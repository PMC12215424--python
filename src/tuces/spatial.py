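"""Queen-contiguity spatial weights and global Moran's I with permutation
inference.

Moran's I for zone values x and weights w:

    I = (n / S0) · Σ_ij w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²

with S0 = Σ_ij w_ij.  Binary (unstandardized) weights are the default, so the
printed S0 term is explicit; row standardization is available by flag.  Its
null expectation under random permutation is −1/(n−1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DimensionError, DomainError, ZeroVarianceError
from .raster import Raster


@dataclass
class SpatialWeights:
    """Symmetric zone-adjacency weights with zero diagonal."""

    w: np.ndarray
    ids: tuple[int, ...]
    style: str = "binary"
    islands: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.ids)
        if self.w.shape != (n, n):
            raise DimensionError(f"weights shape {self.w.shape} vs {n} ids")
        if (self.w < 0).any():
            raise ConfigurationError("weights must be nonnegative")
        if np.diagonal(self.w).any():
            raise ConfigurationError("weight matrix diagonal must be zero")
        if self.style == "binary" and not np.allclose(self.w, self.w.T):
            raise ConfigurationError("binary weights must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        return float(self.w.sum())

    def row_standardized(self) -> "SpatialWeights":
        rows = self.w.sum(axis=1, keepdims=True)
        out = np.divide(self.w, rows, out=np.zeros_like(self.w), where=rows > 0)
        return SpatialWeights(out, self.ids, style="row_standardized",
                              islands=self.islands)

    def neighbors(self, zone_id: int) -> list[int]:
        i = self.ids.index(zone_id)
        return [self.ids[j] for j in np.nonzero(self.w[i])[0]]

    def to_adjacency_frame(self) -> pd.DataFrame:
        i, j = np.nonzero(self.w)
        return pd.DataFrame({"zone_i": [self.ids[a] for a in i],
                             "zone_j": [self.ids[b] for b in j],
                             "weight": self.w[i, j]})


@dataclass
class MoranResult:
    """Global Moran's I with its permutation-null summary."""

    i_value: float
    e_i: float
    p_perm: float | None = None
    z_score: float | None = None
    n_perm: int | None = None


def queen_contiguity(zones, contiguity: str = "queen") -> SpatialWeights:
    """Binary contiguity weights from a zone raster or id → polygon mapping.

    Queen: zones neighbor if they share *any* boundary point (edge or corner).
    Rook: only shared edges count.  Island zones (no neighbors) are recorded
    on the result and trigger a warning, not a failure.
    """
    if contiguity not in ("queen", "rook"):
        raise ConfigurationError(f"contiguity must be 'queen' or 'rook', got {contiguity!r}")
    if isinstance(zones, Raster):
        return _contiguity_from_raster(zones, contiguity)
    return _contiguity_from_polygons(zones, contiguity)


def _contiguity_from_raster(zones: Raster, contiguity: str) -> SpatialWeights:
    z = zones.data.astype(int)
    valid = zones.valid_mask
    ids = tuple(int(v) for v in np.unique(z[valid]))
    if len(ids) < 2:
        raise DomainError("contiguity needs at least 2 zones")
    pos = {zid: k for k, zid in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    rows, cols = z.shape
    padded = np.full((rows + 2, cols + 2), -1, dtype=int)
    padded[1:-1, 1:-1] = np.where(valid, z, -1)
    center = padded[1:-1, 1:-1]
    shifts = [(0, 1), (1, 0)]
    if contiguity == "queen":
        shifts += [(1, 1), (1, -1)]
    for dr, dc in shifts:
        nb = padded[1 + dr:rows + 1 + dr, 1 + dc:cols + 1 + dc]
        touch = (center != nb) & (center >= 0) & (nb >= 0)
        for za, zb in {(int(x), int(y)) for x, y in zip(center[touch], nb[touch])}:
            w[pos[za], pos[zb]] = w[pos[zb], pos[za]] = 1.0
    return _finish_weights(w, ids)


def _contiguity_from_polygons(polygons: dict, contiguity: str) -> SpatialWeights:
    ids = tuple(sorted(polygons))
    if len(ids) < 2:
        raise DomainError("contiguity needs at least 2 zones")
    w = np.zeros((len(ids), len(ids)))
    for a in range(len(ids)):
        ga = polygons[ids[a]]
        for b in range(a + 1, len(ids)):
            gb = polygons[ids[b]]
            if not ga.intersects(gb):
                continue
            inter = ga.intersection(gb)
            shared = (not inter.is_empty) if contiguity == "queen" else inter.length > 0
            if shared:
                w[a, b] = w[b, a] = 1.0
    return _finish_weights(w, ids)


def _finish_weights(w: np.ndarray, ids: tuple[int, ...]) -> SpatialWeights:
    islands = tuple(ids[k] for k in np.nonzero(w.sum(axis=1) == 0)[0])
    if islands:
        warnings.warn(f"island zones with no neighbors: {islands}", stacklevel=3)
    return SpatialWeights(w, ids, style="binary", islands=islands)


def expected_morans_null(n: int) -> float:
    """Permutation-null expectation of Moran's I: −1/(n−1)."""
    if n < 2:
        raise DomainError(f"need at least 2 zones, got {n}")
    return -1.0 / (n - 1)


def _moran_statistic(x: np.ndarray, w: np.ndarray, s0: float) -> float:
    dev = x - x.mean()
    denom = float(dev @ dev)
    return float(len(x) / s0 * (dev @ w @ dev) / denom)


def global_morans_i(x, weights: SpatialWeights) -> MoranResult:
    """Global Moran's I statistic (no inference)."""
    arr = np.asarray(x, dtype=float)
    if arr.size != weights.n:
        raise DimensionError(f"{arr.size} values for {weights.n} zones")
    if np.ptp(arr) == 0:
        raise ZeroVarianceError("Moran's I undefined for constant values")
    if weights.s0 <= 0:
        raise ConfigurationError("weights sum S0 must be positive")
    return MoranResult(i_value=_moran_statistic(arr, weights.w, weights.s0),
                       e_i=expected_morans_null(weights.n))


def morans_permutation_test(x, weights: SpatialWeights, n_perm: int = 999,
                            seed: int = 0,
                            alternative: str = "two-sided") -> MoranResult:
    """Permutation inference for Moran's I.

    p_upper = (1 + #{I_perm ≥ I_obs}) / (n_perm + 1); two-sided doubles the
    smaller tail (capped at 1).  Deterministic for a fixed seed.
    """
    if n_perm < 99:
        raise ConfigurationError(f"n_perm must be >= 99, got {n_perm}")
    if alternative not in ("two-sided", "greater", "less"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    result = global_morans_i(x, weights)
    arr = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    w, s0 = weights.w, weights.s0
    for k in range(n_perm):
        sims[k] = _moran_statistic(rng.permutation(arr), w, s0)
    p_up = (1 + np.sum(sims >= result.i_value)) / (n_perm + 1)
    p_lo = (1 + np.sum(sims <= result.i_value)) / (n_perm + 1)
    if alternative == "greater":
        p = p_up
    elif alternative == "less":
        p = p_lo
    else:
        p = min(1.0, 2.0 * min(p_up, p_lo))
    sd = sims.std(ddof=1)
    z = (result.i_value - sims.mean()) / sd if sd > 0 else np.nan
    return MoranResult(i_value=result.i_value, e_i=result.e_i,
                       p_perm=float(p), z_score=float(z), n_perm=n_perm)
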