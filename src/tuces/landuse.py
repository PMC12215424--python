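"""Categorical land-use accounting: reclassification, transition matrices,
composition shares, conversion (Sankey) flows and net change.

All areas are km²; shares are percentages computed at full precision.  Class
order is fixed everywhere as (Cropland, Forest, Grassland, Water Bodies,
Construction, Barren) = codes 1..6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, EmptyDomainError, MappingError
from .raster import (CLASS_CODES, CLASS_NAMES, CODE_TO_NAME, LandUseRaster,
                     Raster)


def reclassify(raw: Raster, mapping: dict[int, int],
               unmapped_to_nodata: bool = False) -> LandUseRaster:
    """Map source codes onto the six-class scheme.

    ``mapping`` must cover every code present in ``raw`` unless
    ``unmapped_to_nodata`` is set, in which case uncovered codes become nodata.
    """
    data = raw.data
    valid = raw.valid_mask
    present = np.unique(data[valid])
    missing = [int(c) for c in present if int(c) not in mapping]
    if missing and not unmapped_to_nodata:
        raise MappingError(f"unmapped land-use codes: {missing}")
    out = np.full(raw.shape, LandUseRaster.nodata, dtype=np.uint8)
    for src, dst in mapping.items():
        if dst not in CLASS_CODES:
            raise MappingError(f"mapping target {dst} is not a legal class code")
        out[valid & (data == src)] = dst
    return LandUseRaster(out, raw.cell_area_km2)


@dataclass
class TransitionMatrix:
    """6×6 area matrix (km²): entry (i, j) = area moving class i → class j."""

    areas: np.ndarray
    t0_year: int | None = None
    t1_year: int | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (6, 6):
            raise DimensionError(f"transition matrix must be 6×6, got {self.areas.shape}")
        if (self.areas < 0).any():
            raise DimensionError("transition areas must be nonnegative")

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.areas, index=list(CLASS_NAMES),
                            columns=list(CLASS_NAMES))


def transition_matrix(lu_t0: LandUseRaster, lu_t1: LandUseRaster) -> TransitionMatrix:
    """Cross-tabulate classes at two timepoints over jointly valid cells."""
    if lu_t0.shape != lu_t1.shape:
        raise DimensionError(f"grids differ: {lu_t0.shape} vs {lu_t1.shape}")
    if not np.isclose(lu_t0.cell_area_km2, lu_t1.cell_area_km2):
        raise DimensionError("cell areas differ between timepoints")
    joint = lu_t0.valid_mask & lu_t1.valid_mask
    a = lu_t0.data[joint].astype(int) - 1
    b = lu_t1.data[joint].astype(int) - 1
    counts = np.bincount(a * 6 + b, minlength=36).reshape(6, 6)
    return TransitionMatrix(counts * lu_t0.cell_area_km2,
                            t0_year=lu_t0.year, t1_year=lu_t1.year)


def composition(lu: LandUseRaster) -> pd.DataFrame:
    """Per-class area (km²) and share (%) over non-nodata cells."""
    valid = lu.valid_mask
    n = int(valid.sum())
    if n == 0:
        raise EmptyDomainError("raster has no valid cells")
    counts = np.bincount(lu.data[valid].astype(int), minlength=7)[1:7]
    area = counts * lu.cell_area_km2
    return pd.DataFrame({
        "class_code": list(CLASS_CODES),
        "class_name": list(CLASS_NAMES),
        "area_km2": area,
        "share_pct": 100.0 * area / area.sum(),
    })


def sankey_flows(tm: TransitionMatrix, exclude_diagonal: bool = True) -> pd.DataFrame:
    """Long-form conversion flows with each flow's share of total converted area."""
    m = tm.areas.copy()
    if exclude_diagonal:
        np.fill_diagonal(m, 0.0)
    total = m.sum()
    if total <= 0:
        raise EmptyDomainError("no converted area (matrix is diagonal)")
    rows = [(CLASS_NAMES[i], CLASS_NAMES[j], m[i, j], 100.0 * m[i, j] / total)
            for i in range(6) for j in range(6) if m[i, j] > 0]
    return pd.DataFrame(rows, columns=["source", "target", "area_km2", "share_pct"])


def inflow_summary(tm: TransitionMatrix, exclude_diagonal: bool = True) -> pd.DataFrame:
    """Converted area flowing *into* each class and its share of all conversion."""
    flows = sankey_flows(tm, exclude_diagonal=exclude_diagonal)
    agg = (flows.groupby("target", sort=False)[["area_km2", "share_pct"]]
           .sum().reindex(list(CLASS_NAMES), fill_value=0.0).reset_index())
    return agg.rename(columns={"target": "class_name"})


def conversion_shares(inflows: dict[str, float] | pd.Series) -> pd.Series:
    """Normalize converted-area inflows to percentage shares summing to 100."""
    s = pd.Series(inflows, dtype=float)
    total = s.sum()
    if total <= 0:
        raise EmptyDomainError("total converted area is zero")
    return 100.0 * s / total


def net_change(tm: TransitionMatrix) -> pd.Series:
    """Signed per-class area change: inflow minus outflow (sums to 0)."""
    net = tm.areas.sum(axis=0) - tm.areas.sum(axis=1)
    return pd.Series(net, index=list(CLASS_NAMES), name="net_change_km2")
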