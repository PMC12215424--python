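"""Minimal raster containers and plain-text grid I/O.

Rasters are 2-D numpy arrays wrapped with a cell area and a nodata sentinel.
Continuous layers use float64 in memory with nodata -9999.0; categorical
land-use layers use uint8 with nodata 255.  On disk both are stored as
ESRI ASCII grids (``.asc``) — a header of six ``key value`` lines followed by
whitespace-separated rows — which keeps every artifact human-readable.

Land use is always the six-class scheme
(1 Cropland, 2 Forest, 3 Grassland, 4 Water Bodies, 5 Construction, 6 Barren).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, DomainError

CONTINUOUS_NODATA = -9999.0
CATEGORICAL_NODATA = 255

CLASS_CODES = (1, 2, 3, 4, 5, 6)
CLASS_NAMES = ("Cropland", "Forest", "Grassland", "Water Bodies",
               "Construction", "Barren")
CODE_TO_NAME = dict(zip(CLASS_CODES, CLASS_NAMES))

CROPLAND, FOREST, GRASSLAND, WATER, CONSTRUCTION, BARREN = CLASS_CODES


@dataclass
class Raster:
    """A single-band grid with uniform square cells.

    Parameters
    ----------
    data
        2-D array of cell values.
    cell_area_km2
        Area of one cell in km²; the cell side is ``sqrt(cell_area_km2)`` km.
    nodata
        Sentinel marking invalid cells.
    """

    data: np.ndarray
    cell_area_km2: float = 1.0
    nodata: float = CONTINUOUS_NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise DimensionError(f"raster data must be 2-D, got {self.data.ndim}-D")
        if not self.cell_area_km2 > 0:
            raise DomainError(f"cell_area_km2 must be > 0, got {self.cell_area_km2}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_size_km(self) -> float:
        return float(np.sqrt(self.cell_area_km2))

    @property
    def valid_mask(self) -> np.ndarray:
        if np.issubdtype(self.data.dtype, np.floating):
            return ~np.isclose(self.data, self.nodata) & ~np.isnan(self.data)
        return self.data != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.data[self.valid_mask]

    def copy_with(self, data: np.ndarray) -> "Raster":
        return Raster(np.asarray(data), self.cell_area_km2, self.nodata)

    def aligned_with(self, other: "Raster") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.cell_area_km2, other.cell_area_km2))


def require_aligned(*rasters: Raster) -> None:
    """Raise :class:`DimensionError` unless all rasters share grid and cell size."""
    first = rasters[0]
    for r in rasters[1:]:
        if not first.aligned_with(r):
            raise DimensionError(
                f"rasters misaligned: {first.shape} @ {first.cell_area_km2} km² "
                f"vs {r.shape} @ {r.cell_area_km2} km²")


@dataclass
class LandUseRaster(Raster):
    """Categorical raster restricted to the six land-use class codes."""

    nodata: int = CATEGORICAL_NODATA
    year: int | None = field(default=None)

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.uint8, copy=False)
        bad = np.setdiff1d(np.unique(self.data),
                           np.array(CLASS_CODES + (self.nodata,), dtype=np.uint8))
        if bad.size:
            raise DomainError(f"illegal land-use codes present: {bad.tolist()}")

    def copy_with(self, data: np.ndarray, year: int | None = None) -> "LandUseRaster":
        return LandUseRaster(np.asarray(data), self.cell_area_km2,
                             year=self.year if year is None else year)


def write_ascii_grid(raster: Raster, path: str | Path, cellsize: float | None = None) -> None:
    """Write an ESRI ASCII grid. Categorical data is written as integers."""
    path = Path(path)
    rows, cols = raster.shape
    cellsize = raster.cell_size_km * 1000.0 if cellsize is None else cellsize
    is_int = np.issubdtype(raster.data.dtype, np.integer)
    header = (f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
              f"cellsize {cellsize}\nNODATA_value {raster.nodata}\n")
    fmt = "%d" if is_int else "%.6f"
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.data, fmt=fmt)


def read_ascii_grid(path: str | Path, categorical: bool = False,
                    year: int | None = None) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    cell_km = header["cellsize"] / 1000.0
    area = cell_km * cell_km
    if categorical:
        return LandUseRaster(data.astype(np.uint8), area, year=year)
    return Raster(data, area, nodata=header.get("nodata_value", CONTINUOUS_NODATA))
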