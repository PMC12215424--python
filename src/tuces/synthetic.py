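"""Seeded synthetic landscapes, climate layers and municipal indicator panels.

The generator emulates the statistical structure the downstream analysis
assumes for a large semi-arid river basin: an east-high/west-low tourism-
urbanization gradient across city zones, Markov land-use change with spatially
clustered construction growth, strictly positive climate and soil layers, and
a 22-indicator city × year yearbook-style panel.  Everything is deterministic
for a fixed :class:`SyntheticConfig` (independent seeded streams per layer, so
e.g. the panel does not change when the land-use sampler is re-run).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import indicators as ind
from .errors import ConfigurationError, DomainError
from .raster import (CLASS_CODES, CONSTRUCTION, LandUseRaster, Raster,
                     require_aligned)

# fixed salts giving each layer its own independent RNG stream
_SALT_ZONES, _SALT_LANDUSE, _SALT_CLIMATE, _SALT_PANEL, _SALT_TRANS = range(5)


def _rng(seed: int, salt: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt, *extra]))


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the synthetic basin.

    Defaults describe the emulated setting: a 60×60 grid of 5 km cells
    (300 × 300 km domain), 12 cities, observation years 2000/2010/2020,
    grassland-dominated composition, and a moderate eastward development
    gradient with lognormal indicator noise.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    cell_area_km2: float = 25.0
    n_cities: int = 12
    years: tuple[int, ...] = (2000, 2010, 2020)
    # grassland-dominated composition, construction & water minor
    class_fractions: tuple[float, ...] = (0.20, 0.12, 0.42, 0.03, 0.05, 0.18)
    transition_rates: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    gradient_strength: float = 1.0
    noise_sd: float = 0.15
    construction_cluster: float = 0.7
    precip_base_mm: float = 450.0
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigurationError("grid_rows/grid_cols must be positive")
        if self.cell_area_km2 <= 0:
            raise ConfigurationError("cell_area_km2 must be positive")
        if not (0 < self.n_cities <= self.grid_rows * self.grid_cols):
            raise ConfigurationError(
                f"n_cities must be in [1, {self.grid_rows * self.grid_cols}]")
        if len(self.years) < 1 or list(self.years) != sorted(set(self.years)):
            raise ConfigurationError("years must be a strictly increasing list")
        frac = np.asarray(self.class_fractions, dtype=float)
        if frac.shape != (6,) or (frac < 0).any() or abs(frac.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "class_fractions must be 6 nonnegative values summing to 1")
        _check_row_stochastic(np.asarray(self.transition_rates, dtype=float))
        if self.gradient_strength < 0:
            raise ConfigurationError("gradient_strength must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.construction_cluster <= 1.0):
            raise ConfigurationError("construction_cluster must be in [0, 1]")
        if self.precip_base_mm <= 0:
            raise ConfigurationError("precip_base_mm must be positive")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


# Row-stochastic 6×6 Markov rates per decade step, rows/cols in class order
# (Cropland, Forest, Grassland, Water, Construction, Barren).  Strong
# diagonals; cropland→construction and barren→grassland are the dominant
# off-diagonal flows, mirroring conversion-to-construction and revegetation.
DEFAULT_TRANSITIONS = np.array([
    [0.900, 0.020, 0.040, 0.002, 0.030, 0.008],   # Cropland
    [0.010, 0.960, 0.025, 0.001, 0.002, 0.002],   # Forest
    [0.030, 0.020, 0.920, 0.002, 0.008, 0.020],   # Grassland
    [0.010, 0.005, 0.010, 0.960, 0.005, 0.010],   # Water
    [0.002, 0.001, 0.002, 0.000, 0.993, 0.002],   # Construction
    [0.010, 0.005, 0.060, 0.002, 0.003, 0.920],   # Barren
])


def _check_row_stochastic(m: np.ndarray) -> None:
    if m.shape != (6, 6):
        raise ConfigurationError(f"transition_rates must be 6×6, got {m.shape}")
    if (m < 0).any():
        raise ConfigurationError("transition_rates must be nonnegative")
    rows = m.sum(axis=1)
    bad = np.where(np.abs(rows - 1.0) > 1e-9)[0]
    if bad.size:
        raise ConfigurationError(
            f"transition_rates rows {bad.tolist()} do not sum to 1 (sums {rows[bad]})")


@dataclass
class LandscapeBundle:
    """All co-registered layers for one synthetic basin."""

    landuse: dict[int, LandUseRaster]          # year -> raster
    precipitation: Raster                      # mm/yr
    pet: Raster                                # mm/yr
    awc: Raster                                # plant-available water, mm
    root_depth: Raster                         # root-restricting depth, mm
    r_factor: Raster                           # rainfall erosivity
    k_factor: Raster                           # soil erodibility
    ls_factor: Raster                          # slope length-steepness
    zones: Raster                              # int zone ids 1..n_cities
    city_easting: pd.Series                    # zone id -> easting in [0, 1]
    config: SyntheticConfig

    def continuous_layers(self) -> dict[str, Raster]:
        return {"precipitation": self.precipitation, "pet": self.pet,
                "awc": self.awc, "root_depth": self.root_depth,
                "r_factor": self.r_factor, "k_factor": self.k_factor,
                "ls_factor": self.ls_factor}


def _zone_layout(config: SyntheticConfig) -> tuple[Raster, pd.Series]:
    """Voronoi tessellation of seeded points → contiguous irregular city zones."""
    rng = _rng(config.seed, _SALT_ZONES)
    rows, cols = config.grid_rows, config.grid_cols
    n = config.n_cities
    # sample distinct seed cells
    flat = rng.choice(rows * cols, size=n, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, (rows, cols))).astype(float)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    d2 = ((rr[..., None] - seeds[:, 0]) ** 2
          + (cc[..., None] - seeds[:, 1]) ** 2)
    zones = d2.argmin(axis=2).astype(np.int32) + 1
    zraster = Raster(zones, config.cell_area_km2, nodata=0)
    # easting = normalized mean column of each zone
    east = pd.Series({z: cc[zones == z].mean() for z in range(1, n + 1)})
    span = east.max() - east.min()
    east = (east - east.min()) / span if span > 0 else east * 0.0
    east.index.name = "city_id"
    east.name = "easting"
    return zraster, east


def zone_polygons(zones: Raster):
    """Dissolve each zone's cells into a shapely polygon (cell side = cell size km)."""
    from shapely import unary_union
    from shapely.geometry import box

    size = zones.cell_size_km
    rows, _ = zones.shape
    out = {}
    for z in np.unique(zones.data[zones.data != zones.nodata]):
        cells = np.argwhere(zones.data == z)
        boxes = [box(c * size, (rows - 1 - r) * size,
                     (c + 1) * size, (rows - r) * size) for r, c in cells]
        out[int(z)] = unary_union(boxes)
    return out


def hargreaves_pet(tmin, tmax, tmean, ra):
    """Hargreaves reference evapotranspiration, mm per day-equivalent of ra.

    PET = 0.0023 · Ra · (Tmean + 17.8) · sqrt(Tmax − Tmin), clamped at 0.
    Inputs are °C rasters/arrays plus extraterrestrial radiation Ra already
    expressed in mm-equivalent; nodata propagates from any input.
    """
    arrays, rasters = [], []
    for x in (tmin, tmax, tmean, ra):
        if isinstance(x, Raster):
            rasters.append(x)
            arrays.append(x.data.astype(float))
        else:
            arrays.append(np.asarray(x, dtype=float))
    if rasters:
        require_aligned(*rasters)
    tn, tx, tm, rad = np.broadcast_arrays(*arrays)
    valid = np.ones(tn.shape, dtype=bool)
    for r, arr in zip((tmin, tmax, tmean, ra), (tn, tx, tm, rad)):
        if isinstance(r, Raster):
            valid &= ~np.isclose(arr, r.nodata)
    if (tx[valid] < tn[valid]).any():
        idx = np.argwhere(valid & (tx < tn))[0]
        raise DomainError(f"tmax < tmin at cell {tuple(int(i) for i in idx)}")
    pet = np.zeros_like(tn, dtype=float)
    pet[valid] = np.maximum(
        0.0023 * rad[valid] * (tm[valid] + 17.8) * np.sqrt(tx[valid] - tn[valid]),
        0.0)
    template = rasters[0] if rasters else None
    if template is not None:
        out = np.full(pet.shape, template.nodata, dtype=float)
        out[valid] = pet[valid]
        return Raster(out, template.cell_area_km2, nodata=template.nodata)
    return pet


def _lognoise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    return np.exp(rng.normal(0.0, sd, size=shape)) if sd > 0 else np.ones(shape)


def generate_landscape(config: SyntheticConfig) -> LandscapeBundle:
    """Build all co-registered synthetic layers for the configured basin."""
    config.validate()
    rows, cols = config.grid_rows, config.grid_cols
    area = config.cell_area_km2
    zones, easting = _zone_layout(config)

    # --- land use: i.i.d. multinomial start, Markov steps between years ---
    rng_lu = _rng(config.seed, _SALT_LANDUSE)
    codes = np.array(CLASS_CODES, dtype=np.uint8)
    lu0 = rng_lu.choice(codes, size=(rows, cols),
                        p=np.asarray(config.class_fractions, dtype=float))
    years = list(config.years)
    landuse = {years[0]: LandUseRaster(lu0, area, year=years[0])}
    rates = np.asarray(config.transition_rates, dtype=float)
    for k in range(1, len(years)):
        prev = landuse[years[k - 1]]
        seed_k = int(_rng(config.seed, _SALT_TRANS, k).integers(2**31))
        nxt = apply_transition_model(prev, rates, seed_k)
        if config.construction_cluster > 0:
            nxt = _cluster_construction(prev, nxt, config.construction_cluster,
                                        _rng(config.seed, _SALT_TRANS, k, 1))
        nxt.year = years[k]
        landuse[years[k]] = nxt

    # --- climate & soil layers: gradient × lognormal noise, strictly > 0 ---
    rng_cl = _rng(config.seed, _SALT_CLIMATE)
    east_cell = (np.tile(np.arange(cols), (rows, 1)) / max(cols - 1, 1))
    g = config.gradient_strength
    sd = config.noise_sd

    def layer(base: float, grad: float = 0.0) -> Raster:
        data = base * (1.0 + grad * east_cell) * _lognoise(rng_cl, (rows, cols), sd)
        return Raster(data, area)

    precip = layer(config.precip_base_mm, grad=0.4 * g)  # wetter east
    tmean = 8.0 + 4.0 * g * east_cell + (rng_cl.normal(0, sd, (rows, cols)) if sd > 0 else 0)
    trange = np.full((rows, cols), 9.0)
    ra = np.full((rows, cols), 14.0)
    pet_daily = hargreaves_pet(tmean - trange / 2, tmean + trange / 2, tmean, ra)
    pet = Raster(np.maximum(pet_daily, 1e-6) * 365.0, area)
    awc = layer(120.0)
    root_depth = layer(1800.0)
    r_factor = layer(1500.0, grad=0.2 * g)
    k_factor = layer(0.035)
    ls_factor = layer(2.2)

    return LandscapeBundle(landuse=landuse, precipitation=precip, pet=pet,
                           awc=awc, root_depth=root_depth, r_factor=r_factor,
                           k_factor=k_factor, ls_factor=ls_factor, zones=zones,
                           city_easting=easting, config=config)


def apply_transition_model(lu_t0: LandUseRaster, transition_rates: np.ndarray,
                           seed: int) -> LandUseRaster:
    """One Markov step: each cell's next class is sampled from its row.

    Nodata cells are preserved; the empirical transition frequencies converge
    to ``transition_rates`` as the number of cells per source class grows.
    """
    rates = np.asarray(transition_rates, dtype=float)
    _check_row_stochastic(rates)
    rng = np.random.default_rng(seed)
    out = lu_t0.data.copy()
    valid = lu_t0.valid_mask
    cum = rates.cumsum(axis=1)
    u = rng.random(lu_t0.shape)
    src = lu_t0.data.astype(int) - 1
    # inverse-CDF draw per cell, vectorized over the 6 rows
    for i in range(6):
        cells = valid & (src == i)
        if cells.any():
            out[cells] = 1 + np.searchsorted(cum[i], u[cells], side="right").clip(max=5)
    return LandUseRaster(out, lu_t0.cell_area_km2, year=lu_t0.year)


def _cluster_construction(prev: LandUseRaster, nxt: LandUseRaster,
                          mixing: float, rng: np.random.Generator) -> LandUseRaster:
    """Relocate a share of newly converted construction cells next to existing ones.

    Swaps sampled outcomes between cell pairs of the same source class, so all
    class counts and empirical transition frequencies are exactly preserved —
    only *where* conversion lands changes.
    """
    out = nxt.data.copy()
    existing = prev.data == CONSTRUCTION
    # queen-neighborhood of existing construction
    adj = np.zeros(prev.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            adj |= np.roll(np.roll(existing, dr, axis=0), dc, axis=1)
    new_con = np.argwhere((out == CONSTRUCTION) & ~existing & prev.valid_mask)
    for r, c in new_con:
        if rng.random() >= mixing or adj[r, c]:
            continue
        src = prev.data[r, c]
        # candidate: same source class, adjacent to construction, unchanged outcome
        cand = np.argwhere(adj & (prev.data == src) & (out == src))
        if cand.size == 0:
            continue
        r2, c2 = cand[rng.integers(len(cand))]
        out[r, c], out[r2, c2] = out[r2, c2], out[r, c]
    return LandUseRaster(out, nxt.cell_area_km2, year=nxt.year)


def generate_indicator_panel(config: SyntheticConfig) -> pd.DataFrame:
    """City × year × 22-indicator panel with the imposed eastward gradient.

    Model per indicator j, city i, year step k:
    ``value = baseline_j · gradient_factor(easting_i) · trend_j^k · exp(ε)``,
    ε ~ N(0, noise_sd²).  "+" indicators rise with easting, "−" indicators
    (industrial pressures) fall; all values are strictly positive.
    """
    config.validate()
    _, easting = _zone_layout(config)
    rng = _rng(config.seed, _SALT_PANEL)
    g, sd = config.gradient_strength, config.noise_sd
    rows = []
    for code, meta in ind.INDICATORS.iterrows():
        for k, year in enumerate(config.years):
            trend = float(meta["decade_trend"]) ** k
            for city_id, e in easting.items():
                grad = 1.0 + g * (e if meta["direction"] == "+" else 1.0 - e)
                noise = np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0
                rows.append((int(city_id), int(year), code,
                             float(meta["baseline"]) * grad * trend * noise))
    panel = pd.DataFrame(rows, columns=["city_id", "year", "indicator_code", "value"])
    return panel.sort_values(["year", "city_id", "indicator_code"],
                             ignore_index=True)
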