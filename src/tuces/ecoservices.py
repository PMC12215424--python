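"""InVEST-style ecosystem-service models on co-registered rasters.

Four services, each a simplified but faithful annual formulation:

* water yield — Budyko–Zhang curve: AET/P = 1 + PET/P − (1 + (PET/P)^ω)^(1/ω)
  with ω = z·S/P + 1.25, S the plant-available storage min(AWC, root depth);
  non-vegetated classes evaporate min(PET, P);
* soil conservation — RUSLE retention R·K·LS·(1 − C·P), no sediment routing;
* habitat quality — threat-decay degradation with half-saturation response
  Q = H·(1 − D^z/(D^z + k^z));
* carbon storage — four-pool (above, below, soil, dead) per-class lookup.

Plus zonal aggregation, annualized change rates, and Mann–Kendall trend
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import norm

from .errors import (ConfigurationError, DimensionError, DomainError)
from .raster import (CLASS_CODES, CLASS_NAMES, LandUseRaster, Raster,
                     require_aligned)

#: classes treated as vegetated in the Budyko water-yield branch
VEGETATED_CLASSES = (1, 2, 3)   # Cropland, Forest, Grassland

BIOPHYSICAL_COLUMNS = ["class_code", "class_name", "c_above", "c_below",
                       "c_soil", "c_dead", "habitat", "cover_C", "practice_P"]


@dataclass
class BiophysicalTable:
    """Per-class biophysical parameters (carbon pools t/ha, H, C, P factors)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = set(BIOPHYSICAL_COLUMNS) - set(t.columns)
        if missing:
            raise ConfigurationError(f"biophysical table missing columns {sorted(missing)}")
        if sorted(t["class_code"]) != list(CLASS_CODES):
            raise ConfigurationError(
                f"biophysical table must have one row per class code 1..6, "
                f"got {sorted(t['class_code'])}")
        pools = t[["c_above", "c_below", "c_soil", "c_dead"]].to_numpy(float)
        if (pools < 0).any():
            raise ConfigurationError("carbon pools must be nonnegative")
        for col in ("habitat", "cover_C", "practice_P"):
            v = t[col].to_numpy(float)
            if ((v < 0) | (v > 1)).any():
                raise ConfigurationError(f"{col} must lie in [0, 1]")
        self.table = t.set_index("class_code").sort_index()

    def lookup(self, column: str) -> np.ndarray:
        """Values of ``column`` indexed so that position code-1 holds class code."""
        return self.table[column].to_numpy(float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiophysicalTable":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "BiophysicalTable":
        """Plausible per-class parameters for a semi-arid temperate basin."""
        rows = [
            # code, name, c_above, c_below, c_soil, c_dead, H, C, P
            (1, "Cropland",     8.0,  4.0,  60.0, 1.0, 0.40, 0.25, 0.60),
            (2, "Forest",      60.0, 15.0,  90.0, 5.0, 1.00, 0.02, 1.00),
            (3, "Grassland",   12.0, 10.0,  75.0, 2.0, 0.80, 0.08, 1.00),
            (4, "Water Bodies", 0.0,  0.0,   0.0, 0.0, 0.90, 0.00, 1.00),
            (5, "Construction", 2.0,  1.0,  25.0, 0.0, 0.00, 0.00, 1.00),
            (6, "Barren",       1.0,  1.0,  30.0, 0.0, 0.30, 0.45, 1.00),
        ]
        return cls(pd.DataFrame(rows, columns=BIOPHYSICAL_COLUMNS))


@dataclass
class ThreatSpec:
    """One degradation source for the habitat-quality model.

    ``sensitivity`` maps class code → S ∈ [0, 1]; ``decay`` is "linear"
    (1 − d/d_max) or "exponential" (exp(−2.99·d/d_max)), zero beyond d_max.
    """

    name: str
    raster: Raster                    # presence/intensity in [0, 1]
    max_dist_km: float
    weight: float = 1.0
    decay: str = "linear"
    sensitivity: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_dist_km <= 0:
            raise ConfigurationError(f"threat {self.name}: max_dist_km must be > 0")
        if not (0.0 <= self.weight <= 1.0):
            raise ConfigurationError(f"threat {self.name}: weight must be in [0, 1]")
        if self.decay not in ("linear", "exponential"):
            raise ConfigurationError(f"threat {self.name}: unknown decay {self.decay!r}")
        for code, s in self.sensitivity.items():
            if not (0.0 <= s <= 1.0):
                raise ConfigurationError(
                    f"threat {self.name}: sensitivity[{code}] must be in [0, 1]")


def construction_threat(lulc: LandUseRaster, max_dist_km: float = 10.0,
                        weight: float = 1.0, decay: str = "linear") -> ThreatSpec:
    """Default threat layer: presence of Construction cells degrading habitat."""
    intensity = (lulc.data == 5).astype(float)
    return ThreatSpec(
        name="construction",
        raster=Raster(intensity, lulc.cell_area_km2),
        max_dist_km=max_dist_km, weight=weight, decay=decay,
        sensitivity={1: 0.5, 2: 0.8, 3: 0.6, 4: 0.7, 5: 0.0, 6: 0.3})


# ---------------------------------------------------------------- water yield

def water_yield(p: Raster, pet: Raster, awc: Raster, root_depth: Raster,
                lulc: LandUseRaster, z_param: float = 3.0) -> Raster:
    """Budyko–Zhang annual water yield (mm): WY = (1 − AET/P)·P.

    ω = z_param·S/P + 1.25 with storage S = min(AWC, root-restricting depth)
    in mm.  Water Bodies, Construction and Barren cells bypass the curve and
    lose min(PET, P) to evaporation.
    """
    require_aligned(p, pet, awc, root_depth, lulc)
    valid = (p.valid_mask & pet.valid_mask & awc.valid_mask
             & root_depth.valid_mask & lulc.valid_mask)
    pv = p.data.astype(float)
    if (pv[valid] <= 0).any():
        idx = np.argwhere(valid & (pv <= 0))[0]
        raise DomainError(f"nonpositive precipitation at cell {tuple(int(i) for i in idx)}")
    out = np.full(p.shape, p.nodata, dtype=float)
    petv = pet.data.astype(float)
    storage = np.minimum(awc.data.astype(float), root_depth.data.astype(float))
    veg = valid & np.isin(lulc.data, VEGETATED_CLASSES)
    non = valid & ~np.isin(lulc.data, VEGETATED_CLASSES)

    phi = np.zeros_like(pv)
    np.divide(petv, pv, out=phi, where=valid)
    omega = np.ones_like(pv)
    np.divide(z_param * storage, pv, out=omega, where=valid)
    omega += 1.25
    aet_ratio = 1.0 + phi - (1.0 + phi ** omega) ** (1.0 / omega)
    out[veg] = np.clip((1.0 - aet_ratio[veg]) * pv[veg], 0.0, pv[veg])
    out[non] = pv[non] - np.minimum(petv[non], pv[non])
    return Raster(out, p.cell_area_km2, nodata=p.nodata)


# ---------------------------------------------------------- soil conservation

def soil_conservation(r: Raster, k: Raster, ls: Raster, lulc: LandUseRaster,
                      bio: BiophysicalTable) -> Raster:
    """RUSLE retention SC = R·K·LS·(1 − C·P) in t/ha/yr, locally (no routing)."""
    require_aligned(r, k, ls, lulc)
    for name, rast in (("R", r), ("K", k), ("LS", ls)):
        if (rast.data[rast.valid_mask] < 0).any():
            raise DomainError(f"{name} factor contains negative values")
    cp = bio.lookup("cover_C") * bio.lookup("practice_P")
    if (cp > 1.0 + 1e-12).any():
        raise ConfigurationError("C_f·P_f exceeds 1 for some class (table corruption)")
    valid = r.valid_mask & k.valid_mask & ls.valid_mask & lulc.valid_mask
    out = np.full(r.shape, r.nodata, dtype=float)
    cls = lulc.data[valid].astype(int) - 1
    out[valid] = (r.data[valid] * k.data[valid] * ls.data[valid]
                  * (1.0 - cp[cls]))
    return Raster(out, r.cell_area_km2, nodata=r.nodata)


# ------------------------------------------------------------ habitat quality

def _decay_kernel(threat: ThreatSpec, cell_km: float) -> np.ndarray:
    radius = int(np.floor(threat.max_dist_km / cell_km))
    offs = np.arange(-radius, radius + 1)
    d = np.hypot(offs[:, None], offs[None, :]) * cell_km
    if threat.decay == "linear":
        kern = np.clip(1.0 - d / threat.max_dist_km, 0.0, None)
    else:
        kern = np.exp(-2.99 * d / threat.max_dist_km)
    kern[d > threat.max_dist_km] = 0.0
    return kern


def habitat_degradation(lulc: LandUseRaster, threats: list[ThreatSpec]) -> Raster:
    """Total degradation D per cell: Σ_r (w_r/Σw)·Σ_y intensity_y·decay(d)·S_class."""
    out = np.zeros(lulc.shape, dtype=float)
    if not threats:
        return Raster(out, lulc.cell_area_km2)
    wsum = sum(t.weight for t in threats)
    if wsum <= 0:
        raise ConfigurationError("threat weights sum to zero")
    cell_km = lulc.cell_size_km
    sens_stack = np.zeros(lulc.shape, dtype=float)
    for threat in threats:
        if threat.raster.shape != lulc.shape:
            raise DimensionError(
                f"threat {threat.name} raster {threat.raster.shape} does not "
                f"match land use {lulc.shape}")
        intensity = np.where(threat.raster.valid_mask, threat.raster.data, 0.0)
        kern = _decay_kernel(threat, cell_km)
        exposure = fftconvolve(intensity, kern, mode="same")
        exposure = np.clip(exposure, 0.0, None)      # fft round-off
        sens = np.zeros(7)
        for code in CLASS_CODES:
            sens[code] = threat.sensitivity.get(code, 0.0)
        sens_stack = sens[lulc.data.astype(int).clip(0, 6)]
        out += (threat.weight / wsum) * exposure * sens_stack
    out[~lulc.valid_mask] = 0.0
    return Raster(out, lulc.cell_area_km2)


def habitat_quality(lulc: LandUseRaster, threats: list[ThreatSpec],
                    bio: BiophysicalTable, k_half: float = 0.5,
                    z_exp: float = 2.5) -> Raster:
    """Q = H_class · (1 − D^z / (D^z + k_half^z)), in [0, 1]."""
    if k_half <= 0:
        raise ConfigurationError("k_half must be > 0")
    deg = habitat_degradation(lulc, threats).data
    h = bio.lookup("habitat")
    out = np.full(lulc.shape, -9999.0, dtype=float)
    valid = lulc.valid_mask
    cls = lulc.data[valid].astype(int) - 1
    dz = deg[valid] ** z_exp
    out[valid] = h[cls] * (1.0 - dz / (dz + k_half ** z_exp))
    return Raster(out, lulc.cell_area_km2)


# -------------------------------------------------------------- carbon storage

def carbon_storage(lulc: LandUseRaster, bio: BiophysicalTable) -> Raster:
    """Total carbon density (t/ha): sum of the four pools of the cell's class."""
    pools = (bio.lookup("c_above") + bio.lookup("c_below")
             + bio.lookup("c_soil") + bio.lookup("c_dead"))
    out = np.full(lulc.shape, -9999.0, dtype=float)
    valid = lulc.valid_mask
    out[valid] = pools[lulc.data[valid].astype(int) - 1]
    return Raster(out, lulc.cell_area_km2)


# ------------------------------------------------------------ zonal statistics

def zonal_summary(value: Raster, zones: Raster, stat: str = "mean") -> pd.Series:
    """Aggregate a continuous raster over integer zones (nodata excluded).

    Zones containing no valid value cell get NaN (flagged missing, not zero).
    """
    if stat not in ("mean", "sum"):
        raise ConfigurationError(f"stat must be 'mean' or 'sum', got {stat!r}")
    if value.shape != zones.shape:
        raise DimensionError(f"value {value.shape} vs zones {zones.shape}")
    zdata = zones.data.astype(int)
    zone_ids = np.unique(zdata[zones.valid_mask])
    valid = value.valid_mask & zones.valid_mask
    z, v = zdata[valid], value.data[valid].astype(float)
    top = int(zone_ids.max()) + 1 if zone_ids.size else 1
    sums = np.bincount(z, weights=v, minlength=top)
    counts = np.bincount(z, minlength=top)
    out = {}
    for zid in zone_ids:
        if counts[zid] == 0:
            out[int(zid)] = np.nan
        elif stat == "mean":
            out[int(zid)] = sums[zid] / counts[zid]
        else:
            out[int(zid)] = sums[zid]
    s = pd.Series(out, name=stat)
    s.index.name = "zone"
    return s


# ------------------------------------------------------- change & trend rates

def annualized_change(es_t0, es_t1, span_years: int):
    """Elementwise (ES_t1 − ES_t0) / span, units per year."""
    if span_years <= 0:
        raise DomainError(f"span_years must be > 0, got {span_years}")
    if isinstance(es_t0, Raster) and isinstance(es_t1, Raster):
        require_aligned(es_t0, es_t1)
        valid = es_t0.valid_mask & es_t1.valid_mask
        out = np.full(es_t0.shape, es_t0.nodata, dtype=float)
        out[valid] = (es_t1.data[valid] - es_t0.data[valid]) / span_years
        return Raster(out, es_t0.cell_area_km2, nodata=es_t0.nodata)
    a, b = np.asarray(es_t0, dtype=float), np.asarray(es_t1, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"shapes differ: {a.shape} vs {b.shape}")
    rate = (b - a) / span_years
    if isinstance(es_t0, pd.Series):
        return pd.Series(rate, index=es_t0.index, name="rate_per_yr")
    return rate


def percent_change(es_t0: float, es_t1: float) -> float:
    """Relative change (ES_t1 − ES_t0)/ES_t0 × 100."""
    if es_t0 == 0:
        raise DomainError("percent change undefined for zero baseline")
    return 100.0 * (es_t1 - es_t0) / es_t0


def mann_kendall(series) -> tuple[int, float, float]:
    """Mann–Kendall trend test: returns (S, z, two-sided p).

    Normal approximation with tie correction and continuity correction;
    intended for short annual/decadal series (n ≥ 4).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise DomainError("Mann–Kendall needs at least 2 observations")
    s = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())
    _, tie_counts = np.unique(x, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5)
           - sum(t * (t - 1) * (2 * t + 5) for t in tie_counts if t > 1)) / 18.0
    if var == 0:
        return s, 0.0, 1.0
    z = (s - np.sign(s)) / np.sqrt(var) if s != 0 else 0.0
    p = 2.0 * norm.sf(abs(z))
    return s, float(z), float(min(p, 1.0))


def trend_classification(rates, threshold: float = 0.0, series=None,
                         alpha: float = 0.05) -> pd.Series:
    """Classify each zone as increase / decrease / no significant change.

    With a per-zone series of ≥4 timepoints, significance comes from a
    two-sided Mann–Kendall test at ``alpha`` and the sign of the rate gives
    direction.  With fewer timepoints, |rate| ≤ threshold means no change.
    """
    if threshold < 0:
        raise DomainError("threshold must be >= 0")
    r = pd.Series(rates, dtype=float)
    if r.empty:
        raise DomainError("empty rate series")
    labels = {}
    for key, rate in r.items():
        seq = None if series is None else np.asarray(series[key], dtype=float)
        if seq is not None and seq.size >= 4:
            _, _, p = mann_kendall(seq)
            significant = p < alpha and rate != 0
        else:
            significant = abs(rate) > threshold
        if not significant:
            labels[key] = "no significant change"
        else:
            labels[key] = "increase" if rate > 0 else "decrease"
    return pd.Series(labels, name="trend")
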