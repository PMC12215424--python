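"""End-to-end orchestration: simulate → ecosystem services → TU index →
CCD → spatial statistics, from a single YAML-able run configuration.

Every stage writes plain-text artifacts (CSV tables, .asc rasters, GeoJSON
zones) into the output directory and the run manifest records the config
hash, seed and package versions, so a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import coupling as cp
from . import ecoservices as es
from . import landuse as lu
from . import spatial as sp
from . import tu as tu_mod
from .errors import ConfigurationError
from .indicators import INDICATOR_CODES
from .raster import CLASS_CODES, write_ascii_grid
from .synthetic import (LandscapeBundle, SyntheticConfig, generate_indicator_panel,
                        generate_landscape, zone_polygons)

log = logging.getLogger("tuces")

ES_NAMES = ("WY", "SC", "HQ", "CS")


@dataclass
class RunConfig:
    """All knobs for one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    z_param: float = 3.0            # Budyko seasonality constant
    k_half: float = 0.5             # habitat-quality half-saturation
    z_exp: float = 2.5              # habitat-quality response exponent
    threat_max_dist_km: float = 10.0
    threat_decay: str = "linear"
    epsilon: float = 1e-4           # normalization floor before the entropy log
    alpha: float = 0.5              # CCD weight on the ES side
    beta: float = 0.5               # CCD weight on the TU side
    pooling: str = "global"
    rescale: bool = True
    renormalize_subsystems: bool = True
    n_perm: int = 999
    write_rasters: bool = False
    write_zones_geojson: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        return cls(synthetic=syn, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["transition_rates"] = np.asarray(
            self.synthetic.transition_rates).tolist()
        d["synthetic"]["years"] = list(self.synthetic.years)
        d["synthetic"]["class_fractions"] = list(self.synthetic.class_fractions)
        return d

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, synthetic=self.synthetic.with_seed(seed))

    def validate(self) -> None:
        self.synthetic.validate()
        if self.z_param <= 0:
            raise ConfigurationError("z_param must be > 0")
        if self.k_half <= 0:
            raise ConfigurationError("k_half must be > 0")
        if not 0 < self.epsilon < 0.5:
            raise ConfigurationError("epsilon must be a small positive number")
        cp.CouplingParams(self.alpha, self.beta)
        if self.pooling not in ("global", "per_year"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")
        if self.n_perm < 99:
            raise ConfigurationError("n_perm must be >= 99")


@dataclass
class ResultBundle:
    """All tables produced by one run, plus the provenance manifest."""

    es_table: pd.DataFrame          # city_id, year, wy_mm, sc_t_ha, hq, cs_t_ha
    tu_table: pd.DataFrame          # city_id, year, subsystem scores, tu
    weights: pd.Series              # indicator_code -> entropy weight
    ccd_table: pd.DataFrame         # city_id, year, es_name, wi, u, c, t, d, levels
    moran_table: pd.DataFrame       # variable, year, i_value, e_i, p_perm, ...
    transition_tables: dict[tuple[int, int], lu.TransitionMatrix]
    flow_tables: dict[tuple[int, int], pd.DataFrame]
    composition_table: pd.DataFrame
    spearman_table: pd.DataFrame
    ccd_change: pd.DataFrame
    landscape: LandscapeBundle
    manifest: dict


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ------------------------------------------------------------------- stages

def stage_ecosystem_services(bundle: LandscapeBundle, config: RunConfig,
                             bio: es.BiophysicalTable | None = None
                             ) -> tuple[pd.DataFrame, dict]:
    """Per-year ES rasters and their per-city zonal means."""
    bio = bio or es.BiophysicalTable.default()
    rasters: dict[tuple[str, int], object] = {}
    rows = []
    for year, lulc in bundle.landuse.items():
        wy = es.water_yield(bundle.precipitation, bundle.pet, bundle.awc,
                            bundle.root_depth, lulc, z_param=config.z_param)
        sc = es.soil_conservation(bundle.r_factor, bundle.k_factor,
                                  bundle.ls_factor, lulc, bio)
        threats = [es.construction_threat(lulc, config.threat_max_dist_km,
                                          decay=config.threat_decay)]
        hq = es.habitat_quality(lulc, threats, bio, k_half=config.k_half,
                                z_exp=config.z_exp)
        cs = es.carbon_storage(lulc, bio)
        rasters.update({("WY", year): wy, ("SC", year): sc,
                        ("HQ", year): hq, ("CS", year): cs})
        zmeans = {name: es.zonal_summary(r, bundle.zones, "mean")
                  for name, r in (("WY", wy), ("SC", sc), ("HQ", hq), ("CS", cs))}
        for city in zmeans["WY"].index:
            rows.append((int(city), int(year), zmeans["WY"][city],
                         zmeans["SC"][city], zmeans["HQ"][city],
                         zmeans["CS"][city]))
    table = pd.DataFrame(rows, columns=["city_id", "year", "wy_mm", "sc_t_ha",
                                        "hq", "cs_t_ha"])
    return table.sort_values(["year", "city_id"], ignore_index=True), rasters


def stage_tu(panel: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, pd.Series]:
    scores, weights = tu_mod.compute_tu(
        panel, pooling=config.pooling, epsilon=config.epsilon,
        renormalize=config.renormalize_subsystems, rescale=config.rescale)
    out = scores.reset_index()
    out = out.rename(columns={"tu_raw": "tu_raw", "tu": "tu_rescaled"})
    return out, weights


def stage_ccd(es_table: pd.DataFrame, tu_table: pd.DataFrame,
              config: RunConfig) -> pd.DataFrame:
    params = cp.CouplingParams(config.alpha, config.beta)
    u_col = "tu_rescaled" if "tu_rescaled" in tu_table.columns else "tu_raw"
    u = tu_table.set_index(["city_id", "year"])[u_col]
    frames = []
    es_cols = dict(zip(ES_NAMES, ("wy_mm", "sc_t_ha", "hq", "cs_t_ha")))
    indexed = es_table.set_index(["city_id", "year"])
    for name, col in es_cols.items():
        wi = cp.es_normalize(indexed[col])
        frames.append(cp.coupling_records(wi, u.reindex(wi.index), name, params))
    return pd.concat(frames, ignore_index=True)


def stage_spatial(bundle: LandscapeBundle, es_table: pd.DataFrame,
                  tu_table: pd.DataFrame, ccd_table: pd.DataFrame,
                  config: RunConfig) -> pd.DataFrame:
    weights = sp.queen_contiguity(bundle.zones)
    order = list(weights.ids)
    rows = []
    seed_base = int(config.synthetic.seed) % (2**31 - 1)

    def add(variable: str, year: int, series: pd.Series) -> None:
        x = series.reindex(order).to_numpy(float)
        if np.ptp(x) == 0:
            return
        salt = int(hashlib.sha256(f"{variable}:{year}".encode()).hexdigest()[:8], 16)
        res = sp.morans_permutation_test(
            x, weights, n_perm=config.n_perm,
            seed=(seed_base * 1000003 + salt) % (2**31))
        rows.append((variable, year, res.i_value, res.e_i, res.p_perm,
                     res.z_score, res.n_perm))

    tu_idx = tu_table.set_index(["city_id", "year"])
    u_col = "tu_rescaled" if "tu_rescaled" in tu_idx.columns else "tu_raw"
    es_idx = es_table.set_index(["city_id", "year"])
    for year in config.synthetic.years:
        add("TU", year, tu_idx.xs(year, level="year")[u_col])
        for name, col in zip(ES_NAMES, ("wy_mm", "sc_t_ha", "hq", "cs_t_ha")):
            add(name, year, es_idx.xs(year, level="year")[col])
    for name in ES_NAMES:
        sub = ccd_table[ccd_table["es_name"] == name]
        for year in config.synthetic.years:
            d = sub[sub["year"] == year].set_index("city_id")["d"]
            add(f"CCD_{name}", year, d)
    return pd.DataFrame(rows, columns=["variable", "year", "i_value", "e_i",
                                       "p_perm", "z_score", "n_perm"])


def stage_landuse(bundle: LandscapeBundle):
    years = sorted(bundle.landuse)
    transitions, flows = {}, {}
    comps = []
    for year in years:
        c = lu.composition(bundle.landuse[year])
        c.insert(0, "year", year)
        comps.append(c)
    for t0, t1 in zip(years[:-1], years[1:]):
        tm = lu.transition_matrix(bundle.landuse[t0], bundle.landuse[t1])
        transitions[(t0, t1)] = tm
        flows[(t0, t1)] = lu.sankey_flows(tm)
    if len(years) > 1:
        tm = lu.transition_matrix(bundle.landuse[years[0]], bundle.landuse[years[-1]])
        transitions[(years[0], years[-1])] = tm
        flows[(years[0], years[-1])] = lu.sankey_flows(tm)
    return transitions, flows, pd.concat(comps, ignore_index=True)


def stage_spearman(es_table: pd.DataFrame, tu_table: pd.DataFrame) -> pd.DataFrame:
    merged = es_table.merge(tu_table, on=["city_id", "year"])
    cols = {"TU": "tu_rescaled" if "tu_rescaled" in merged.columns else "tu_raw",
            "TS": "s_tourism", "US": "s_urban", "ES": "s_eco",
            "WY": "wy_mm", "SC": "sc_t_ha", "HQ": "hq", "CS": "cs_t_ha"}
    frame = pd.DataFrame({k: merged[v] for k, v in cols.items()})
    return cp.spearman_matrix(frame)


def stage_ccd_change(ccd_table: pd.DataFrame, years) -> pd.DataFrame:
    t0, t1 = min(years), max(years)
    rows = []
    for name in ES_NAMES:
        sub = ccd_table[ccd_table["es_name"] == name]
        stats = cp.ccd_change_stats(sub[sub["year"] == t0], sub[sub["year"] == t1])
        rows.append({"es_name": name, "t0_year": t0, "t1_year": t1, **stats})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- runner

def validate_inputs(bundle: LandscapeBundle, panel: pd.DataFrame) -> list[str]:
    """Report-only consistency checks across all pipeline inputs."""
    violations: list[str] = []
    ref = bundle.zones
    for name, rast in bundle.continuous_layers().items():
        if not ref.aligned_with(rast):
            violations.append(f"{name} raster misaligned: {rast.shape} vs zones {ref.shape}")
    for year, lulc in bundle.landuse.items():
        if not ref.aligned_with(lulc):
            violations.append(f"landuse[{year}] misaligned: {lulc.shape} vs {ref.shape}")
        extra = set(np.unique(lulc.valid_values())) - set(CLASS_CODES)
        if extra:
            violations.append(f"landuse[{year}] has illegal codes {sorted(extra)}")
    have = set(panel["indicator_code"].unique())
    missing = [c for c in INDICATOR_CODES if c not in have]
    if missing:
        violations.append(f"panel missing indicators {missing}")
    if (panel["value"] < 0).any():
        violations.append("panel contains negative indicator values")
    zone_ids = set(int(z) for z in np.unique(ref.data[ref.valid_mask]))
    panel_cities = set(panel["city_id"].unique())
    if panel_cities - zone_ids:
        violations.append(f"panel cities without zones: {sorted(panel_cities - zone_ids)}")
    return violations


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 bio: es.BiophysicalTable | None = None) -> ResultBundle:
    """Execute every stage; optionally write all artifacts under ``out_dir``."""
    config.validate()
    t_start = time.perf_counter()

    def timed(stage: str, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        log.info("stage %-10s %6.2f s", stage, time.perf_counter() - t0)
        return out

    bundle = timed("simulate", generate_landscape, config.synthetic)
    panel = timed("panel", generate_indicator_panel, config.synthetic)
    violations = validate_inputs(bundle, panel)
    if violations:
        raise ConfigurationError(f"[stage validate] {violations}")
    transitions, flows, comp = timed("landuse", stage_landuse, bundle)
    es_table, es_rasters = timed("es", stage_ecosystem_services, bundle, config, bio)
    tu_table, weights = timed("tu", stage_tu, panel, config)
    ccd_table = timed("ccd", stage_ccd, es_table, tu_table, config)
    moran_table = timed("spatial", stage_spatial, bundle, es_table, tu_table,
                        ccd_table, config)
    spearman_table = timed("spearman", stage_spearman, es_table, tu_table)
    ccd_change = timed("ccd_change", stage_ccd_change, ccd_table,
                       config.synthetic.years)

    manifest = {
        "package": "tuces", "version": __version__,
        "config_sha256": config_hash(config),
        "seed": int(config.synthetic.seed),
        "numpy": np.__version__, "pandas": pd.__version__,
        "tables": {"es": len(es_table), "tu": len(tu_table),
                   "ccd": len(ccd_table), "moran": len(moran_table)},
        "runtime_s": round(time.perf_counter() - t_start, 3),
    }
    result = ResultBundle(es_table=es_table, tu_table=tu_table, weights=weights,
                          ccd_table=ccd_table, moran_table=moran_table,
                          transition_tables=transitions, flow_tables=flows,
                          composition_table=comp, spearman_table=spearman_table,
                          ccd_change=ccd_change, landscape=bundle,
                          manifest=manifest)
    if out_dir is not None:
        write_results(result, Path(out_dir), config, es_rasters)
    return result


def write_results(result: ResultBundle, out_dir: Path, config: RunConfig,
                  es_rasters: dict | None = None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.es_table.to_csv(out_dir / "es_city.csv", index=False)
    result.tu_table.to_csv(out_dir / "tu_scores.csv", index=False)
    w = result.weights.reset_index()
    w.columns = ["indicator_code", "weight"]
    w.to_csv(out_dir / "weights.csv", index=False)
    result.ccd_table.to_csv(out_dir / "ccd.csv", index=False)
    result.moran_table.to_csv(out_dir / "moran.csv", index=False)
    result.composition_table.to_csv(out_dir / "composition.csv", index=False)
    result.spearman_table.to_csv(out_dir / "spearman.csv", index=False)
    result.ccd_change.to_csv(out_dir / "ccd_change.csv", index=False)
    for (t0, t1), tm in result.transition_tables.items():
        tm.to_dataframe().to_csv(out_dir / f"transition_{t0}_{t1}.csv")
        result.flow_tables[(t0, t1)].to_csv(
            out_dir / f"flows_{t0}_{t1}.csv", index=False)
    # manifest must not depend on wall time
    manifest = {k: v for k, v in result.manifest.items() if k != "runtime_s"}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    if config.write_rasters and es_rasters:
        rdir = out_dir / "rasters"
        rdir.mkdir(exist_ok=True)
        for (name, year), rast in es_rasters.items():
            write_ascii_grid(rast, rdir / f"{name.lower()}_{year}.asc")
        for year, lulc in result.landscape.landuse.items():
            write_ascii_grid(lulc, rdir / f"landuse_{year}.asc")
    if config.write_zones_geojson:
        _write_zones_geojson(result.landscape, out_dir / "zones.geojson")


def _write_zones_geojson(bundle: LandscapeBundle, path: Path) -> None:
    from shapely.geometry import mapping
    features = [{"type": "Feature", "properties": {"zone_id": zid},
                 "geometry": mapping(geom)}
                for zid, geom in zone_polygons(bundle.zones).items()]
    path.write_text(json.dumps({"type": "FeatureCollection",
                                "features": features}))
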