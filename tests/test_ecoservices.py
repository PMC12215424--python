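import numpy as np
import pandas as pd
import pytest

from tuces.ecoservices import (BiophysicalTable, ThreatSpec, annualized_change,
                               carbon_storage, construction_threat,
                               habitat_degradation, habitat_quality,
                               mann_kendall, percent_change, soil_conservation,
                               trend_classification, water_yield, zonal_summary)
from tuces.errors import ConfigurationError, DomainError
from tuces.raster import LandUseRaster, Raster


def const(value, shape=(6, 6), area=1.0):
    return Raster(np.full(shape, float(value)), area)


def lu_of(code, shape=(6, 6), area=1.0):
    return LandUseRaster(np.full(shape, code, dtype=np.uint8), area)


class TestWaterYield:
    def test_zero_pet_yields_all_precipitation(self):
        wy = water_yield(const(500), const(0), const(100), const(1000), lu_of(3))
        assert np.allclose(wy.data, 500.0)

    def test_huge_pet_drives_yield_to_zero(self):
        # Budyko approaches the water limit as a power law, so push PET far out
        wy = water_yield(const(500), const(1e12), const(100), const(1000), lu_of(3))
        assert (wy.data < 1e-3).all()

    def test_budyko_curve_direct_evaluation(self):
        # P=500, PET=400, ω=2  →  AET/P = 1 + 0.8 − √1.64 = 0.519375
        # ω = z·S/P + 1.25 = 2 with S = min(awc, depth) = 125, z = 3
        p, pet = const(500), const(400)
        wy = water_yield(p, pet, const(125), const(1e4), lu_of(2), z_param=3.0)
        aet_ratio = 1 + 0.8 - (1 + 0.8 ** 2) ** 0.5
        assert np.allclose(wy.data, (1 - aet_ratio) * 500)
        assert wy.data[0, 0] == pytest.approx(240.31, abs=0.005)

    def test_non_vegetated_uses_evaporative_fraction(self):
        wy = water_yield(const(500), const(200), const(100), const(1000), lu_of(5))
        assert np.allclose(wy.data, 300.0)      # P − min(PET, P)
        wy2 = water_yield(const(500), const(900), const(100), const(1000), lu_of(4))
        assert np.allclose(wy2.data, 0.0)

    def test_bounded_by_precipitation_and_monotone_in_pet(self):
        rng = np.random.default_rng(5)
        p = Raster(rng.uniform(200, 800, (15, 15)), 1.0)
        awc, depth = const(120, (15, 15)), const(1500, (15, 15))
        lulc = LandUseRaster(rng.integers(1, 7, (15, 15)).astype(np.uint8), 1.0)
        prev = None
        for pet_level in (0, 200, 400, 800, 1600):
            wy = water_yield(p, const(pet_level, (15, 15)), awc, depth, lulc)
            assert (wy.data >= -1e-9).all() and (wy.data <= p.data + 1e-9).all()
            if prev is not None:
                assert (wy.data <= prev + 1e-9).all()
            prev = wy.data

    def test_nonpositive_precipitation_raises(self):
        with pytest.raises(DomainError, match="precipitation"):
            water_yield(const(0), const(10), const(10), const(10), lu_of(1))


class TestSoilConservation:
    def test_bare_ground_retains_nothing(self, bio):
        t = bio.table.reset_index()
        t.loc[t.class_code == 6, ["cover_C", "practice_P"]] = 1.0
        sc = soil_conservation(const(100), const(0.3), const(2), lu_of(6),
                               BiophysicalTable(t))
        assert np.allclose(sc.data, 0.0)

    def test_zero_cover_factor_keeps_full_potential(self, bio):
        t = bio.table.reset_index()
        t.loc[t.class_code == 2, "cover_C"] = 0.0
        sc = soil_conservation(const(100), const(0.3), const(2), lu_of(2),
                               BiophysicalTable(t))
        assert np.allclose(sc.data, 100 * 0.3 * 2)

    def test_direct_rusle_evaluation(self, bio):
        t = bio.table.reset_index()
        t.loc[t.class_code == 1, ["cover_C", "practice_P"]] = [0.1, 0.5]
        sc = soil_conservation(const(100), const(0.3), const(2), lu_of(1),
                               BiophysicalTable(t))
        assert np.allclose(sc.data, 57.0)

    def test_monotone_decreasing_in_cp_product(self, bio):
        values = []
        for c in (0.0, 0.2, 0.5, 0.9):
            t = bio.table.reset_index()
            t.loc[t.class_code == 3, ["cover_C", "practice_P"]] = [c, 1.0]
            sc = soil_conservation(const(80), const(0.4), const(1.5), lu_of(3),
                                   BiophysicalTable(t))
            values.append(sc.data[0, 0])
        assert all(a > b for a, b in zip(values, values[1:]))


class TestHabitatQuality:
    def test_no_threats_returns_habitat_suitability(self, bio):
        for code, h in ((2, 1.0), (3, 0.8), (5, 0.0)):
            hq = habitat_quality(lu_of(code), [], bio)
            assert np.allclose(hq.data, h)

    def test_construction_has_zero_quality_regardless(self, bio):
        lulc = lu_of(5)
        threats = [construction_threat(lulc, max_dist_km=3.0)]
        assert np.allclose(habitat_quality(lulc, threats, bio).data, 0.0)

    def test_half_saturation_identity(self, bio):
        # a single source at the center of its own cell: decay(0)=1, so with
        # weight 1, intensity k_half and sensitivity 1 the degradation at the
        # source cell is exactly k_half → Q = 0.5·H there
        k_half = 0.37
        intensity = np.zeros((9, 9))
        intensity[4, 4] = k_half
        threat = ThreatSpec("t", Raster(intensity, 1.0), max_dist_km=0.5,
                            sensitivity={3: 1.0})
        hq = habitat_quality(lu_of(3, (9, 9)), [threat], bio, k_half=k_half)
        assert hq.data[4, 4] == pytest.approx(0.5 * 0.8, abs=1e-9)

    def test_degradation_decays_with_distance_and_stops_at_dmax(self, bio):
        intensity = np.zeros((21, 21))
        intensity[10, 10] = 1.0
        threat = ThreatSpec("t", Raster(intensity, 1.0), max_dist_km=3.0,
                            decay="linear", sensitivity={3: 1.0})
        deg = habitat_degradation(lu_of(3, (21, 21)), [threat]).data
        assert deg[10, 10] == pytest.approx(1.0, abs=1e-9)
        assert deg[10, 12] == pytest.approx(1 - 2 / 3, abs=1e-9)
        assert deg[10, 14] == pytest.approx(0.0, abs=1e-12)   # beyond d_max

    def test_quality_monotone_nonincreasing_in_intensity(self, bio):
        prev = None
        for level in (0.0, 0.3, 0.6, 1.0):
            intensity = np.full((11, 11), level)
            threat = ThreatSpec("t", Raster(intensity, 1.0), max_dist_km=2.0,
                                sensitivity={2: 0.9})
            hq = habitat_quality(lu_of(2, (11, 11)), [threat], bio).data
            assert ((hq >= 0) & (hq <= 1)).all()
            if prev is not None:
                assert (hq <= prev + 1e-12).all()
            prev = hq


class TestCarbonAndZonal:
    def test_pool_sum_lookup(self, bio):
        cs = carbon_storage(lu_of(2), bio)
        forest = bio.table.loc[2]
        expected = forest[["c_above", "c_below", "c_soil", "c_dead"]].sum()
        assert np.allclose(cs.data, expected)

    def test_zonal_mean_matches_brute_force(self, small_bundle, bio):
        cs = carbon_storage(small_bundle.landuse[2000], bio)
        means = zonal_summary(cs, small_bundle.zones, "mean")
        for zid in means.index:
            cells = small_bundle.zones.data == zid
            assert means[zid] == pytest.approx(cs.data[cells].mean(), rel=1e-9)

    def test_constant_raster_mean_and_enumerated_mean(self):
        zones = Raster(np.array([[1, 1], [2, 2]]), 1.0, nodata=0)
        vals = Raster(np.array([[1.0, 2.0], [3.0, 4.0]]), 1.0)
        means = zonal_summary(vals, zones)
        assert means[1] == 1.5 and means[2] == 3.5
        assert zonal_summary(vals, zones, "sum")[2] == 7.0

    def test_zone_without_valid_cells_is_nan_not_zero(self):
        zones = Raster(np.array([[1, 2]]), 1.0, nodata=0)
        vals = Raster(np.array([[5.0, -9999.0]]), 1.0)
        means = zonal_summary(vals, zones)
        assert means[1] == 5.0 and np.isnan(means[2])


class TestChangeAndTrends:
    def test_zero_change_and_table_arithmetic(self):
        assert annualized_change(np.array([3.0]), np.array([3.0]), 20)[0] == 0
        assert annualized_change(np.array([39.06]), np.array([64.43]), 20)[0] \
            == pytest.approx(1.2685, abs=5e-5)
        assert percent_change(39.06, 64.43) == pytest.approx(64.95, abs=0.005)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=8)
        c, d = rng.normal(size=8), rng.normal(size=8)
        lhs = annualized_change(a + c, b + d, 10)
        rhs = annualized_change(a, b, 10) + annualized_change(c, d, 10)
        assert np.allclose(lhs, rhs)

    def test_invalid_span_raises(self):
        with pytest.raises(DomainError):
            annualized_change(np.array([1.0]), np.array([2.0]), 0)

    def test_mann_kendall_monotone_series_significant(self):
        s, z, p = mann_kendall(np.arange(10, dtype=float))
        assert s == 45 and p < 0.05

    def test_mann_kendall_constant_series_not_significant(self):
        _, _, p = mann_kendall(np.full(6, 2.0))
        assert p == 1.0

    def test_trend_classification_rules(self):
        rates = pd.Series({"a": 0.0, "b": 2.0, "c": -2.0, "d": 0.5})
        series = {"a": np.full(5, 1.0), "b": np.arange(5.0) * 2,
                  "c": -np.arange(5.0) * 2, "d": np.array([1.0, 3.0])}
        out = trend_classification(rates, threshold=1.0, series=series)
        assert out["a"] == "no significant change"
        assert out["b"] == "increase" and out["c"] == "decrease"
        # only 2 timepoints: falls back to |rate| <= threshold rule
        assert out["d"] == "no significant change"

    def test_empty_rates_raise(self):
        with pytest.raises(DomainError):
            trend_classification(pd.Series(dtype=float))


def test_corrupt_biophysical_table_rejected(bio):
    t = bio.table.reset_index()
    t.loc[0, "habitat"] = 1.5
    with pytest.raises(ConfigurationError):
        BiophysicalTable(t)
    t2 = bio.table.reset_index().drop(index=0)
    with pytest.raises(ConfigurationError):
        BiophysicalTable(t2)
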