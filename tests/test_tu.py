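import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tuces.errors import DegenerateIndicatorError, DomainError
from tuces.indicators import INDICATOR_CODES, SUBSYSTEMS
from tuces.synthetic import SyntheticConfig, generate_indicator_panel
from tuces.tu import (coefficient_of_variation, column_entropy, compute_tu,
                      entropy_weights, normalize_indicators, panel_to_wide,
                      subsystem_scores, tu_state_space)


def toy_panel(values: dict[str, list[float]], cities=None) -> pd.DataFrame:
    cities = cities or list(range(1, len(next(iter(values.values()))) + 1))
    rows = [(c, 2000, code, v) for code, vals in values.items()
            for c, v in zip(cities, vals)]
    return pd.DataFrame(rows, columns=["city_id", "year", "indicator_code", "value"])


class TestNormalization:
    def test_positive_direction_endpoints(self):
        eps = 1e-4
        norm = normalize_indicators(toy_panel({"T1": [0, 5, 10]}), epsilon=eps)
        vals = norm["T1"].to_numpy()
        assert vals[0] == pytest.approx(eps)
        assert vals[1] == pytest.approx(eps + (1 - eps) * 0.5)
        assert vals[2] == pytest.approx(1.0)

    def test_negative_direction_reverses_order(self):
        norm = normalize_indicators(toy_panel({"E1": [0, 5, 10]}))
        vals = norm["E1"].to_numpy()
        assert vals[0] == pytest.approx(1.0)
        assert vals[2] == pytest.approx(1e-4)

    def test_rank_preservation_oracle(self):
        rng = np.random.default_rng(4)
        raw = rng.lognormal(size=12)
        norm = normalize_indicators(toy_panel({"U5": raw.tolist()}))
        assert (np.argsort(norm["U5"].to_numpy())
                == np.argsort(raw)).all()

    def test_constant_indicator_names_the_code(self):
        with pytest.raises(DegenerateIndicatorError, match="U3"):
            normalize_indicators(toy_panel({"U3": [7, 7, 7], "T1": [1, 2, 3]}))

    def test_per_year_pooling_normalizes_within_year(self):
        rows = [(c, y, "T2", v) for y, vals in ((2000, [1, 2]), (2010, [10, 30]))
                for c, v in zip((1, 2), vals)]
        panel = pd.DataFrame(rows, columns=["city_id", "year", "indicator_code",
                                            "value"])
        norm = normalize_indicators(panel, pooling="per_year")
        by_year = norm.groupby(level="year")["T2"]
        assert np.allclose(by_year.max().to_numpy(), 1.0)


class TestEntropyWeights:
    def test_hand_evaluated_entropy(self):
        # p = (0.2, 0.3, 0.5) → E = −(Σ p ln p)/ln 3 = 0.9372
        assert column_entropy([0.2, 0.3, 0.5]) == pytest.approx(0.9372, abs=5e-5)

    def test_weight_formula_from_entropies(self):
        # E = (0.9, 0.8) → ω = (0.1, 0.2)/0.3 = (1/3, 2/3); reproduce via
        # columns engineered to those dispersion ratios is indirect, so check
        # the identity on the formula's own terms
        e = np.array([0.9, 0.8])
        w = (1 - e) / (1 - e).sum()
        assert np.allclose(w, [1 / 3, 2 / 3])

    def test_weights_sum_to_one_and_uniform_column_gets_zero(self):
        n = 8
        uniform = np.full(n, 0.6)
        varying = np.linspace(0.1, 1.0, n)
        frame = pd.DataFrame({"T1": uniform, "T2": varying})
        w = entropy_weights(frame)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert w["T1"] == pytest.approx(0.0, abs=1e-12)
        assert w["T2"] == pytest.approx(1.0, abs=1e-12)

    def test_all_uniform_columns_raise_zero_denominator(self):
        frame = pd.DataFrame({"T1": np.full(5, 0.3), "T2": np.full(5, 0.9)})
        with pytest.raises(DomainError, match="zero denominator"):
            entropy_weights(frame)

    def test_three_city_toy_panel_matches_hand_evaluation(self):
        # independent oracle: evaluate the entropy/weight formulas step by
        # step with plain loops on a 3-city × 3-indicator panel
        frame = pd.DataFrame({"T1": [0.2, 0.5, 1.0], "U1": [1.0, 0.4, 0.1],
                              "E4": [0.3, 0.9, 0.6]})
        n = 3
        entropies = {}
        for code in frame:
            col = frame[code].to_numpy()
            p = col / col.sum()
            entropies[code] = -sum(pi * np.log(pi) for pi in p) / np.log(n)
        total = sum(1 - e for e in entropies.values())
        expected = {c: (1 - e) / total for c, e in entropies.items()}
        w = entropy_weights(frame)
        for code in frame:
            assert w[code] == pytest.approx(expected[code], abs=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_permutation_equivariance_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(size=(6, 3))
        panel = toy_panel({"T1": raw[:, 0].tolist(), "U1": raw[:, 1].tolist(),
                           "E1": raw[:, 2].tolist()})
        w1 = entropy_weights(normalize_indicators(panel))
        # scaling a raw column is absorbed by min-max
        scaled = panel.copy()
        scaled.loc[scaled.indicator_code == "T1", "value"] *= 37.0
        w2 = entropy_weights(normalize_indicators(scaled))
        assert np.allclose(w1, w2, atol=1e-12)
        # permuting cities permutes rows only; weights are unchanged
        perm = panel.copy()
        perm["city_id"] = perm["city_id"].map(
            dict(zip(range(1, 7), rng.permutation(range(1, 7)))))
        w3 = entropy_weights(normalize_indicators(perm))
        assert np.allclose(w1, w3, atol=1e-12)


class TestScoresAndStateSpace:
    def test_bounds_at_extremes(self):
        idx = pd.MultiIndex.from_tuples([(1, 2000), (2, 2000)],
                                        names=["city_id", "year"])
        codes = list(INDICATOR_CODES)
        weights = pd.Series(1 / 22, index=codes)
        ones = pd.DataFrame(1.0, index=idx, columns=codes)
        zeros = pd.DataFrame(0.0, index=idx, columns=codes)
        assert np.allclose(subsystem_scores(ones, weights), 1.0)
        assert np.allclose(subsystem_scores(zeros, weights), 0.0)

    def test_single_indicator_subsystem_passthrough(self):
        idx = pd.MultiIndex.from_tuples([(1, 2000), (2, 2000), (3, 2000)],
                                        names=["city_id", "year"])
        frame = pd.DataFrame({"T5": [0.2, 0.6, 0.9], "U1": [0.5, 0.5, 0.5],
                              "E4": [0.1, 0.2, 0.3]}, index=idx)
        weights = pd.Series({"T5": 0.6, "U1": 0.3, "E4": 0.1})
        scores = subsystem_scores(frame, weights, renormalize=True)
        assert np.allclose(scores["s_tourism"], frame["T5"])

    def test_tu_norm_identities(self):
        scores = pd.DataFrame({"s_urban": [0.3, 1.0, 0.0],
                               "s_tourism": [0.4, 1.0, 0.0],
                               "s_eco": [0.0, 1.0, 0.0]})
        out = tu_state_space(scores, rescale=True)
        assert out["tu_raw"].tolist() == pytest.approx([0.5, np.sqrt(3), 0.0])
        assert out["tu"][1] == pytest.approx(1.0)

    def test_tu_monotone_in_each_subsystem(self):
        base = pd.DataFrame({"s_urban": [0.4], "s_tourism": [0.4], "s_eco": [0.4]})
        tu0 = tu_state_space(base)["tu_raw"][0]
        for col in base.columns:
            bumped = base.copy()
            bumped[col] += 0.2
            assert tu_state_space(bumped)["tu_raw"][0] > tu0

    def test_end_to_end_scores_in_unit_interval(self):
        cfg = SyntheticConfig(grid_rows=15, grid_cols=15, n_cities=6, seed=31)
        scores, weights = compute_tu(generate_indicator_panel(cfg))
        for col in ("s_tourism", "s_urban", "s_eco", "tu"):
            assert scores[col].between(0, 1).all(), col
        assert weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestCV:
    def test_constant_series_zero(self):
        assert coefficient_of_variation([4.0, 4.0, 4.0]) == 0.0

    def test_hand_computation_sample_sd(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    def test_scale_invariance(self):
        x = [1.0, 2.0, 5.0]
        assert coefficient_of_variation(x) == pytest.approx(
            coefficient_of_variation([3 * v for v in x]))

    def test_zero_mean_raises(self):
        with pytest.raises(DomainError):
            coefficient_of_variation([-1.0, 1.0])


def test_panel_to_wide_rejects_duplicates_and_unknown_codes():
    import pytest as _pt
    panel = toy_panel({"T1": [1, 2]})
    dup = pd.concat([panel, panel.iloc[[0]]], ignore_index=True)
    with _pt.raises(Exception, match="duplicate"):
        panel_to_wide(dup)
    bad = panel.copy()
    bad.loc[0, "indicator_code"] = "X9"
    with _pt.raises(Exception, match="X9"):
        panel_to_wide(bad)
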