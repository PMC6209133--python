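import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbhmort.age_bins import DEFAULT_SCHEME
from sbhmort.aggregation import (
    AggregatedTrend,
    aggregate_trends,
    combine_bins,
    compute_eeb,
    summarize_uncertainty,
    survival_to_entry,
)


def hyp_frame(n, pob=0.5, ceb=2.0, year=2005, country="X", weight=1.0):
    return pd.DataFrame(
        {
            "mother_id": [f"m{i}" for i in range(n)],
            "survey_id": "S",
            "country": country,
            "birth_year": year,
            "years_prior": 5,
            "pob": pob,
            "ceb": ceb,
            "survey_weight": weight,
        }
    )


class TestSurvival:
    def test_zero_hazard(self):
        np.testing.assert_array_equal(survival_to_entry(np.zeros(7)), np.ones(7))

    def test_constant_hazard(self):
        S = survival_to_entry(np.full(7, 0.1))
        assert S[0] == 1.0
        assert S[1] == pytest.approx(0.9)
        assert S[2] == pytest.approx(0.81)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(deadline=None)
    def test_matches_loop_oracle(self, q):
        q = np.array(q)
        S = survival_to_entry(q)
        acc = 1.0
        for a in range(len(q)):
            assert S[a] == pytest.approx(acc, abs=1e-12)
            acc *= 1.0 - q[a]

    def test_invalid_hazard_rejected(self):
        with pytest.raises(ValueError):
            survival_to_entry(np.array([0.2, 1.5]))


class TestEEB:
    def test_hand_example(self):
        q = np.zeros((1, 7))
        q[0, 0] = 0.1
        eeb = compute_eeb(np.array([0.5]), np.array([2.0]), q)
        assert eeb[0, 0] == pytest.approx(1.0)
        assert eeb[0, 1] == pytest.approx(0.9)

    def test_zero_pob_zero_weight(self):
        eeb = compute_eeb(np.array([0.0]), np.array([3.0]), np.full((1, 7), 0.2))
        assert (eeb == 0).all()

    def test_zero_hazard_constant_eeb(self):
        eeb = compute_eeb(np.array([0.25]), np.array([4.0]), np.zeros((1, 7)))
        np.testing.assert_allclose(eeb, 1.0)

    def test_nonincreasing_within_child(self):
        rng = np.random.default_rng(3)
        q = rng.uniform(0, 0.3, size=(50, 7))
        eeb = compute_eeb(rng.uniform(0, 1, 50), rng.integers(1, 8, 50).astype(float), q)
        assert (np.diff(eeb, axis=1) <= 1e-12).all()


class TestAggregation:
    def test_single_child_returns_its_hazard(self):
        hyp = hyp_frame(1)
        q = np.full((1, 7), 0.07)
        trend = aggregate_trends(hyp, q)
        np.testing.assert_allclose(trend.q, 0.07)

    def test_weighted_mean_arithmetic(self):
        hyp = hyp_frame(2, pob=1.0, ceb=1.0)
        q = np.zeros((2, 7))
        q[0, 0], q[1, 0] = 0.1, 0.3
        trend = aggregate_trends(hyp, q)
        assert trend.q[0, 0] == pytest.approx(0.2)
        # unequal EEB via CEB 3 vs 1: (0.1*3 + 0.3*1) / 4 = 0.15
        hyp2 = hyp_frame(2, pob=1.0)
        hyp2["ceb"] = [3.0, 1.0]
        trend2 = aggregate_trends(hyp2, q)
        assert trend2.q[0, 0] == pytest.approx(0.15)

    def test_constant_hazard_invariant_to_weights(self):
        rng = np.random.default_rng(0)
        hyp = hyp_frame(20, pob=1.0)
        hyp["ceb"] = rng.integers(1, 9, 20).astype(float)
        hyp["survey_weight"] = rng.uniform(0.2, 3.0, 20)
        trend = aggregate_trends(hyp, np.full((20, 7), 0.04))
        np.testing.assert_allclose(trend.q, 0.04)

    def test_survey_weights_enter_summands(self):
        hyp = hyp_frame(2, pob=1.0, ceb=1.0)
        hyp["survey_weight"] = [3.0, 1.0]
        q = np.zeros((2, 7))
        q[0, 0], q[1, 0] = 0.1, 0.3
        weighted = aggregate_trends(hyp, q, use_survey_weights=True)
        unweighted = aggregate_trends(hyp, q, use_survey_weights=False)
        assert weighted.q[0, 0] == pytest.approx(0.15)
        assert unweighted.q[0, 0] == pytest.approx(0.2)

    def test_expected_deaths_are_numerator(self):
        hyp = hyp_frame(5)
        q = np.full((5, 7), 0.02)
        trend = aggregate_trends(hyp, q)
        np.testing.assert_allclose(trend.deaths, q[0] * trend.entrants)

    def test_zero_entrants_undefined(self):
        hyp = hyp_frame(1, pob=0.0)
        trend = aggregate_trends(hyp, np.full((1, 7), 0.1))
        assert np.isnan(trend.q).all()


class TestCombineBins:
    @staticmethod
    def _trend_from_q(q):
        G = q.shape[0]
        keys = pd.DataFrame({"country": "X", "year": np.arange(G)})
        return AggregatedTrend(
            keys=keys,
            scheme=DEFAULT_SCHEME,
            q=q,
            deaths=np.zeros_like(q),
            entrants=np.ones_like(q),
        )

    def test_hand_example_infant_mortality(self):
        q = np.zeros((1, 7))
        q[0, :3] = [0.03, 0.015, 0.013]
        out = combine_bins(self._trend_from_q(q), "1q0")
        assert out["q"][0] == pytest.approx(1 - 0.97 * 0.985 * 0.987, abs=1e-12)

    def test_degenerate_cases(self):
        q = np.zeros((1, 7))
        assert combine_bins(self._trend_from_q(q), "5q0")["q"][0] == 0.0
        q[0, 3] = 1.0
        assert combine_bins(self._trend_from_q(q), "5q0")["q"][0] == 1.0

    def test_non_contiguous_rejected(self):
        q = np.full((1, 7), 0.01)
        with pytest.raises(ValueError):
            combine_bins(self._trend_from_q(q), [0, 2])
        with pytest.raises(ValueError):
            combine_bins(self._trend_from_q(q), [1, 2, 3])

    def test_matches_loop_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        q = rng.uniform(0, 1, size=(500, 7))
        got = combine_bins(self._trend_from_q(q), "5q0")["q"].to_numpy()
        for i in range(500):
            acc = 1.0
            for a in range(7):
                acc *= 1.0 - q[i, a]
            assert abs(got[i] - (1.0 - acc)) < 1e-12


class TestUncertainty:
    def test_identical_draws_collapse(self):
        draws = np.full((4, 100), 0.3)
        point, lo, hi = summarize_uncertainty(draws)
        assert (point == 0.3).all() and (lo == 0.3).all() and (hi == 0.3).all()

    def test_quantile_rule_frozen_value(self):
        draws = (np.arange(1, 101) / 1000.0)[None, :]
        point, lo, hi = summarize_uncertainty(draws)
        # linear-interpolation quantiles on 1..100 permille:
        # position (n-1)*p = 99*0.025 = 2.475 -> 0.003 + 0.475*0.001
        assert lo[0] == pytest.approx(0.003475, abs=1e-12)
        assert hi[0] == pytest.approx(0.097525, abs=1e-12)
        assert point[0] == pytest.approx(0.0505)

    def test_bounds_bracket_mean(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0.1, 0.01, size=(6, 400)).clip(0, 1)
        point, lo, hi = summarize_uncertainty(draws)
        assert (lo <= point).all() and (point <= hi).all()

    def test_requires_two_draws(self):
        with pytest.raises(ValueError):
            summarize_uncertainty(np.ones((3, 1)))


def test_draw_level_aggregation_quantiles():
    rng = np.random.default_rng(2)
    hyp = hyp_frame(30)
    q = rng.uniform(0.01, 0.1, size=(30, 7))
    q_draws = q[..., None] * rng.uniform(0.8, 1.2, size=(30, 7, 50))
    trend = aggregate_trends(hyp, q, q_draws.clip(0, 1))
    frame = trend.to_frame()
    assert trend.n_draws == 50
    assert (frame["q_lower"] <= frame["q_upper"]).all()
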