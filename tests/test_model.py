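import numpy as np
import pandas as pd
import pytest

import sbhmort as sm
from sbhmort.model import (
    FittedDTSA,
    ModelSpec,
    fit_baseline,
    fit_by_region,
    fit_full,
    predict_hazard,
)


@pytest.fixture(scope="module")
def trend_fit(tiny_pp):
    return fit_full(tiny_pp, ModelSpec(variant="TREND"))


class TestBaseline:
    def test_saturated_mle_equals_empirical_fractions(self, tiny_pp):
        fitted = fit_baseline(tiny_pp)
        counts = tiny_pp.groupby("bin_index")["death"].agg(["sum", "size"])
        expected = (counts["sum"] / counts["size"]).to_numpy()
        np.testing.assert_allclose(fitted.baseline_q, expected, atol=1e-12)

    def test_zero_death_bin_flagged_divergent(self):
        pp = pd.DataFrame({"bin_index": [0, 0, 1, 1], "death": [1, 0, 0, 0]})
        fitted = fit_baseline(pp, sm.AgeBinScheme((("a", 0, 10), ("b", 10, 20))))
        assert fitted.baseline_q[1] == 0.0
        assert fitted.baseline_flags["divergent"][1]
        assert not fitted.baseline_flags["divergent"][0]

    def test_empty_bin_reported_missing(self):
        pp = pd.DataFrame({"bin_index": [0, 0], "death": [1, 0]})
        fitted = fit_baseline(pp, sm.AgeBinScheme((("a", 0, 10), ("b", 10, 20))))
        assert np.isnan(fitted.baseline_q[1])
        assert fitted.baseline_flags["missing"][1]

    def test_prediction_round_trips_exact_fractions(self, tiny_pp):
        fitted = fit_baseline(tiny_pp)
        pred = fitted.predict(pd.DataFrame({"bin_index": np.arange(7)}))
        np.testing.assert_array_equal(pred.point, fitted.baseline_q)


class TestFullModel:
    def test_year_effect_recovers_simulated_sign(self, tiny_pp, trend_fit):
        """With declining simulated mortality the fitted year trend declines."""
        rows = tiny_pp.drop_duplicates("bin_index").copy()
        early, late = rows.copy(), rows.copy()
        early["birth_year"], late["birth_year"] = 1995, 2009
        q_early = predict_hazard(trend_fit, early).point
        q_late = predict_hazard(trend_fit, late).point
        assert (q_late < q_early).all()

    def test_trend_variant_close_to_baseline_on_flat_data(self, flat_population):
        """With no simulated trend the smooth model reduces to the baseline."""
        p = flat_population
        pp = sm.reshape_to_person_period(p["children"], p["mothers"], p["sdi"])
        base = fit_baseline(pp)
        fitted = fit_full(pp, ModelSpec(variant="TREND"))
        pred = predict_hazard(fitted, pp)
        pp2 = pp.assign(q=pred.point)
        by_bin = pp2.groupby("bin_index")["q"].mean().to_numpy()
        n = pp.groupby("bin_index").size().to_numpy()
        se = np.sqrt(base.baseline_q * (1 - base.baseline_q) / n)
        assert (np.abs(by_bin - base.baseline_q) < 4 * se + 0.1 * base.baseline_q).all()

    def test_covariate_rescaling_invariance(self, tiny_pp):
        """Multiplying a raw covariate by 10 leaves predictions unchanged."""
        spec = ModelSpec(variant="INDIV", use_survey_re=False, use_country_bin_re=False)
        f1 = fit_full(tiny_pp, spec)
        scaled = tiny_pp.copy()
        scaled["mother_age_at_birth"] = 10.0 * scaled["mother_age_at_birth"]
        f2 = fit_full(scaled, spec)
        head = tiny_pp.head(500)
        head_scaled = scaled.head(500)
        q1 = predict_hazard(f1, head).point
        q2 = predict_hazard(f2, head_scaled).point
        np.testing.assert_allclose(q1, q2, atol=1e-6)

    def test_duplication_with_matched_penalty_is_invariant(self, tiny_pp):
        """Duplicating all rows (and doubling fixed penalties) changes nothing."""
        spec = ModelSpec(variant="TREND")
        lam = {
            "g1": 5.0, "g1_null": 5.0, "g1_slopes": 5.0, "g1_slopes_null": 5.0,
            "re_survey": 2.0, "re_country_bin": 2.0,
        }
        f1 = fit_full(tiny_pp, spec, fixed_lambdas=lam, irls_tol=1e-14)
        doubled = pd.concat([tiny_pp, tiny_pp], ignore_index=True)
        f2 = fit_full(
            doubled, spec, fixed_lambdas={k: 2 * v for k, v in lam.items()}, irls_tol=1e-14
        )
        q1 = predict_hazard(f1, tiny_pp.head(400)).point
        q2 = predict_hazard(f2, tiny_pp.head(400)).point
        np.testing.assert_allclose(q1, q2, rtol=1e-6)

    def test_missing_bin_rejected(self, tiny_pp):
        with pytest.raises(ValueError):
            fit_full(tiny_pp[tiny_pp["bin_index"] != 3], ModelSpec(variant="TREND"))

    @pytest.mark.parametrize("variant", ["ADD", "INT", "INDIV"])
    def test_all_variants_fit_and_predict(self, tiny_pp, variant):
        fitted = fit_full(tiny_pp, ModelSpec(variant=variant))
        pred = predict_hazard(fitted, tiny_pp.head(200))
        assert ((pred.point > 0) & (pred.point < 1)).all()

    def test_fit_by_region_stratifies(self, tiny_pp):
        fits = fit_by_region(
            tiny_pp, ModelSpec(variant="ADD"), region_map={"C00": "west", "C01": "east"}
        )
        assert set(fits) == {"west", "east"}


class TestPrediction:
    def test_all_zero_linear_predictor_gives_half(self, trend_fit):
        zeroed = FittedDTSA(
            design=trend_fit.design,
            beta=np.zeros_like(trend_fit.beta),
            cov=np.zeros_like(trend_fit.cov),
            sigma2_survey=0.0,
            sigma2_country_bin=0.0,
        )
        rows = pd.DataFrame(
            {
                "bin_index": [0],
                "birth_year": [2005],
                "sdi": [0.5],
                "survey_id": ["C00-2010"],
                "country": ["C00"],
            }
        )
        assert predict_hazard(zeroed, rows).point[0] == pytest.approx(0.5)

    def test_zero_covariance_draws_equal_point(self, trend_fit, tiny_pp):
        frozen = FittedDTSA(
            design=trend_fit.design,
            beta=trend_fit.beta,
            cov=np.zeros_like(trend_fit.cov),
            sigma2_survey=0.0,
            sigma2_country_bin=0.0,
        )
        rows = tiny_pp.head(50)
        pred = predict_hazard(frozen, rows, n_draws=20, seed=3)
        # equal up to the tiny jitter used to keep the Cholesky factorizable
        assert np.abs(pred.draws - pred.point[:, None]).max() < 1e-8

    def test_draw_mean_near_point_linear_predictor(self, trend_fit, tiny_pp):
        rows = tiny_pp.head(200)
        pred = predict_hazard(trend_fit, rows, n_draws=1000, seed=11)
        from scipy.special import logit

        eta_point = logit(pred.point)
        eta_draws = logit(pred.draws)
        se = eta_draws.std(axis=1) / np.sqrt(1000)
        ok = np.abs(eta_draws.mean(axis=1) - eta_point) < 3.5 * np.maximum(se, 1e-8)
        assert ok.mean() > 0.98

    def test_draws_reproducible_under_seed(self, trend_fit, tiny_pp):
        rows = tiny_pp.head(30)
        a = predict_hazard(trend_fit, rows, n_draws=25, seed=99)
        b = predict_hazard(trend_fit, rows, n_draws=25, seed=99)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_unseen_levels_flagged_and_handled(self, trend_fit, tiny_pp):
        rows = tiny_pp.head(10).copy()
        rows["survey_id"] = "never-seen"
        rows["country"] = "Z99"
        pred = predict_hazard(trend_fit, rows, n_draws=50, seed=5)
        assert pred.unseen_survey.all() and pred.unseen_country.all()
        assert np.isfinite(pred.point).all()
        # unseen-level draws add random-intercept noise, shared within a level
        assert pred.draws.std() > 0

    def test_out_of_range_year_flagged_not_refused(self, trend_fit, tiny_pp):
        rows = tiny_pp.head(5).copy()
        rows["birth_year"] = 2050
        pred = predict_hazard(trend_fit, rows)
        assert pred.extrapolated.all()
        assert np.isfinite(pred.point).all()


class TestSerialization:
    def test_json_round_trip_bit_exact(self, trend_fit, tiny_pp, tmp_path):
        path = tmp_path / "model.json"
        trend_fit.to_json(path)
        back = FittedDTSA.from_json(path)
        np.testing.assert_array_equal(back.beta, trend_fit.beta)
        np.testing.assert_array_equal(back.cov, trend_fit.cov)
        rows = tiny_pp.head(100)
        np.testing.assert_array_equal(
            predict_hazard(back, rows).point, predict_hazard(trend_fit, rows).point
        )
        a = predict_hazard(back, rows, n_draws=10, seed=1).draws
        b = predict_hazard(trend_fit, rows, n_draws=10, seed=1).draws
        np.testing.assert_array_equal(a, b)


def test_survey_variance_component_recovery():
    """Survey intercept variance recovered within a factor of 2 at 100 surveys.

    The TREND variant is used because the mother-level CD/CEB covariate, by
    construction, absorbs survey-level mortality differences and with it much
    of the survey intercept variance.
    """
    cfg = sm.SimulationConfig(
        n_countries=25,
        n_surveys_per_country=4,
        n_mothers_per_survey=60,
        survey_years=(2000, 2005, 2010, 2015),
        survey_re_sd=0.4,
        frailty_sd=0.0,
        country_bin_re_sd=0.0,
        seed=13,
    )
    mothers, children, sdi, _ = sm.simulate_population(cfg)
    pp = sm.reshape_to_person_period(children, mothers, sdi)
    fitted = fit_full(pp, ModelSpec(variant="TREND"))
    assert 0.5 * 0.16 <= fitted.sigma2_survey <= 2.0 * 0.16
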