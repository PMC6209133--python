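import numpy as np
import pandas as pd
import pytest

import sbhmort as sm
from sbhmort.age_bins import BEYOND_UNDER5, DEFAULT_SCHEME, coded_age_to_days, months_to_days
from sbhmort.birth_history import reshape_to_person_period, tabulate_direct_hazards

from conftest import make_random_children


def brute_force_person_period(children, mothers, scheme=DEFAULT_SCHEME):
    """Independent bin-walk oracle: one child at a time, pure python."""
    m = mothers.set_index("mother_id")
    rows = []
    for rec in children.itertuples():
        if rec.mother_id not in m.index:
            continue
        if rec.alive:
            days = months_to_days(float(rec.age_months))
            for a, (_, start, end) in enumerate(scheme.bins):
                if end <= days:
                    rows.append((rec.child_id, a, 0))
        else:
            days = coded_age_to_days(rec.aod_unit, float(rec.aod_value))
            death_bin = scheme.index_for_days(days)
            if death_bin == BEYOND_UNDER5:
                for a in range(scheme.n_bins):
                    rows.append((rec.child_id, a, 0))
            else:
                for a in range(death_bin + 1):
                    rows.append((rec.child_id, a, int(a == death_bin)))
    return sorted(rows)


def simple_mother(mother_id="m1", survey_year=2015, age=30, ceb=2, cd=1):
    return pd.DataFrame(
        {
            "mother_id": [mother_id],
            "survey_id": ["S"],
            "country": ["X"],
            "survey_year": [survey_year],
            "age_at_survey": [age],
            "ceb": [ceb],
            "cd": [cd],
            "survey_weight": [1.0],
        }
    )


def make_child(child_id="c1", birth_year=2014, alive=False, unit="days", value=15, age_months=None):
    return pd.DataFrame(
        {
            "child_id": [child_id],
            "mother_id": ["m1"],
            "birth_year": [birth_year],
            "alive": [alive],
            "aod_unit": [unit if not alive else ""],
            "aod_value": [value if not alive else np.nan],
            "age_months": [age_months],
        }
    )


class TestReshape:
    def test_neonatal_death_single_row(self):
        pp = reshape_to_person_period(make_child(unit="days", value=15), simple_mother())
        assert len(pp) == 1
        assert pp.iloc[0]["bin_index"] == 0 and pp.iloc[0]["death"] == 1

    def test_living_child_36_months_five_rows(self):
        pp = reshape_to_person_period(
            make_child(alive=True, birth_year=2012, age_months=36.0), simple_mother()
        )
        assert list(pp["bin_index"]) == [0, 1, 2, 3, 4]
        assert pp["death"].sum() == 0

    def test_death_at_14_months_four_rows(self):
        pp = reshape_to_person_period(make_child(unit="months", value=14), simple_mother())
        assert list(pp["bin_index"]) == [0, 1, 2, 3]
        assert list(pp["death"]) == [0, 0, 0, 1]

    def test_death_beyond_under5_counts_as_survivor_everywhere(self):
        pp = reshape_to_person_period(make_child(unit="years", value=6), simple_mother())
        assert list(pp["bin_index"]) == list(range(7))
        assert pp["death"].sum() == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        children, mothers = make_random_children(1000, rng)
        pp = reshape_to_person_period(children, mothers)
        got = sorted(zip(pp["child_id"], pp["bin_index"], pp["death"]))
        assert got == brute_force_person_period(children, mothers)

    def test_order_independence(self):
        rng = np.random.default_rng(5)
        children, mothers = make_random_children(300, rng)
        pp1 = reshape_to_person_period(children, mothers)
        perm = children.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pp2 = reshape_to_person_period(perm, mothers)
        key = ["child_id", "bin_index"]
        a = pp1.sort_values(key).reset_index(drop=True)
        b = pp2.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b[a.columns])

    def test_death_indicator_sums(self, tiny_population, tiny_pp):
        """Per child, the death indicators sum to 1 iff it died under 5."""
        sums = tiny_pp.groupby("child_id")["death"].sum()
        assert set(sums.unique()) <= {0, 1}
        children = tiny_population["children"]
        died_u5 = children[
            (~children["alive"])
        ]["child_id"]
        # every death in the generated data is under 5 by construction
        assert sums.reindex(died_u5).fillna(0).sum() == len(died_u5)

    def test_covariates_attached(self, tiny_pp):
        assert tiny_pp["sdi"].between(0, 1).all()
        assert (tiny_pp["ceb_at_birth"] >= 1).all()
        assert (tiny_pp["mother_age_at_birth"] >= 12).all()

    def test_ceb_at_birth_counts_same_year_siblings(self):
        children = pd.concat(
            [
                make_child("c1", birth_year=2010, alive=True, age_months=60.0),
                make_child("c2", birth_year=2010, alive=True, age_months=60.0),
                make_child("c3", birth_year=2013, alive=True, age_months=24.0),
            ]
        )
        pp = reshape_to_person_period(children, simple_mother(ceb=3, cd=0))
        got = pp.groupby("child_id")["ceb_at_birth"].first()
        assert got["c1"] == 2 and got["c2"] == 2 and got["c3"] == 3

    def test_invalid_mothers_dropped(self):
        bad = simple_mother(ceb=1, cd=2)  # cd > ceb
        pp = reshape_to_person_period(make_child(), bad)
        assert len(pp) == 0

    def test_missing_sdi_error_or_skip(self):
        sdi = pd.DataFrame({"country": ["X"], "year": [1900], "sdi": [0.4]})
        with pytest.raises(ValueError):
            reshape_to_person_period(make_child(), simple_mother(), sdi, on_missing_sdi="error")
        pp = reshape_to_person_period(make_child(), simple_mother(), sdi, on_missing_sdi="skip")
        assert len(pp) == 0


class TestDirectTabulation:
    def _cohort(self, n=10, n_deaths=1):
        rows = []
        for i in range(n):
            alive = i >= n_deaths
            rows.append(
                {
                    "child_id": f"c{i}",
                    "mother_id": "m1",
                    "birth_year": 2008,
                    "alive": alive,
                    "aod_unit": "" if alive else "days",
                    "aod_value": np.nan if alive else 10,
                    "age_months": 84.0 if alive else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def test_single_cohort_hazards(self):
        mothers = simple_mother(ceb=10, cd=1)
        out = tabulate_direct_hazards(self._cohort(), mothers)
        nn = out[out["bin_index"] == 0].iloc[0]
        assert nn["n"] == 10 and nn["d"] == 1 and nn["q"] == pytest.approx(0.1)
        later = out[out["bin_index"] > 0]
        assert (later["q"] == 0).all()
        assert (later["n"] == 9).all()

    def test_five_year_pooling_is_noop_for_single_year(self):
        mothers = simple_mother(ceb=10, cd=1)
        annual = tabulate_direct_hazards(self._cohort(), mothers, period_width=1)
        pooled = tabulate_direct_hazards(self._cohort(), mothers, period_width=5)
        assert np.allclose(
            annual.sort_values("bin_index")["q"], pooled.sort_values("bin_index")["q"]
        )

    def test_recovers_constant_hazards_within_binomial_error(self, flat_population):
        """Tabulated q from a flat-hazard cohort sits within 3 binomial SE."""
        p = flat_population
        out = tabulate_direct_hazards(p["children"], p["mothers"], group_by="survey_id")
        agg = out.groupby("bin_index")[["n", "d"]].sum()
        q_true = np.array(p["config"].baseline_q)
        q_hat = agg["d"] / agg["n"]
        se = np.sqrt(q_true * (1 - q_true) / agg["n"])
        assert (np.abs(q_hat - q_true) < 3 * se).all()

    def test_total_deaths_match_cd(self, tiny_population):
        p = tiny_population
        out = tabulate_direct_hazards(p["children"], p["mothers"])
        assert out["d"].sum() == p["mothers"]["cd"].sum()
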