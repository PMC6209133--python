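import numpy as np
import pandas as pd
import pytest

import sbhmort as sm


@pytest.fixture(scope="session")
def tiny_population():
    """Small but full-featured synthetic population (2 countries x 2 surveys)."""
    cfg = sm.SimulationConfig(
        n_countries=2, n_surveys_per_country=2, n_mothers_per_survey=400, seed=42
    )
    mothers, children, sdi, truth = sm.simulate_population(cfg)
    return {"config": cfg, "mothers": mothers, "children": children, "sdi": sdi, "truth": truth}


@pytest.fixture(scope="session")
def tiny_pp(tiny_population):
    p = tiny_population
    return sm.reshape_to_person_period(p["children"], p["mothers"], p["sdi"], p["config"].scheme)


@pytest.fixture(scope="session")
def flat_population():
    """Population with constant hazards and no heterogeneity (~20k children)."""
    cfg = sm.SimulationConfig(
        n_countries=2,
        n_surveys_per_country=2,
        n_mothers_per_survey=2000,
        year_slope=(0.0,) * 7,
        sdi_effect=0.0,
        frailty_sd=0.0,
        survey_re_sd=0.0,
        country_bin_re_sd=0.0,
        seed=7,
    )
    mothers, children, sdi, truth = sm.simulate_population(cfg)
    return {"config": cfg, "mothers": mothers, "children": children, "sdi": sdi, "truth": truth}


@pytest.fixture(scope="session")
def holdout_result():
    """The full desk-scale holdout experiment (shared by several tests)."""
    return sm.run_holdout_experiment(seed=1)


def make_random_children(n, rng, survey_year=2015):
    """Random raw child records exercising every coding path."""
    mother_ids = [f"m{i}" for i in rng.integers(0, max(n // 3, 1), size=n)]
    birth_year = rng.integers(survey_year - 30, survey_year + 1, size=n)
    alive = rng.random(n) < 0.8
    unit = rng.choice(["days", "months", "years"], size=n)
    value = np.where(
        unit == "days",
        rng.integers(0, 40, size=n),
        np.where(unit == "months", rng.integers(0, 30, size=n), rng.integers(0, 7, size=n)),
    )
    children = pd.DataFrame(
        {
            "child_id": [f"c{i}" for i in range(n)],
            "mother_id": mother_ids,
            "birth_year": birth_year,
            "alive": alive,
            "aod_unit": np.where(alive, "", unit),
            "aod_value": np.where(alive, np.nan, value),
            "age_months": np.where(alive, 12 * (survey_year - birth_year), np.nan),
        }
    )
    mids = sorted(set(mother_ids))
    mothers = pd.DataFrame(
        {
            "mother_id": mids,
            "survey_id": "S1",
            "country": "X",
            "survey_year": survey_year,
            "age_at_survey": rng.integers(15, 50, size=len(mids)),
            "ceb": 30,  # upper bound; per-mother counts are not needed here
            "cd": 0,
            "survey_weight": 1.0,
        }
    )
    return children, mothers
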