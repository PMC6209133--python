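"""Synthetic paired CBH/SBH data with known ground-truth hazards.

The generator emulates a multi-country collection of household surveys.  Each
woman gets a survey, an age, and a birth history drawn from hump-shaped
age-specific fertility rates; each child's death bin is sampled sequentially
from discrete hazards that are logit-additive in birth year, country-year
development (SDI), mother frailty, and survey / country-bin random
intercepts — the same additive structure the estimation model assumes, so
recovery studies are well-posed.  A ``misspecified`` switch adds a
non-additive SDI-by-mother-age interaction to exercise robustness.

Ages at death are coded the way CBH surveys record them (days under 1 month,
months under 2 years, completed years after), and living children report age
in months, so the generated tables round-trip the person-period reshape
exactly.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_bins import DEFAULT_SCHEME, AgeBinScheme, months_to_days
from scipy.special import expit, logit

# annual birth probability by single year of age (hump peaking in the 20s;
# lifetime total ~5 births, typical of high-mortality settings)
_DEFAULT_ASFR = {
    (12, 14): 0.02,
    (15, 19): 0.10,
    (20, 24): 0.25,
    (25, 29): 0.25,
    (30, 34): 0.20,
    (35, 39): 0.13,
    (40, 44): 0.06,
    (45, 49): 0.02,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Defaults give the desk-scale design: 4 countries, 2 survey rounds five
    years apart with collection years staggered across countries (2008/2013
    through 2011/2016, as real survey programmes are spread), 5,000 women
    per survey; per-bin baseline hazards at levels typical of the surveyed
    countries; mortality declining on the logit scale both secularly and
    with rising SDI.
    """

    n_countries: int = 4
    n_surveys_per_country: int = 2
    n_mothers_per_survey: int = 5000
    survey_years: tuple = (2010, 2015)
    #: per-country year offsets applied cyclically to every round, emulating
    #: the staggered timing of real survey programmes across countries
    survey_year_stagger: tuple = (-2, -1, 0, 1)
    sdi_start: tuple = (0.25, 0.40, 0.55, 0.70)
    sdi_slope: float = 0.007
    baseline_q: tuple = (0.031, 0.015, 0.013, 0.013, 0.009, 0.006, 0.003)
    year_slope: tuple = (-0.02, -0.03, -0.03, -0.04, -0.04, -0.04, -0.04)
    ref_year: int = 2000
    sdi_effect: float = -2.5
    sdi_ref: float = 0.5
    frailty_sd: float = 0.2
    survey_re_sd: float = 0.05
    country_bin_re_sd: float = 0.10
    asfr: dict = field(default_factory=lambda: dict(_DEFAULT_ASFR))
    max_ceb: int = 15
    mother_age_range: tuple = (15, 49)
    min_mother_age: int = 12
    survey_weight_sd: float = 0.0
    misspecified: bool = False
    seed: int = 0
    scheme: AgeBinScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        if len(self.survey_years) != self.n_surveys_per_country:
            raise ValueError("survey_years must list one year per survey round")
        if not self.survey_year_stagger:
            self.survey_year_stagger = (0,)
        if len(self.baseline_q) != self.scheme.n_bins:
            raise ValueError("baseline_q must match the bin scheme")
        if not all(0 < q < 1 for q in self.baseline_q):
            raise ValueError("baseline hazards must lie in (0, 1)")

    def survey_years_for(self, country_index: int) -> tuple:
        off = self.survey_year_stagger[country_index % len(self.survey_year_stagger)]
        return tuple(int(y) + int(off) for y in self.survey_years)

    def asfr_at(self, age: np.ndarray) -> np.ndarray:
        out = np.zeros(np.shape(age))
        a = np.asarray(age)
        for (lo, hi), rate in self.asfr.items():
            out = np.where((a >= lo) & (a <= hi), rate, out)
        return out


@dataclass
class GroundTruth:
    """True hazards underlying a simulated population.

    ``trends`` is the population-level estimand per (country, birth year,
    bin): the birth-weighted mean true hazard excluding the survey intercept
    (a survey-specific idiosyncrasy).  ``child_hazards`` are the per-child
    hazards actually used to sample deaths, survey intercept included.
    """

    trends: pd.DataFrame  # country, year, bin_index, q_true, births
    child_hazards: np.ndarray  # (n_children, A), aligned with children table
    config: SimulationConfig
    country_bin_effects: pd.DataFrame | None = None  # realized eta per (country, bin)
    survey_effects: pd.DataFrame | None = None  # realized nu per survey

    def true_5q0(self) -> pd.DataFrame:
        piv = self.trends.pivot_table(
            index=["country", "year"], columns="bin_index", values="q_true"
        ).sort_index(axis=1)
        q5 = 1.0 - np.prod(1.0 - piv.to_numpy(), axis=1)
        out = piv.reset_index()[["country", "year"]]
        out["q_true"] = q5
        return out


def make_sdi_table(config: SimulationConfig, years=None) -> pd.DataFrame:
    """Monotone SDI trajectories per country (clipped to [0.05, 0.95])."""
    if years is None:
        span = max(abs(int(o)) for o in config.survey_year_stagger)
        last = max(config.survey_years) + span
        first = (
            min(config.survey_years)
            - span
            - (config.mother_age_range[1] - config.min_mother_age)
            - 1
        )
        years = np.arange(first, last + 1)
    rows = []
    for c in range(config.n_countries):
        start = config.sdi_start[c % len(config.sdi_start)]
        for y in years:
            sdi = np.clip(start + config.sdi_slope * (y - 1990), 0.05, 0.95)
            rows.append((f"C{c:02d}", int(y), float(sdi)))
    return pd.DataFrame(rows, columns=["country", "year", "sdi"])


def _true_logit_hazard(config, bin_idx, birth_year, sdi, frailty, nu, eta, mother_age):
    lq = (
        logit(np.asarray(config.baseline_q)[bin_idx])
        + np.asarray(config.year_slope)[bin_idx] * (birth_year - config.ref_year)
        + config.sdi_effect * (sdi - config.sdi_ref)
        + frailty
        + nu
        + eta
    )
    if config.misspecified:
        lq = lq + 0.5 * (sdi - config.sdi_ref) * (mother_age - 25.0) / 10.0
    return lq


def simulate_population(config: SimulationConfig):
    """Simulate (mothers, children, sdi, ground_truth).

    Women (including the childless) form the mother table; every recorded
    birth becomes a child row with CBH-coded outcome.  Ground-truth trends
    are the per-(country, birth-year, bin) means of each born child's true
    hazard — the quantity a direct tabulation estimates in expectation.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    A = scheme.n_bins
    starts, ends = scheme.starts, scheme.ends

    sdi_df = make_sdi_table(config)
    sdi_lut = {(r.country, r.year): r.sdi for r in sdi_df.itertuples()}

    countries = [f"C{c:02d}" for c in range(config.n_countries)]
    eta = rng.normal(0.0, config.country_bin_re_sd, size=(config.n_countries, A))
    eta_df = pd.DataFrame(
        [(countries[c], a, eta[c, a]) for c in range(config.n_countries) for a in range(A)],
        columns=["country", "bin_index", "eta"],
    )
    nu_rows = []

    mothers_rows = []
    child_frames = []
    hazard_blocks = []
    pop_hazard_blocks = []
    mother_counter = 0
    child_counter = 0

    age_lo, age_hi = config.mother_age_range
    ages_all = np.arange(age_lo, age_hi + 1)
    age_weights = np.linspace(1.0, 0.6, len(ages_all))
    age_weights = age_weights / age_weights.sum()

    for ci, country in enumerate(countries):
        for si, survey_year in enumerate(config.survey_years_for(ci)):
            survey_id = f"{country}-{survey_year}"
            nu = rng.normal(0.0, config.survey_re_sd)
            nu_rows.append((survey_id, nu))
            nm = config.n_mothers_per_survey
            age_at_survey = rng.choice(ages_all, size=nm, p=age_weights)
            frailty = rng.normal(0.0, config.frailty_sd, size=nm)
            if config.survey_weight_sd > 0:
                sw = rng.lognormal(
                    -0.5 * config.survey_weight_sd**2, config.survey_weight_sd, size=nm
                )
            else:
                sw = np.ones(nm)
            mother_ids = np.array(
                [f"M{mother_counter + i:07d}" for i in range(nm)]
            )
            mother_counter += nm

            # birth histories: Bernoulli at each age from min_mother_age to age now
            max_span = age_hi - config.min_mother_age + 1
            ages_grid = config.min_mother_age + np.arange(max_span)[None, :]
            exposed = ages_grid <= age_at_survey[:, None]
            p_birth = config.asfr_at(ages_grid) * exposed
            births = rng.random((nm, max_span)) < p_birth
            # cap CEB (drop the earliest surplus births)
            ceb_raw = births.sum(axis=1)
            over = np.where(ceb_raw > config.max_ceb)[0]
            for i in over:
                idx = np.where(births[i])[0]
                births[i, idx[: len(idx) - config.max_ceb]] = False

            mrow, aidx = np.where(births)
            birth_age = config.min_mother_age + aidx
            birth_year = survey_year - (age_at_survey[mrow] - birth_age)
            n_children = len(mrow)
            child_ids = np.array(
                [f"K{child_counter + i:08d}" for i in range(n_children)]
            )
            child_counter += n_children

            sdi_by = np.array([sdi_lut[(country, int(y))] for y in birth_year])
            bin_grid = np.arange(A)
            lq = _true_logit_hazard(
                config,
                bin_grid[None, :],
                birth_year[:, None],
                sdi_by[:, None],
                frailty[mrow][:, None],
                nu,
                eta[ci][None, :],
                birth_age[:, None],
            )
            q_true = np.clip(expit(lq), 1e-12, 1 - 1e-12)
            # population-level hazard: the survey intercept nu is a
            # survey-specific idiosyncrasy, not part of the country trend
            q_pop = np.clip(expit(lq - nu), 1e-12, 1 - 1e-12)

            # exposure: full bins survived, fractional risk in the current bin
            att_days = months_to_days(12 * (survey_year - birth_year))
            frac = np.clip(
                (att_days[:, None] - starts[None, :]) / (ends - starts)[None, :], 0.0, 1.0
            )
            u = rng.random((n_children, A))
            died = u < q_true * frac
            any_death = died.any(axis=1)
            death_bin = np.where(any_death, died.argmax(axis=1), -1)

            # code ages at death in the CBH convention
            aod_unit = np.full(n_children, "", dtype=object)
            aod_value = np.full(n_children, np.nan)
            if any_death.any():
                db = death_bin[any_death]
                lo = starts[db]
                hi = np.minimum(ends[db], att_days[any_death])
                dd = lo + np.floor(rng.random(any_death.sum()) * np.maximum(hi - lo, 1)).astype(int)
                unit = np.where(dd < 29, "days", np.where(dd < 730, "months", "years"))
                months = np.maximum(dd // 30.44, 1).astype(int)
                years = (dd // 365).astype(int)
                # completed-unit coding can slip a boundary day into the bin
                # below; bump so decoded ages stay in the death bin
                m_recon = np.rint(30.44 * months).astype(int)
                months = months + (scheme.index_for_days(m_recon) < scheme.index_for_days(dd))
                y_recon = np.rint(365.25 * years).astype(int)
                years = years + (scheme.index_for_days(y_recon) < scheme.index_for_days(dd))
                val = np.where(dd < 29, dd, np.where(dd < 730, months, years)).astype(int)
                aod_unit[any_death] = unit
                aod_value[any_death] = val

            children = pd.DataFrame(
                {
                    "child_id": child_ids,
                    "mother_id": mother_ids[mrow],
                    "birth_year": birth_year.astype(int),
                    "alive": ~any_death,
                    "aod_unit": aod_unit,
                    "aod_value": aod_value,
                    "age_months": np.where(
                        any_death, np.nan, 12.0 * (survey_year - birth_year)
                    ),
                    "country": country,
                }
            )
            child_frames.append(children)
            hazard_blocks.append(q_true)
            pop_hazard_blocks.append(q_pop)

            cd = pd.Series(any_death).groupby(pd.Series(mother_ids[mrow])).sum()
            ceb = pd.Series(np.ones(n_children)).groupby(pd.Series(mother_ids[mrow])).sum()
            mdf = pd.DataFrame(
                {
                    "mother_id": mother_ids,
                    "survey_id": survey_id,
                    "country": country,
                    "survey_year": survey_year,
                    "age_at_survey": age_at_survey,
                    "ceb": pd.Series(mother_ids).map(ceb).fillna(0).astype(int).to_numpy(),
                    "cd": pd.Series(mother_ids).map(cd).fillna(0).astype(int).to_numpy(),
                    "survey_weight": sw,
                }
            )
            mothers_rows.append(mdf)

    mothers = pd.concat(mothers_rows, ignore_index=True)
    children = pd.concat(child_frames, ignore_index=True)
    child_hazards = np.vstack(hazard_blocks) if hazard_blocks else np.empty((0, A))
    pop_hazards = np.vstack(pop_hazard_blocks) if pop_hazard_blocks else np.empty((0, A))

    gt_df = children[["country", "birth_year"]].copy()
    trends = []
    for a in range(A):
        gt_df["q"] = pop_hazards[:, a]
        agg = gt_df.groupby(["country", "birth_year"], as_index=False).agg(
            q_true=("q", "mean"), births=("q", "size")
        )
        agg["bin_index"] = a
        trends.append(agg)
    trends = pd.concat(trends, ignore_index=True).rename(columns={"birth_year": "year"})

    ground_truth = GroundTruth(
        trends=trends,
        child_hazards=child_hazards,
        config=config,
        country_bin_effects=eta_df,
        survey_effects=pd.DataFrame(nu_rows, columns=["survey_id", "nu"]),
    )
    return mothers, children.drop(columns="country"), sdi_df, ground_truth


def derive_sbh_view(mothers: pd.DataFrame, children: pd.DataFrame, include_childless: bool = True) -> pd.DataFrame:
    """Collapse a CBH to its summary view: per-mother CEB and CD only.

    CEB and CD are re-derived from the child table (not copied from the
    mother table), so the view is a deterministic function of the CBH.
    """
    counts = children.groupby("mother_id").agg(
        ceb=("child_id", "size"), cd=("alive", lambda s: int((~s.astype(bool)).sum()))
    )
    sbh = mothers.drop(columns=[c for c in ("ceb", "cd") if c in mothers.columns]).merge(
        counts, left_on="mother_id", right_index=True, how="left"
    )
    sbh[["ceb", "cd"]] = sbh[["ceb", "cd"]].fillna(0).astype(int)
    if not include_childless:
        sbh = sbh[sbh["ceb"] > 0].reset_index(drop=True)
    return sbh


def make_holdout_split(surveys: pd.DataFrame, rule: str = "most-recent-per-country"):
    """Split surveys into (train, test): test = latest survey per country.

    ``surveys`` needs ``survey_id, country, survey_year``.  Countries with a
    single survey contribute no test survey.  Ties on year break by survey id
    so the split is deterministic.
    """
    if rule != "most-recent-per-country":
        raise ValueError(f"unknown holdout rule: {rule}")
    s = surveys.drop_duplicates("survey_id").sort_values(
        ["country", "survey_year", "survey_id"]
    )
    latest = s.groupby("country").tail(1)
    counts = s.groupby("country")["survey_id"].transform("size")
    eligible = latest[latest["country"].isin(s.loc[counts > 1, "country"])]
    test = eligible.reset_index(drop=True)
    train = s[~s["survey_id"].isin(test["survey_id"])].reset_index(drop=True)
    if len(test) == 0:
        import logging

        logging.getLogger(__name__).warning("no country has more than one survey; empty test set")
    return train, test


def survey_table(mothers: pd.DataFrame) -> pd.DataFrame:
    """Unique (survey_id, country, survey_year) rows from a mother table."""
    return mothers[["survey_id", "country", "survey_year"]].drop_duplicates().reset_index(drop=True)
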