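"""Birth-history tables, person-period reshaping, and direct tabulation.

Complete birth histories (CBH) are held as two pandas DataFrames:

``mothers``
    one row per woman: ``mother_id, survey_id, country, region, admin1_area,
    survey_year, age_at_survey, ceb, cd, survey_weight`` (``region`` and
    ``admin1_area`` optional).
``children``
    one row per recorded birth: ``child_id, mother_id, birth_year, alive,
    aod_unit, aod_value, age_months`` where exactly one of the coded age at
    death (``aod_unit``/``aod_value``) and the current age (``age_months``)
    is populated.

The person-period reshape turns each child into one row per age bin entered,
with a death indicator that is 1 only on the death bin.  Censored bins — the
bin a living child currently occupies, and everything after it — are dropped
rather than fractionally weighted, the usual discrete-time survival
convention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .age_bins import (
    BEYOND_UNDER5,
    DEFAULT_SCHEME,
    AgeBinScheme,
    coded_age_to_days,
    months_to_days,
)

logger = logging.getLogger(__name__)

MOTHER_COLUMNS = [
    "mother_id",
    "survey_id",
    "country",
    "survey_year",
    "age_at_survey",
    "ceb",
    "cd",
    "survey_weight",
]

CHILD_COLUMNS = [
    "child_id",
    "mother_id",
    "birth_year",
    "alive",
    "aod_unit",
    "aod_value",
    "age_months",
]

PERSON_PERIOD_COLUMNS = [
    "child_id",
    "mother_id",
    "bin_index",
    "death",
    "birth_year",
    "sdi",
    "cd_over_ceb",
    "ceb_at_birth",
    "mother_age_at_birth",
    "survey_id",
    "country",
    "survey_year",
    "survey_weight",
]


def validate_mothers(mothers: pd.DataFrame) -> pd.DataFrame:
    """Drop invalid mother rows (cd > ceb, missing CEB, negative weight).

    Dropped counts are logged, never silent.
    """
    df = mothers.copy()
    n0 = len(df)
    bad = df["ceb"].isna() | df["cd"].isna() | (df["cd"] > df["ceb"]) | (df["cd"] < 0)
    if "survey_weight" in df:
        bad |= df["survey_weight"] < 0
    df = df[~bad]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("dropped %d invalid mother records (cd>ceb / missing)", dropped)
    return df


def _merge_children_mothers(children: pd.DataFrame, mothers: pd.DataFrame) -> pd.DataFrame:
    mcols = [c for c in mothers.columns if c not in children.columns or c == "mother_id"]
    df = children.merge(mothers[mcols], on="mother_id", how="left", validate="m:1")
    if df["survey_year"].isna().any():
        missing = df["survey_year"].isna().sum()
        raise ValueError(f"{missing} children reference mothers absent from the mother table")
    return df


def _attained_days(df: pd.DataFrame) -> np.ndarray:
    """Days of exposure for living children, from their age in months."""
    months = df["age_months"].to_numpy(dtype=float)
    months = np.where(np.isnan(months), 0.0, months)
    return months_to_days(months)


def reshape_to_person_period(
    children: pd.DataFrame,
    mothers: pd.DataFrame,
    sdi_table: pd.DataFrame | None = None,
    scheme: AgeBinScheme = DEFAULT_SCHEME,
    on_missing_sdi: str = "error",
) -> pd.DataFrame:
    """Reshape CBH data into one row per (child, age bin entered).

    A child who died in bin *k* yields *k*+1 rows with the death indicator set
    on the last; a living child yields one row per bin fully survived.  Deaths
    at age 5+ count as survivors of all bins.  Covariates are attached per
    row: mother's age at the birth year, the mother's survey-time CD/CEB, the
    running count of her births up to (and including) the child's birth year,
    and the country-year development index (SDI) if a table is given.

    Parameters
    ----------
    on_missing_sdi
        ``"error"`` raises when a (country, birth_year) has no SDI;
        ``"skip"`` drops those children with a logged count.
    """
    mothers = validate_mothers(mothers)
    children = children[children["mother_id"].isin(mothers["mother_id"])]
    df = _merge_children_mothers(children, mothers)
    n = len(df)
    if n == 0:
        return pd.DataFrame(columns=PERSON_PERIOD_COLUMNS)

    ends = scheme.ends
    A = scheme.n_bins

    alive = df["alive"].to_numpy(dtype=bool)
    # Death bin (BEYOND_UNDER5 for deaths past the last boundary).
    death_bin = np.full(n, BEYOND_UNDER5, dtype=int)
    if (~alive).any():
        dead = df[~alive]
        days = coded_age_to_days(
            dead["aod_unit"].to_numpy(), dead["aod_value"].to_numpy(dtype=float)
        )
        death_bin[~alive] = scheme.index_for_days(days)

    # Number of person-period rows per child.
    n_rows = np.zeros(n, dtype=int)
    died_under5 = (~alive) & (death_bin >= 0)
    n_rows[died_under5] = death_bin[died_under5] + 1
    survived_all = (~alive) & (death_bin == BEYOND_UNDER5)
    n_rows[survived_all] = A
    if alive.any():
        att = _attained_days(df)[alive]
        n_rows[alive] = np.searchsorted(ends, att, side="right")

    keep = n_rows > 0
    df = df[keep].reset_index(drop=True)
    n_rows = n_rows[keep]
    death_bin = death_bin[keep]
    died_under5 = died_under5[keep]
    if len(df) == 0:
        return pd.DataFrame(columns=PERSON_PERIOD_COLUMNS)

    # Mother-level covariates at child level.
    ceb = df["ceb"].to_numpy(dtype=float)
    cd = df["cd"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cd_over_ceb = np.where(ceb > 0, cd / np.maximum(ceb, 1.0), 0.0)
    mother_age_at_birth = (
        df["age_at_survey"].to_numpy(dtype=float)
        - (df["survey_year"].to_numpy(dtype=float) - df["birth_year"].to_numpy(dtype=float))
    )
    # Running birth count: births with birth_year <= this child's, ties counted
    # on both (same-year siblings each see the other).
    ceb_at_birth = (
        df.groupby("mother_id")["birth_year"].rank(method="max").to_numpy(dtype=float)
    )

    child_level = pd.DataFrame(
        {
            "child_id": df["child_id"].to_numpy(),
            "mother_id": df["mother_id"].to_numpy(),
            "birth_year": df["birth_year"].to_numpy(),
            "cd_over_ceb": cd_over_ceb,
            "ceb_at_birth": ceb_at_birth,
            "mother_age_at_birth": mother_age_at_birth,
            "survey_id": df["survey_id"].to_numpy(),
            "country": df["country"].to_numpy(),
            "survey_year": df["survey_year"].to_numpy(),
            "survey_weight": df.get(
                "survey_weight", pd.Series(1.0, index=df.index)
            ).to_numpy(dtype=float),
        }
    )
    for extra in ("region", "admin1_area"):
        if extra in df.columns:
            child_level[extra] = df[extra].to_numpy()

    # Expand to person-period rows.
    total = int(n_rows.sum())
    starts = np.repeat(np.cumsum(n_rows) - n_rows, n_rows)
    bin_index = np.arange(total) - starts
    death = np.zeros(total, dtype=np.int8)
    last_row = np.cumsum(n_rows) - 1
    death[last_row[died_under5]] = 1

    pp = child_level.loc[np.repeat(np.arange(len(df)), n_rows)].reset_index(drop=True)
    pp.insert(2, "bin_index", bin_index)
    pp.insert(3, "death", death)

    if sdi_table is not None:
        sdi = sdi_table.rename(columns={"year": "birth_year"})
        pp = pp.merge(sdi[["country", "birth_year", "sdi"]], on=["country", "birth_year"], how="left")
        miss = pp["sdi"].isna()
        if miss.any():
            n_children = pp.loc[miss, "child_id"].nunique()
            if on_missing_sdi == "skip":
                logger.warning("dropping %d children with missing SDI", n_children)
                bad_ids = pp.loc[miss, "child_id"].unique()
                pp = pp[~pp["child_id"].isin(bad_ids)].reset_index(drop=True)
            else:
                raise ValueError(f"missing SDI for {n_children} children")
    else:
        pp["sdi"] = np.nan

    front = [c for c in PERSON_PERIOD_COLUMNS if c in pp.columns]
    rest = [c for c in pp.columns if c not in front]
    return pp[front + rest]


def tabulate_direct_hazards(
    children: pd.DataFrame,
    mothers: pd.DataFrame,
    scheme: AgeBinScheme = DEFAULT_SCHEME,
    group_by: str | list[str] = "country",
    period_width: int = 1,
) -> pd.DataFrame:
    """Directly tabulate discrete hazards from CBH data.

    For every (group, period, bin): ``n`` children entering the bin (born in
    the period), ``d`` deaths within it, and ``q = d/n``.  With
    ``period_width=1`` the period is the birth year; wider widths pool birth
    cohorts by completed years before each survey (the convention used when
    small-area samples are too thin for annual estimates), labelling each
    period by its first calendar year.
    """
    if period_width not in (1, 5):
        raise ValueError("period_width must be 1 or 5")
    group_cols = [group_by] if isinstance(group_by, str) else list(group_by)
    pp = reshape_to_person_period(children, mothers, None, scheme)
    if len(pp) == 0:
        return pd.DataFrame(columns=group_cols + ["period", "bin_index", "n", "d", "q"])
    if period_width == 1:
        pp["period"] = pp["birth_year"]
    else:
        years_prior = pp["survey_year"] - pp["birth_year"]
        k = years_prior // period_width
        pp["period"] = pp["survey_year"] - period_width * (k + 1) + 1
    out = (
        pp.groupby(group_cols + ["period", "bin_index"], as_index=False)
        .agg(n=("death", "size"), d=("death", "sum"))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["q"] = np.where(out["n"] > 0, out["d"] / out["n"], np.nan)
    out["bin_label"] = [scheme.label_of(a) for a in out["bin_index"]]
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_mothers(path) -> pd.DataFrame:
    return validate_mothers(pd.read_csv(path))


def read_children(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["alive"] = df["alive"].astype(int).astype(bool)
    return df


def read_sdi(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"country", "year", "sdi"}
    if not need.issubset(df.columns):
        raise ValueError(f"SDI table must carry columns {sorted(need)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
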