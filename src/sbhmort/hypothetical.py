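"""Enumeration of hypothetical children for summary-birth-history mothers.

An SBH row tells us a mother's age, her children ever born (CEB) and children
died (CD) — but not when her children were born.  The indirect method
therefore predicts a hazard function for one *hypothetical* child per
calendar year of her reproductive life, from the survey year back to the year
she turned 12, and weights each by the empirical probability that a birth
actually fell in that year (POB).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pob import POBTable, ceb_class

logger = logging.getLogger(__name__)

HYPOTHETICAL_COLUMNS = [
    "mother_id",
    "survey_id",
    "country",
    "birth_year",
    "years_prior",
    "mother_age_at_birth",
    "ceb_at_birth",
    "cd_over_ceb",
    "sdi",
    "pob",
    "ceb",
    "survey_weight",
]


def enumerate_hypothetical_children(
    mothers: pd.DataFrame,
    sdi_table: pd.DataFrame | None,
    pob_table: POBTable,
    min_mother_age: int = 12,
    include_childless: bool = False,
) -> pd.DataFrame:
    """One hypothetical child per (mother, year) of reproductive life.

    Years run from the survey year back until the mother was
    ``min_mother_age``, giving ``age_at_survey - min_mother_age + 1`` children
    per mother.  Each carries its birth-year covariates (mother's age then,
    expected CEB at birth imputed from the POB distribution, her survey-time
    CD/CEB, country-year SDI) and its POB weight.

    Mothers with CEB 0 carry zero POB weight everywhere and are skipped by
    default; ``include_childless=True`` keeps them with ``pob = 0``.
    """
    m = mothers.copy()
    if not include_childless:
        m = m[m["ceb"] >= 1]
    if "region" not in m.columns:
        m["region"] = "all"
    m["region"] = m["region"].fillna("all")
    if len(m) == 0:
        return pd.DataFrame(columns=HYPOTHETICAL_COLUMNS)

    ages = m["age_at_survey"].to_numpy(int)
    n_child = np.maximum(ages - min_mother_age + 1, 1)
    rep = np.repeat(np.arange(len(m)), n_child)
    starts = np.repeat(np.cumsum(n_child) - n_child, n_child)
    t = np.arange(n_child.sum()) - starts  # completed years before the survey

    out = m.iloc[rep].reset_index(drop=True)
    out["years_prior"] = t
    out["birth_year"] = out["survey_year"].to_numpy(int) - t
    out["mother_age_at_birth"] = out["age_at_survey"].to_numpy(int) - t
    ceb = out["ceb"].to_numpy(float)
    cd = out["cd"].to_numpy(float)
    out["cd_over_ceb"] = np.where(ceb > 0, cd / np.maximum(ceb, 1.0), 0.0)

    # POB weight and expected CEB at birth, one table fetch per (region, age,
    # CEB-class) cell rather than per mother.
    pob = np.zeros(len(out))
    ceb_birth = np.ones(len(out))
    cell = pd.DataFrame(
        {
            "region": out["region"].to_numpy(),
            "age": out["age_at_survey"].to_numpy(int),
            "cls": ceb_class(out["ceb"]),
        }
    )
    max_t = pob_table.max_years_prior
    for (region, age, cls_), idx in cell.groupby(["region", "age", "cls"]).groups.items():
        vec = pob_table.vector(region, age, cls_)
        if vec is None:
            pob_table.missing_lookups += len(idx)
            continue
        tt = t[np.asarray(idx)]
        inside = tt <= max_t
        vals = np.zeros(len(tt))
        vals[inside] = vec[tt[inside]]
        pob[np.asarray(idx)] = vals
        # mass strictly earlier than the hypothetical birth
        tail = np.concatenate([np.cumsum(vec[::-1])[::-1][1:], [0.0]])
        earlier = np.where(inside, tail[np.minimum(tt, max_t)], 0.0)
        cb = 1.0 + ceb[np.asarray(idx)] * earlier
        ceb_birth[np.asarray(idx)] = np.clip(
            cb, 1.0, np.maximum(ceb[np.asarray(idx)], 1.0)
        )
    out["pob"] = pob
    out["ceb_at_birth"] = ceb_birth

    if sdi_table is not None:
        sdi = sdi_table.rename(columns={"year": "birth_year"})
        out = out.merge(
            sdi[["country", "birth_year", "sdi"]],
            on=["country", "birth_year"],
            how="left",
        )
        miss = out["sdi"].isna()
        if miss.any():
            logger.warning(
                "dropping %d hypothetical child-years with missing SDI", int(miss.sum())
            )
            out = out[~miss].reset_index(drop=True)
    else:
        out["sdi"] = np.nan

    if "survey_weight" not in out.columns:
        out["survey_weight"] = 1.0
    keep = [c for c in HYPOTHETICAL_COLUMNS if c in out.columns]
    extra = [c for c in ("region", "admin1_area") if c in out.columns]
    return out[keep + extra]
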