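"""Empirical probability-of-birth (POB) distributions.

For each cell (region, mother's age at survey, CEB class) the POB table holds
the distribution of that cell's recorded births over completed years before
the survey, normalized to sum to one over ``t in [0, max_years_prior]``.
These distributions weight hypothetical children — a woman aged 30 with CEB 4
is unlikely to have had a birth 17 years before the survey, so a hypothetical
child born then gets little weight — and supply the expected running birth
count (CEB at birth) for each hypothetical child.

CEB classes are exact counts 0-7 with 8+ pooled.  Sparse cells are resolved
at lookup time by backoff: pool CEB classes, then pool to adjacent single
ages (+-1), then pool regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CEB_CLASS_MAX = 8  # 8 encodes "8 or more"

_POOLED = "__all__"


def ceb_class(ceb) -> np.ndarray:
    """Map raw CEB counts to classes 0-7, 8+."""
    return np.minimum(np.asarray(ceb, dtype=int), CEB_CLASS_MAX)


@dataclass
class POBTable:
    """POB distributions keyed by (region, age at survey, CEB class).

    ``counts`` maps each key to a length ``max_years_prior + 1`` array of
    birth counts by completed years prior to the survey; probabilities are
    served normalized.  ``provenance`` records how the table was built.
    """

    counts: dict[tuple, np.ndarray]
    max_years_prior: int = 25
    provenance: str = ""
    _cache: dict = field(default_factory=dict, repr=False)
    missing_lookups: int = field(default=0, repr=False)

    # -- lookup ------------------------------------------------------------

    def vector(self, region, age_at_survey, ceb) -> np.ndarray | None:
        """Normalized POB vector for a mother, with documented backoff.

        Backoff order: exact cell -> pool CEB classes -> pool ages +-1 (CEB
        pooled) -> pool regions (exact age, then +-1).  Returns ``None`` only
        if every level is empty.
        """
        age = int(age_at_survey)
        cls = int(ceb_class(ceb))
        key = (region, age, cls)
        if key in self._cache:
            return self._cache[key]
        candidates = [
            [(region, age, cls)],
            [(region, age, _POOLED)],
            [(region, age - 1, _POOLED), (region, age + 1, _POOLED)],
            [(_POOLED, age, cls)],
            [(_POOLED, age, _POOLED)],
            [(_POOLED, age - 1, _POOLED), (_POOLED, age + 1, _POOLED)],
            [(_POOLED, _POOLED, _POOLED)],
        ]
        out = None
        for keys in candidates:
            tot = sum(
                (self._pooled(k) for k in keys if self._pooled(k) is not None),
                np.zeros(self.max_years_prior + 1),
            )
            s = tot.sum()
            if s > 0:
                out = tot / s
                break
        self._cache[key] = out
        return out

    def _pooled(self, key):
        """Count vector for a (possibly pooled) key, memoized."""
        if key in self.counts:
            return self.counts[key]
        if _POOLED not in key:
            return None
        cache_key = ("pool", key)
        if cache_key in self._cache:
            return self._cache[cache_key]
        region, age, cls = key
        acc = np.zeros(self.max_years_prior + 1)
        found = False
        for (r, a, c), v in self.counts.items():
            if region not in (_POOLED, r):
                continue
            if age not in (_POOLED, a):
                continue
            if cls not in (_POOLED, c):
                continue
            acc += v
            found = True
        out = acc if found else None
        self._cache[cache_key] = out
        return out

    def lookup(self, region, age_at_survey, ceb, t) -> float:
        """POB for a birth ``t`` completed years before the survey."""
        if t < 0:
            raise ValueError("years prior to survey must be >= 0")
        if t > self.max_years_prior:
            return 0.0
        vec = self.vector(region, age_at_survey, ceb)
        if vec is None:
            self.missing_lookups += 1
            logger.warning("POB lookup found no data even after backoff")
            return 0.0
        return float(vec[int(t)])

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (region, age, cls), vec in sorted(self.counts.items(), key=lambda kv: str(kv[0])):
            tot = vec.sum()
            for t, c in enumerate(vec):
                if c > 0:
                    rows.append((region, age, cls, t, c / tot, c))
        return pd.DataFrame(rows, columns=["region", "age", "ceb_class", "t", "pob", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, max_years_prior: int | None = None) -> "POBTable":
        if max_years_prior is None:
            max_years_prior = int(df["t"].max())
        counts: dict[tuple, np.ndarray] = {}
        weight_col = "count" if "count" in df.columns else "pob"
        for (region, age, cc), sub in df.groupby(["region", "age", "ceb_class"]):
            vec = np.zeros(max_years_prior + 1)
            vec[sub["t"].to_numpy(int)] = sub[weight_col].to_numpy(float)
            counts[(region, int(age), int(cc))] = vec
        return cls(counts=counts, max_years_prior=max_years_prior, provenance="from_frame")

    @classmethod
    def from_csv(cls, path, max_years_prior: int | None = None) -> "POBTable":
        return cls.from_frame(pd.read_csv(path), max_years_prior)


def tabulate_pob(
    children: pd.DataFrame,
    mothers: pd.DataFrame,
    region_map: dict | None = None,
    max_years_prior: int = 25,
) -> POBTable:
    """Tabulate POB distributions from CBH training data.

    Each mother's births are binned by completed years before her survey; the
    counts accumulate into her (region, age at survey, CEB class) cell.
    Births more than ``max_years_prior`` years before the survey are dropped
    before normalization.  ``region_map`` maps country to region; with none,
    a single pooled region is used.
    """
    m = mothers.set_index("mother_id")
    df = children.merge(
        m[["survey_year", "age_at_survey", "ceb", "country"]],
        left_on="mother_id",
        right_index=True,
        how="inner",
    )
    if region_map:
        df["region"] = df["country"].map(region_map).fillna("all")
    else:
        df["region"] = "all"
    df["t"] = (df["survey_year"] - df["birth_year"]).astype(int)
    df = df[(df["t"] >= 0) & (df["t"] <= max_years_prior)]
    df["age"] = df["age_at_survey"].astype(int)
    df["cls"] = ceb_class(df["ceb"])
    grouped = df.groupby(["region", "age", "cls", "t"]).size()
    counts: dict[tuple, np.ndarray] = {}
    for (region, age, cls_, t), c in grouped.items():
        key = (region, int(age), int(cls_))
        if key not in counts:
            counts[key] = np.zeros(max_years_prior + 1)
        counts[key][int(t)] += c
    return POBTable(counts=counts, max_years_prior=max_years_prior, provenance="tabulate_pob")


def lookup_pob(table: POBTable, region, age_at_survey, ceb, t) -> float:
    """Functional wrapper over :meth:`POBTable.lookup`."""
    return table.lookup(region, age_at_survey, ceb, t)


def impute_ceb_at_birth(table: POBTable, mother, birth_year) -> float:
    """Expected running birth count at a hypothetical child's birth.

    One (the hypothetical child itself) plus the mother's CEB multiplied by
    the POB mass strictly earlier than the birth (``t' > t``), capped at her
    CEB and floored at 1.  ``mother`` is any mapping with ``survey_year``,
    ``age_at_survey``, ``ceb`` and optionally ``region``.
    """
    t = int(mother["survey_year"]) - int(birth_year)
    if t < 0:
        raise ValueError("hypothetical birth after the survey year")
    ceb = float(mother["ceb"])
    if ceb <= 0:
        return 1.0
    region = mother.get("region", "all") if hasattr(mother, "get") else "all"
    vec = table.vector(region, mother["age_at_survey"], ceb)
    earlier = 0.0 if vec is None or t >= len(vec) else float(vec[t + 1 :].sum())
    return float(np.clip(1.0 + ceb * earlier, 1.0, max(ceb, 1.0)))
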