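"""Predictive-validity metrics and the indirect-vs-direct comparison harness.

Five metrics, each weighted by the validation sample size (children entering
the bin in the raw validation data):

* ME   — weighted mean of (estimate - validation); systematic bias.
* SDE  — weighted standard deviation of the errors; error spread.
* MRE  — weighted median of estimate / validation; relative bias (1 = none).
* MAPE — weighted median of 100 * |error| / validation; relative accuracy.
* R2   — 1 - weighted SSE / weighted total variance of the validation values.

Validation trends tabulated from single years of birth-history data are noisy
realizations of the underlying hazard, so they are loess-smoothed (span 0.85,
local linear, tricube kernel, no robustness iterations) before comparison;
cells with zero validation value are excluded from the relative metrics with
a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    return float(v[order][np.searchsorted(cum, 0.5 * tot)])


@dataclass
class MetricReport:
    me: float
    sde: float
    mre: float
    mape: float
    r2: float
    n_pairs: int
    n_zero_excluded: int

    def as_dict(self) -> dict:
        return {
            "ME": self.me,
            "SDE": self.sde,
            "MRE": self.mre,
            "MAPE": self.mape,
            "R2": self.r2,
            "n_pairs": self.n_pairs,
            "n_zero_excluded": self.n_zero_excluded,
        }


def compute_metrics(paired: pd.DataFrame) -> MetricReport:
    """Metric suite on aligned (estimate, validation, weight) records.

    ``paired`` needs columns ``estimate``, ``truth`` and ``weight``.
    """
    df = paired.dropna(subset=["estimate", "truth"])
    est = df["estimate"].to_numpy(float)
    val = df["truth"].to_numpy(float)
    w = df["weight"].to_numpy(float) if "weight" in df else np.ones(len(df))
    if w.sum() <= 0:
        raise ValueError("all-zero weights")
    err = est - val
    me = float(np.average(err, weights=w))
    sde = float(np.sqrt(np.average((err - me) ** 2, weights=w)))
    pos = val > 0
    n_zero = int((~pos).sum())
    if n_zero:
        logger.info("excluding %d zero-validation cells from relative metrics", n_zero)
    if pos.any():
        mre = weighted_median(est[pos] / val[pos], w[pos])
        mape = weighted_median(100.0 * np.abs(err[pos]) / val[pos], w[pos])
    else:
        mre = mape = float("nan")
    vbar = np.average(val, weights=w)
    denom = np.sum(w * (val - vbar) ** 2)
    r2 = float(1.0 - np.sum(w * err**2) / denom) if denom > 0 else float("nan")
    return MetricReport(me, sde, mre, mape, r2, len(df), n_zero)


def metrics_by_bin(paired: pd.DataFrame, bin_col: str = "bin_label") -> pd.DataFrame:
    """Per-bin metric table (the usual layout for reporting)."""
    rows = []
    for b, sub in paired.groupby(bin_col, sort=False):
        rows.append({bin_col: b, **compute_metrics(sub).as_dict()})
    return pd.DataFrame(rows)


def loess_smooth(years, values, span: float = 0.85):
    """Loess (local linear, tricube) fit at the observed years.

    Series with fewer than 4 points are returned unsmoothed with a flag.
    Returns ``(smoothed, was_smoothed)``.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 4:
        return values.copy(), False
    out = values.copy()
    out[ok] = lowess(values[ok], years[ok], frac=span, it=0, return_sorted=False)
    return out, True


def smooth_trends(
    df: pd.DataFrame,
    value_col: str = "q",
    year_col: str = "period",
    by: list | None = None,
    span: float = 0.85,
) -> pd.DataFrame:
    """Loess-smooth a trend table within each (group, bin) series."""
    by = by or ["country", "bin_index"]
    out = df.copy()
    smoothed_col = np.empty(len(df))
    for _, idx in out.groupby(by).groups.items():
        idx = np.asarray(idx)
        sub = out.loc[idx].sort_values(year_col)
        sm, _ = loess_smooth(sub[year_col], sub[value_col], span=span)
        smoothed_col[out.index.get_indexer(sub.index)] = sm
    out[value_col + "_smoothed"] = smoothed_col
    return out


def pair_concurrent_estimates(
    indirect: pd.DataFrame,
    direct: pd.DataFrame,
    max_recall: int = 15,
    min_year: int = 1990,
    keys: list | None = None,
) -> pd.DataFrame:
    """Align indirect estimates with direct validation tabulations.

    Both tables need the join keys (default ``country, year, bin_index``), a
    value column (``q`` -> ``estimate`` / ``truth``), and optionally a
    ``survey_year`` column: rows more than ``max_recall`` years before their
    own survey, or before ``min_year``, are dropped from each side before the
    inner join.  The direct side's ``n`` (entrants) becomes the weight.
    """
    keys = keys or ["country", "year", "bin_index"]

    def _filter(df, value_col, out_col):
        d = df.copy()
        if "period" in d.columns and "year" not in d.columns:
            d = d.rename(columns={"period": "year"})
        d = d[d["year"] >= min_year]
        if "survey_year" in d.columns:
            recall = d["survey_year"] - d["year"]
            d = d[(recall >= 0) & (recall <= max_recall)]
        d = d.rename(columns={value_col: out_col})
        cols = keys + [out_col] + (["n"] if "n" in d.columns else [])
        return d[cols]

    left = _filter(indirect, "q", "estimate")
    right = _filter(direct, "q", "truth")
    paired = left.merge(right, on=keys, how="inner")
    if len(paired) == 0:
        logger.warning("no overlapping (group, year, bin) cells between the two sources")
    paired["weight"] = paired["n"] if "n" in paired.columns else 1.0
    return paired
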