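"""EEB weighting and aggregation of hypothetical-child hazards into trends.

Each hypothetical child's bin-a hazard is weighted by the expected number of
real children it represents entering that bin:

    EEB_{m,a,yr} = POB_{m,yr} * CEB_m * S-hat_{m,a,yr}

where S-hat is the predicted survival to the *entry* of bin a (bin 1 enters
with the full weight POB*CEB).  Population trends are EEB-weighted means:

    q-hat_{a,yr} = sum_m q * EEB / sum_m EEB
                 = expected deaths / expected children entering.

Survey weights, when enabled, multiply into both summands.  Uncertainty is
propagated by repeating the aggregation per hazard draw and reporting the
2.5% / 97.5% empirical quantiles (linear-interpolation, numpy default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_bins import DEFAULT_SCHEME, AgeBinScheme

logger = logging.getLogger(__name__)


def survival_to_entry(q: np.ndarray) -> np.ndarray:
    """Survival probability to the entry of each bin along the last axis.

    ``S[..., 0] = 1`` and ``S[..., a] = prod_{alpha < a} (1 - q[..., alpha])``.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("hazards must lie in [0, 1]")
    S = np.cumprod(1.0 - q, axis=-1)
    return np.concatenate([np.ones(q.shape[:-1] + (1,)), S[..., :-1]], axis=-1)


def compute_eeb(
    pob: np.ndarray, ceb: np.ndarray, q: np.ndarray, survey_weight: np.ndarray | None = None
) -> np.ndarray:
    """Expected children entering each bin for each hypothetical child.

    ``q`` has shape ``(n, A)`` (point) or ``(n, A, D)`` (draws); survival is
    taken along the bin axis.  Survey weights, if given, multiply in.
    """
    q = np.asarray(q, dtype=float)
    bin_axis_first = q if q.ndim == 2 else np.moveaxis(q, -1, 1)  # (n, D, A)
    S = survival_to_entry(bin_axis_first)
    if q.ndim == 3:
        S = np.moveaxis(S, 1, -1)  # back to (n, A, D)
    w = np.asarray(pob, dtype=float) * np.asarray(ceb, dtype=float)
    if survey_weight is not None:
        w = w * np.asarray(survey_weight, dtype=float)
    return w.reshape((-1,) + (1,) * (q.ndim - 1)) * S


@dataclass
class AggregatedTrend:
    """Aggregated age-specific trend for groups of mothers.

    ``keys`` holds one row per (group..., year); ``q`` is (G, A) point
    estimates, ``deaths``/``entrants`` the weighted summands, and ``q_draws``
    (G, A, D) the per-draw aggregates when hazard draws were supplied.
    """

    keys: pd.DataFrame
    scheme: AgeBinScheme
    q: np.ndarray
    deaths: np.ndarray
    entrants: np.ndarray
    q_draws: np.ndarray | None = None
    group_cols: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return 0 if self.q_draws is None else self.q_draws.shape[-1]

    def to_frame(self) -> pd.DataFrame:
        G, A = self.q.shape
        rows = self.keys.loc[np.repeat(np.arange(G), A)].reset_index(drop=True)
        rows["bin_index"] = np.tile(np.arange(A), G)
        rows["bin_label"] = [self.scheme.label_of(a) for a in rows["bin_index"]]
        rows["q"] = self.q.ravel()
        rows["expected_deaths"] = self.deaths.ravel()
        rows["expected_entrants"] = self.entrants.ravel()
        if self.q_draws is not None:
            lo, hi = np.quantile(self.q_draws, [0.025, 0.975], axis=-1)
            rows["q_mean_draws"] = self.q_draws.mean(axis=-1).ravel()
            rows["q_lower"] = lo.ravel()
            rows["q_upper"] = hi.ravel()
            rows["n_draws"] = self.n_draws
        return rows


def aggregate_trends(
    hypothetical: pd.DataFrame,
    q: np.ndarray,
    q_draws: np.ndarray | None = None,
    group_cols: list | str = "country",
    use_survey_weights: bool = True,
    scheme: AgeBinScheme = DEFAULT_SCHEME,
    period_width: int = 1,
) -> AggregatedTrend:
    """EEB-weighted mean hazards per (group, year, bin).

    ``hypothetical`` is the table from
    :func:`sbhmort.hypothetical.enumerate_hypothetical_children`; ``q`` its
    predicted hazard matrix (n, A) and ``q_draws`` optionally (n, A, D).
    ``period_width > 1`` pools birth years into wider periods (labelled by the
    first year), the design used for small-area validation.
    """
    group_cols = [group_cols] if isinstance(group_cols, str) else list(group_cols)
    n, A = q.shape
    if len(hypothetical) != n:
        raise ValueError("hazard matrix and hypothetical table are misaligned")
    year = hypothetical["birth_year"].to_numpy(int)
    if period_width > 1:
        k = hypothetical["years_prior"].to_numpy(int) // period_width
        survey_year = year + hypothetical["years_prior"].to_numpy(int)
        year = survey_year - period_width * (k + 1) + 1
    keydf = hypothetical[group_cols].copy()
    keydf["year"] = year
    codes, keys = pd.factorize(pd.MultiIndex.from_frame(keydf))
    G = len(keys)

    sw = hypothetical["survey_weight"].to_numpy(float) if use_survey_weights else None
    pob = hypothetical["pob"].to_numpy(float)
    ceb = hypothetical["ceb"].to_numpy(float)

    eeb = compute_eeb(pob, ceb, q, sw)
    deaths = np.zeros((G, A))
    entrants = np.zeros((G, A))
    np.add.at(entrants, codes, eeb)
    np.add.at(deaths, codes, q * eeb)
    with np.errstate(invalid="ignore", divide="ignore"):
        qhat = np.where(entrants > 0, deaths / np.where(entrants > 0, entrants, 1.0), np.nan)
    n_undefined = int((entrants == 0).sum())
    if n_undefined:
        logger.warning("%d (group, year, bin) cells have zero expected entrants", n_undefined)

    q_draws_agg = None
    if q_draws is not None:
        D = q_draws.shape[-1]
        q_draws_agg = np.empty((G, A, D))
        for d in range(D):
            qd = q_draws[..., d]
            eebd = compute_eeb(pob, ceb, qd, sw)
            num = np.zeros((G, A))
            den = np.zeros((G, A))
            np.add.at(den, codes, eebd)
            np.add.at(num, codes, qd * eebd)
            with np.errstate(invalid="ignore", divide="ignore"):
                q_draws_agg[..., d] = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    keys_df = pd.DataFrame(list(keys), columns=group_cols + ["year"])
    return AggregatedTrend(
        keys=keys_df,
        scheme=scheme,
        q=qhat,
        deaths=deaths,
        entrants=entrants,
        q_draws=q_draws_agg,
        group_cols=group_cols,
    )


def combine_bins(trend: AggregatedTrend, target="5q0") -> pd.DataFrame:
    """Combine contiguous-from-birth bins as independent conditional risks.

    ``target`` is ``"1q0"`` (bins through the first year), ``"5q0"`` (all
    bins), or an explicit contiguous list of bin indices starting at 0.  The
    combined probability is ``1 - prod(1 - q_a)``, applied per draw when
    draws are present, then summarized.
    """
    scheme = trend.scheme
    if target == "5q0":
        idx = list(range(scheme.n_bins))
    elif target == "1q0":
        idx = [a for a in range(scheme.n_bins) if scheme.ends[a] <= 365]
    else:
        idx = sorted(int(a) for a in target)
    if idx != list(range(len(idx))):
        raise ValueError("target bins must be contiguous from birth")
    q = trend.q[:, idx]
    combined = 1.0 - np.prod(1.0 - q, axis=1)
    out = trend.keys.copy()
    out["q"] = combined
    if trend.q_draws is not None:
        cd = 1.0 - np.prod(1.0 - trend.q_draws[:, idx, :], axis=1)
        point, lo, hi = summarize_uncertainty(cd)
        out["q_mean_draws"] = point
        out["q_lower"] = lo
        out["q_upper"] = hi
    return out


def summarize_uncertainty(draws: np.ndarray, axis: int = -1):
    """Mean and empirical 2.5% / 97.5% quantiles over the draw axis.

    The point estimate is the draw mean (so point and interval come from the
    same simulation sample); quantiles use numpy's default linear
    interpolation rule.
    """
    draws = np.asarray(draws)
    if draws.shape[axis] < 2:
        raise ValueError("need at least two draws to summarize uncertainty")
    point = draws.mean(axis=axis)
    lo = np.quantile(draws, 0.025, axis=axis)
    hi = np.quantile(draws, 0.975, axis=axis)
    return point, lo, hi
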