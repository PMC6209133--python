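"""End-to-end holdout experiments on synthetic populations.

The workflow mirrors the method's intended use: train the hazard model on
complete birth histories from earlier surveys, then estimate age-specific
trends indirectly from the *summary* view of each country's most recent
survey, and score the estimates against the simulation's ground truth over
the recall window (up to 15 years before the test survey).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .aggregation import aggregate_trends, combine_bins
from .birth_history import reshape_to_person_period, tabulate_direct_hazards
from .hypothetical import enumerate_hypothetical_children
from .metrics import compute_metrics
from .model import FittedDTSA, ModelSpec, fit_full, predict_hazard
from .pob import tabulate_pob
from .simulate import (
    SimulationConfig,
    derive_sbh_view,
    make_holdout_split,
    simulate_population,
    survey_table,
)

logger = logging.getLogger(__name__)

_CHUNK = 800_000


def predict_hazard_matrix(
    fitted: FittedDTSA, hypothetical: pd.DataFrame, n_draws: int = 0, seed: int | None = None
):
    """Predict the (n, A) hazard matrix for a hypothetical-children table."""
    A = fitted.scheme.n_bins
    n = len(hypothetical)
    base = hypothetical.reset_index(drop=True)
    rows = base.loc[np.repeat(np.arange(n), A)].reset_index(drop=True)
    rows["bin_index"] = np.tile(np.arange(A), n)
    if n_draws:
        pred = predict_hazard(fitted, rows, n_draws=n_draws, seed=seed)
        return pred.point.reshape(n, A), pred.draws.reshape(n, A, n_draws)
    point = np.empty(n * A)
    for s in range(0, n * A, _CHUNK):
        sl = slice(s, min(s + _CHUNK, n * A))
        point[sl] = predict_hazard(fitted, rows.iloc[sl]).point
    return point.reshape(n, A), None


def run_holdout_experiment(
    config: SimulationConfig | None = None,
    seed: int = 0,
    spec: ModelSpec | None = None,
    n_draws: int = 0,
    max_recall: int = 15,
) -> dict:
    """Simulate, train on earlier surveys, estimate from held-out SBH, score.

    Returns a dict with the fitted model, aggregated trends, paired
    estimate/truth tables, per-bin and 5q0 metric reports, and the
    EEB-vs-observed entrant comparison.
    """
    config = replace(config or SimulationConfig(), seed=seed)
    mothers, children, sdi, truth = simulate_population(config)

    surveys = survey_table(mothers)
    train_surveys, test_surveys = make_holdout_split(surveys)
    train_m = mothers[mothers["survey_id"].isin(train_surveys["survey_id"])]
    test_m = mothers[mothers["survey_id"].isin(test_surveys["survey_id"])]
    train_c = children[children["mother_id"].isin(train_m["mother_id"])]
    test_c = children[children["mother_id"].isin(test_m["mother_id"])]

    pp = reshape_to_person_period(train_c, train_m, sdi, config.scheme)
    fitted = fit_full(pp, spec or ModelSpec(), config.scheme)
    # full reproductive span so POB renormalization does not truncate the
    # early births of older mothers (which would inflate deep-recall EEB)
    span = config.mother_age_range[1] - config.min_mother_age
    pob = tabulate_pob(train_c, train_m, max_years_prior=span)

    sbh = derive_sbh_view(test_m, test_c)
    hyp = enumerate_hypothetical_children(sbh, sdi, pob, config.min_mother_age)
    q, q_draws = predict_hazard_matrix(fitted, hyp, n_draws=n_draws, seed=seed + 1)
    trend = aggregate_trends(
        hyp, q, q_draws, group_cols="country", scheme=config.scheme
    )

    # score against ground truth within the recall window of each test survey
    sy = dict(zip(test_surveys["country"], test_surveys["survey_year"]))
    est = trend.to_frame()
    est["survey_year"] = est["country"].map(sy)
    est = est[(est["survey_year"] - est["year"]).between(0, max_recall)]
    paired = est.merge(
        truth.trends.rename(columns={"q_true": "truth"}),
        on=["country", "year", "bin_index"],
        how="inner",
    ).rename(columns={"q": "estimate", "births": "weight"})

    per_bin = {}
    for a, sub in paired.groupby("bin_index"):
        per_bin[config.scheme.label_of(a)] = compute_metrics(sub)

    q5 = combine_bins(trend, "5q0").rename(columns={"q": "estimate"})
    q5["survey_year"] = q5["country"].map(sy)
    q5 = q5[(q5["survey_year"] - q5["year"]).between(0, max_recall)]
    w5 = (
        truth.trends.groupby(["country", "year"], as_index=False)
        .agg(weight=("births", "max"))
    )
    paired_5q0 = q5.merge(truth.true_5q0().rename(columns={"q_true": "truth"}), on=["country", "year"]).merge(
        w5, on=["country", "year"]
    )
    metrics_5q0 = compute_metrics(paired_5q0)

    # EEB vs directly observed entrants in the held-out CBH
    direct = tabulate_direct_hazards(test_c, test_m, config.scheme, "country", 1)
    ent = est[["country", "year", "bin_index", "expected_entrants"]].merge(
        direct.rename(columns={"period": "year"})[["country", "year", "bin_index", "n"]],
        on=["country", "year", "bin_index"],
        how="inner",
    )
    eeb_pairs = ent.rename(columns={"expected_entrants": "estimate", "n": "truth"})
    eeb_pairs["weight"] = 1.0
    # scored per (year, bin), pooled over surveys: single-survey annual
    # entrant counts fluctuate with realized cohort sizes, which is sampling
    # noise about the expectation rather than weighting error
    eeb_pooled = eeb_pairs.groupby(["year", "bin_index"], as_index=False)[
        ["estimate", "truth"]
    ].sum()
    eeb_pooled["weight"] = 1.0
    eeb_metrics = compute_metrics(eeb_pooled)

    return {
        "config": config,
        "fitted": fitted,
        "pob": pob,
        "trend": trend,
        "paired": paired,
        "per_bin_metrics": per_bin,
        "paired_5q0": paired_5q0,
        "metrics_5q0": metrics_5q0,
        "eeb_pairs": eeb_pairs,
        "eeb_metrics": eeb_metrics,
        "test_surveys": test_surveys,
    }


def run_coverage_study(
    n_replicates: int = 20,
    config: SimulationConfig | None = None,
    n_draws: int = 200,
    seed: int = 0,
    max_recall: int = 15,
) -> dict:
    """Interval calibration for 5q0 across seeded replicates.

    For each replicate, runs the holdout experiment with predictive draws and
    checks whether the 95% interval covers the true 5q0 in each (country,
    year) cell of the recall window.  Returns per-replicate and pooled
    coverage.  The default reduced size (2 countries x 2 surveys x 1,000
    mothers) keeps the intervals' target — parameter uncertainty — the
    dominant error source; the draws do not propagate the sampling noise of
    the SBH input itself, which would swamp them at much smaller surveys.
    """
    if config is None:
        config = SimulationConfig(
            n_countries=2, n_surveys_per_country=2, n_mothers_per_survey=1000
        )
    covered = []
    per_rep = []
    for r in range(n_replicates):
        res = run_holdout_experiment(
            config, seed=(seed + 9973 * r) % (2**31 - 1), n_draws=n_draws, max_recall=max_recall
        )
        p5 = res["paired_5q0"]
        hit = (p5["truth"] >= p5["q_lower"]) & (p5["truth"] <= p5["q_upper"])
        covered.append(hit.to_numpy())
        per_rep.append(float(hit.mean()))
    pooled = float(np.concatenate(covered).mean())
    return {"coverage": pooled, "per_replicate": per_rep, "n_cells": int(sum(len(c) for c in covered))}
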