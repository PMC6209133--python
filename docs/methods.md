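# Methods

`sbhmort` estimates annual, age-specific trends in under-5 mortality from
summary birth histories (SBH): survey records in which each woman reports only
her age, her children ever born (CEB), and her children died (CD).  SBH data
— censuses especially — cover many millions more children than complete birth
histories (CBH), but carry no dates, so mortality cannot be located in time by
tabulation.  The package implements an empirically trained indirect method:

1. **Train** a discrete-time survival model on CBH data, where timing *is*
   observed.
2. **Predict** hazard functions for the *hypothetical children* each SBH
   mother could have borne in every calendar year of her reproductive life.
3. **Weight** each hypothetical child by the empirical probability that a
   birth actually fell in that year, and **aggregate** to population trends.

## Age bins and person-period data

Age under 5 is split into seven half-open day intervals — NN [0, 29), PNN1
[29, 183), PNN2 [183, 365), then single-year bins 1yr–4yr up to 1825 days —
matching how birth-history surveys record age at death (days under 1 month,
months under 2 years, completed years after).  Coded ages convert to days via
`round(30.44 * months)` and `round(365.25 * years)`; the conversion lives in
one function so it can be swapped.

CBH records are reshaped so each row is one (child, age-bin) exposure with a
binary death indicator: a child dying in bin *k* contributes *k*+1 rows with
the indicator set on the last; a living child contributes one row per bin
fully survived.  The bin a living child currently occupies is censored at
entry and excluded — the usual discrete-time survival convention; partial
exposure is not fractionally weighted.  Mothers with CD > CEB or missing CEB
are dropped with a logged count.

## The hazard model

For child *i* of mother *m* in age bin *a*,

    Y_{m,i,a} ~ Bernoulli(q_{m,i,a})
    logit(q)  = beta_a                        (per-bin baseline, no intercept)
              + t(year_i, SDI_{c,year})       (common linear trend)
              + t_a(year_i, SDI_{c,year})     (per-bin slope deviations + smooth)
              + g2(CD/CEB_m, CEB_{m,yr}, MothAge_{m,yr})
              + nu_survey + eta_{country,a}   (independent normal intercepts)

All covariates are centered and scaled by their training standard deviations
(constants stored in the fitted model).  The year-SDI interaction lets the
secular trend vary with a country's development level, which is what permits
prediction in countries or periods without training data.

**Bases and penalties.** Smooths are tensor-product P-splines: cubic B-spline
margins (year dim 6, SDI dim 4; CD/CEB dim 4 and dims 3 for the other two
mother covariates) with second-difference penalties, sum-to-zero constrained
against the bin dummies.  These are low-rank penalized smoothers in the same
spirit as thin-plate regression splines; the modest basis dimensions reflect
the smooth, low-rank signal class at survey scale and keep the fit fast.  Two
structural choices matter for out-of-sample stability, the regime indirect
estimation lives in:

* **Hierarchical trend.**  An unpenalized common (year, SDI, year·SDI) trend
  plus per-bin slope deviations penalized through second differences across
  adjacent age bins (trends vary smoothly with age), with a REML-chosen
  penalty.  Age bins with few deaths borrow their trend from neighbours and
  the common decline instead of extrapolating a noisy slope of their own.
* **Null-space shrinkage.**  Each smooth also carries a second penalty on its
  penalty null space (the double-penalty device used for smooth-term
  selection).  Without it, the unpenalized bilinear year·SDI term is
  unidentified wherever deaths are sparse and extrapolates wildly.

Random intercepts are ridge-penalized dummy blocks, so their precisions are
smoothing parameters and `1/lambda` estimates the variance components — the
smooth-as-random-effect identity.  This yields one joint Bayesian covariance
matrix over *all* fitted coefficients, which is exactly what the
simulation-based uncertainty propagation needs.

**Estimation.**  Penalized IRLS for the coefficients; smoothing parameters by
the generalized Fellner–Schall REML update, extended here to overlapping
penalties (wiggliness + null-space shrinkage on the same columns) by
computing `tr(S_total^- S_j)` with a blockwise pseudo-inverse.  The update is
iterated to its fixed point against the fixed working-likelihood Hessian
between coefficient refits (performance iteration), so the expensive
cross-product is only rebuilt a handful of times.  On a shared
fixture the fit matches mgcv's fREML closely (total EDF 48.6 vs 48.7;
country-bin intercept SD 0.098 vs mgcv's 0.121 at truth 0.10).  The per-bin
year-SDI smooths share one wiggliness parameter by default
(`share_g1_lambda`), so sparse-death bins borrow smoothness; separate
parameters are available.  Fits are per region; the default region map pools
everything.

**Extrapolation.**  B-spline bases are extended linearly beyond the training
range (boundary value plus boundary derivative).  Indirect estimation must
project several years past the newest training survey; linear logit-scale
extension is stable where polynomial extension of the boundary cubic is not.
Out-of-range predictions are flagged, never refused.

**Baseline model.**  The no-covariate model on bin dummies is saturated, so
its MLE is computed in closed form: `inverse-logit(beta_a) = d_a / n_a`
exactly.  Zero-death bins are flagged divergent and reported as q = 0; empty
bins as missing.

**Prediction uncertainty.**  Multivariate-normal draws from the joint
posterior covariance of all fitted parameters (1,000 by default in the CLI;
configurable).  For survey or country levels unseen in training, the point
prediction sets the intercept to zero and draws add independent normals at
the estimated variance components, one sequence per unseen level.  Draws are
deterministic given a seed.  Predicted hazards are clipped to
[1e-12, 1 - 1e-12].

## Probability-of-birth distributions and hypothetical children

For each (region, mother's age at survey, CEB class) cell, the POB table
holds the empirical distribution of that cell's births over completed years
before the survey, normalized to sum to one.  CEB classes are exact counts
0–7 with 8+ pooled; ages are single years.  Sparse cells back off in a fixed
order: pool CEB classes, then adjacent ages (±1), then regions.  The module
default window is 25 years; the end-to-end experiment tabulates over the full
reproductive span (37 years) because renormalizing a shorter window truncates
older mothers' early births and inflates expected entrants at deep recall.

Each SBH mother aged *A* surveyed in year *Y* contributes one hypothetical
child per year from *Y* back to the year she turned 12 (A − 11 children).
Each carries its birth-year covariates; the running birth count at birth is
imputed as `1 + CEB * P(birth earlier than t)` from her POB vector, capped at
her CEB — one plus the expected number of earlier births.  Mothers with
CEB = 0 have zero weight everywhere and are skipped by default.

## EEB weighting and aggregation

The expected number of children entering bin *a* represented by a
hypothetical child is

    EEB_{m,a,yr} = POB_{m,yr} * CEB_m * S_{m,a,yr},

with S the predicted survival to the bin's *entry* (bin 1 enters with weight
POB·CEB; survival to entry is the only reading under which EEB counts
children *entering* the bin).  Population trends are EEB-weighted means of
the per-child hazards per (group, birth year, bin); the numerator is expected
deaths and the denominator expected entrants.  Survey weights, when enabled,
multiply into both summands.  Bins combine as independent conditional
probabilities, `1 - prod(1 - q_a)` over a contiguous-from-birth set (1q0,
5q0), per draw.  Reported intervals are the empirical 2.5%/97.5% quantiles
over draws (numpy's linear-interpolation rule); the reported point estimate
of a draw-based summary is the draw mean, so point and interval come from one
sample — the difference from the plug-in prediction is small and documented
here as a choice.  Five-year period pooling is available for small-area work.

## Validation metrics

Five sample-size-weighted metrics compare estimates with direct CBH
tabulations: ME (weighted mean error), SDE (weighted SD of errors — weighted
for consistency with the rest of the suite), MRE (weighted median of
estimate/validation), MAPE (weighted median of 100·|error|/validation), and
R² (1 − weighted SSE over weighted total variance).  Weights are the number
of children entering the bin in the raw validation data.  The weighted median
is the smallest value whose cumulative weight reaches half the total.  Cells
with zero validation value are excluded from the relative metrics with a
logged count.  Noisy annual validation series are loess-smoothed before
comparison (span 0.85, local linear, tricube kernel, no robustness
iterations).  The pairing harness keeps estimates within 15 years of their
own survey and from 1990 onward before the inner join.

## Synthetic data generator

The generator defines the study conditions under which everything is tested:

* 4 countries × 2 survey rounds five years apart at the typical cadence of
  survey programmes, staggered across countries (2008/2013 through
  2011/2016) the way real collection years are — staggering matters, because
  identical collection years would confound survey vintage with the
  mother-level CD/CEB covariate; 5,000 women per survey, aged 15–49 with a
  gently declining age pyramid.
* Hump-shaped age-specific fertility peaking in the 20s (lifetime total ≈ 5
  births, typical of high-mortality settings); annual Bernoulli births from
  age 12, CEB capped at 15.
* Per-bin baseline hazards (0.031, 0.015, 0.013, 0.013, 0.009, 0.006, 0.003)
  at the reference year 2000 and SDI 0.5 — levels typical of the surveyed
  countries; logit-linear declines of 0.02/yr (NN) to 0.04/yr (older bins),
  matching observed global declines of roughly 2–4%/yr.
* Country SDI trajectories rising 0.007/yr from starts (0.25, 0.40, 0.55,
  0.70) with an SDI effect of −2.5 on the logit, giving cross-country
  mortality spreading over several-fold, as in multi-country survey
  collections.
* Mother frailty SD 0.2, survey intercept SD 0.05, country×bin intercept SD
  0.10, all on the logit scale; optional lognormal survey weights; an
  optional `misspecified` mode adds a non-additive SDI-by-mother-age term to
  exercise robustness.

Deaths are sampled sequentially through the bins, with the partially attained
bin at the survey receiving proportionally scaled risk; ages at death are
coded in the survey convention (days / months / completed years), and the
coding is verified to decode back into the sampled bin.  Everything is
deterministic given the seed.

**Ground truth.**  The per-(country, year, bin) estimand is the birth-weighted
mean true hazard of the children born there, *excluding* the survey random
intercept: that intercept models inter-survey idiosyncrasy, which indirect
prediction for a new survey deliberately sets to zero.  Per-child sampling
hazards (survey intercept included) are also stored.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: survey sampling design (clusters, stratification)
beyond a single weight column; age heaping and birth displacement;
recall-dependent omission of dead children; month-resolution birth dating;
fertility change over time within a cell (the POB stationarity assumption is
true by construction here); sex differences; and non-additive structure
except through the labelled misspecified mode.

## Recovery studies and their scale

The holdout experiment trains on each country's earlier survey, estimates
indirectly from the *summary* view of the held-out most recent survey, and
scores against ground truth over the 15 years before the test survey
(~64 country-year cells per bin).  At the default conditions per-bin R² stays above 0.8, 5q0 R² above 0.95, and
expected entrants track direct tabulations with R² above 0.99; the per-bin
median relative error is mostly within ±10%, though with only four countries
one or two bins per run can drift a few points past that band — the residual
of partially pooled country-bin intercepts and of a development-index effect
identified from just four country levels, both of which wash out at real
multi-country scale.  The expected-entrants comparison is scored per (year, bin) pooled over
surveys, since single-survey annual entrant counts fluctuate with realized
cohort sizes — sampling noise about the expectation, not weighting error.
Interval calibration is checked over 20 seeded replicates at a reduced size
(2 countries × 2 surveys × 1,000 women, 200 draws), where the 95% intervals
cover true 5q0 in well over 80% of cells; the draws propagate parameter
uncertainty only (not the sampling noise of the SBH input itself), so much
smaller surveys under-cover by construction.  These problem sizes are the
package's chosen desk-scale study conditions; the variance-component recovery
check (survey intercept SD within a factor of two) uses 100 small surveys and
the TREND variant, because the CD/CEB covariate — by design — absorbs
survey-level mortality differences and with them much of the survey intercept
variance in the covariate-bearing variants.

## Numerical choices and limitations

* Hazard floor/ceiling 1e-12; IRLS weights floored at 1e-10; IRLS stops at
  relative penalized-deviance change 1e-9 with step halving; Fellner–Schall
  sweeps are damped to e^±2 per step and capped at 12 sweeps with tolerance
  0.1 on max |Δ log λ|.
* Knots at quantiles of the standardized training covariates; covariates with
  too few distinct values fall back to a linear column; ties in CEB-at-birth
  (twins, same-year siblings) both count toward the running total.
* The weighted median breaks ties toward the lower value.
* Fitted models serialize to JSON and round-trip bit-exactly (coefficients,
  covariance, bases, scaling, levels).
* Smoothing-parameter uncertainty is not propagated: draws are conditional on
  the fitted penalties.
* Region stratification is a configuration key; the synthetic studies pool
  one region.
* The CD/CEB covariate includes the index child's own outcome in training —
  inherent to using survey-time totals — and is part of how SBH information
  enters prediction; it also partially absorbs hierarchical variance (see
  above).
* Estimates for deep-recall years rest on POB mass that can be zero for young
  mothers; cells with zero expected entrants are reported as missing, with a
  logged count.
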