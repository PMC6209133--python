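"""Discrete-time survival additive models for under-5 mortality hazards.

The response is the person-period death indicator; on the logit scale the
full model is

    logit(q_{m,i,a}) = beta_a
                       + g1_a(year_i, SDI_{c,year})          (per-bin smooth)
                       + g2(CD/CEB_m, CEB_{m,yr}, MothAge)   (joint smooth)
                       + nu_survey + eta_{country,a}         (random intercepts)

with no global intercept, so each beta_a is the baseline logit hazard of its
age bin.  The per-bin year-SDI term is built hierarchically for stability
out of sample: an unpenalized common linear trend (year, SDI, year*SDI),
per-bin linear slope deviations penalized through differences across
adjacent age bins (trends vary smoothly with age), and per-bin tensor
smooths carrying curvature, with the smooths' null spaces ridge-shrunk
(double penalty) so terms without data support shrink instead of
extrapolating.  Smooths are tensor-product cubic P-splines (B-spline bases
with second-difference penalties, sum-to-zero constrained); random
intercepts are ridge-penalized dummies, so their precision is a smoothing
parameter and ``1/lambda`` estimates the variance component.  All smoothing
parameters are selected by the Fellner-Schall REML-type update in
:mod:`sbhmort._penalized`.

Model variants (for specification comparison):

========  =============================================================
FULL      bin dummies + per-bin (year, SDI) smooth + joint mother smooth
INT       linear covariates with interaction terms instead of smooths
ADD       linear covariates, additive, no interactions
TREND     bin dummies + per-bin (year, SDI) smooth only
INDIV     bin dummies + joint mother-covariate smooth only
========  =============================================================

Random intercepts are retained in every variant (they model the survey /
country hierarchy, not the covariate specification).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.special import expit, logit

from ._penalized import PenaltyBlock, fit_penalized_glm
from .age_bins import DEFAULT_SCHEME, AgeBinScheme

VARIANTS = ("FULL", "INT", "ADD", "TREND", "INDIV", "BASELINE")

#: covariates entering the additive model, in canonical order
COVARIATES = ("birth_year", "sdi", "cd_over_ceb", "ceb_at_birth", "mother_age_at_birth")

_Q_FLOOR, _Q_CEIL = 1e-12, 1.0 - 1e-12


@dataclass
class ModelSpec:
    """Which terms are active and how rich the spline bases are."""

    variant: str = "FULL"
    k_year: int = 6
    k_sdi: int = 4
    #: marginal basis dimensions for (CD/CEB, CEB at birth, mother's age)
    k_g2: tuple = (4, 3, 3)
    #: one smoothing parameter shared by the per-bin year-SDI smooths (the
    #: sparse-death older bins borrow smoothness from the data-rich ones)
    share_g1_lambda: bool = True
    #: double-penalty shrinkage: also penalize each smooth's null space
    #: (unpenalized polynomial terms), so effects unsupported by data shrink
    #: to zero instead of extrapolating freely
    select: bool = True
    use_survey_re: bool = True
    use_country_bin_re: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if isinstance(self.k_g2, int):
            self.k_g2 = (self.k_g2,) * 3
        self.k_g2 = tuple(self.k_g2)

    @property
    def has_g1(self) -> bool:
        return self.variant in ("FULL", "TREND")

    @property
    def has_g2(self) -> bool:
        return self.variant in ("FULL", "INDIV")


# ---------------------------------------------------------------------------
# spline bases


@dataclass
class MarginalBasis:
    """1-d basis for one covariate: cubic B-splines or a linear fallback.

    Beyond the training range the basis is extended linearly (value plus
    boundary derivative), so smooths extrapolate as straight lines on the
    logit scale rather than as boundary polynomials.
    """

    kind: str  # "spline" | "linear"
    lo: float
    hi: float
    knots: list | None = None
    degree: int = 3

    @property
    def n_cols(self) -> int:
        if self.kind == "linear":
            return 1
        return len(self.knots) - self.degree - 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return x[:, None]
        t = np.asarray(self.knots)
        xc = np.clip(x, self.lo, self.hi)
        B = BSpline.design_matrix(xc, t, self.degree).toarray()
        below, above = x < self.lo, x > self.hi
        for mask, x0 in ((below, self.lo), (above, self.hi)):
            if mask.any():
                h = 1e-6 * max(self.hi - self.lo, 1e-8)
                b0 = BSpline.design_matrix(np.array([x0]), t, self.degree).toarray()[0]
                xh = np.clip(x0 - h if x0 == self.hi else x0 + h, self.lo, self.hi)
                bh = BSpline.design_matrix(np.array([xh]), t, self.degree).toarray()[0]
                slope = (bh - b0) / (xh - x0)
                B[mask] = b0[None, :] + (x[mask, None] - x0) * slope[None, :]
        return B

    def out_of_range(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x < self.lo) | (x > self.hi)

    def penalty(self) -> np.ndarray:
        k = self.n_cols
        if self.kind == "linear" or k < 3:
            return np.zeros((k, k))
        D = np.diff(np.eye(k), n=2, axis=0)
        return D.T @ D


def _make_marginal(x: np.ndarray, k: int, degree: int = 3) -> MarginalBasis:
    x = np.asarray(x, dtype=float)
    xu = np.unique(x)
    lo, hi = float(x.min()), float(x.max())
    degree = min(degree, max(k - 1, 1))  # small bases drop to lower order
    if len(xu) < degree + 2 or hi - lo < 1e-8:
        return MarginalBasis(kind="linear", lo=lo, hi=hi)
    n_interior = max(k - degree - 1, 0)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(xu, qs)) if n_interior else np.array([])
    interior = interior[(interior > lo) & (interior < hi)]
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    return MarginalBasis(kind="spline", lo=lo, hi=hi, knots=list(t), degree=degree)


@dataclass
class TensorSmooth:
    """Tensor-product smooth over one or more covariates.

    The raw Kronecker basis is centered by a sum-to-zero constraint ``Z``
    (computed from training column means) so it is identifiable next to the
    bin dummies; the penalty is the sum of marginal difference penalties,
    Kronecker-expanded then projected through ``Z``.
    """

    covariates: list[str]
    margins: list[MarginalBasis]
    Z: np.ndarray | None = None
    penalty_matrix: np.ndarray | None = None

    def raw_design(self, df) -> np.ndarray:
        mats = [m.design(df[c].to_numpy()) for c, m in zip(self.covariates, self.margins)]
        out = mats[0]
        for mat in mats[1:]:
            out = np.einsum("ij,ik->ijk", out, mat).reshape(len(mat), -1)
        return out

    def finalize(self, train_df) -> None:
        raw = self.raw_design(train_df)
        c = raw.mean(axis=0)
        self.Z = scipy.linalg.null_space(c[None, :])
        ks = [m.n_cols for m in self.margins]
        S = np.zeros((int(np.prod(ks)), int(np.prod(ks))))
        for i, m in enumerate(self.margins):
            Si = m.penalty()
            left = np.eye(int(np.prod(ks[:i]))) if i else np.eye(1)
            right = np.eye(int(np.prod(ks[i + 1 :]))) if i < len(ks) - 1 else np.eye(1)
            S += np.kron(np.kron(left, Si), right)
        self.penalty_matrix = self.Z.T @ S @ self.Z

    @property
    def n_cols(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    def design(self, df) -> np.ndarray:
        return self.raw_design(df) @ self.Z

    def out_of_range(self, df) -> np.ndarray:
        out = np.zeros(len(df), dtype=bool)
        for c, m in zip(self.covariates, self.margins):
            out |= m.out_of_range(df[c].to_numpy())
        return out

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "margins": [asdict(m) for m in self.margins],
            "Z": None if self.Z is None else self.Z.tolist(),
            "penalty_matrix": None
            if self.penalty_matrix is None
            else self.penalty_matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TensorSmooth":
        return cls(
            covariates=list(d["covariates"]),
            margins=[MarginalBasis(**m) for m in d["margins"]],
            Z=None if d["Z"] is None else np.array(d["Z"]),
            penalty_matrix=None
            if d["penalty_matrix"] is None
            else np.array(d["penalty_matrix"]),
        )


# ---------------------------------------------------------------------------
# design assembly


def _ordinal_slope_penalty(n_bins: int) -> np.ndarray:
    """Fused penalty for per-bin (year, SDI) slope deviations.

    Mortality trends vary smoothly with age, so deviations from the common
    trend are penalized through second differences across adjacent age bins
    (separately for the year and SDI slopes) rather than shrunk independently
    to zero — sparse-death bins borrow their trend from neighbours.
    """
    D = np.diff(np.eye(n_bins), n=2, axis=0)
    S7 = D.T @ D
    S = np.zeros((2 * n_bins, 2 * n_bins))
    for offset in (0, 1):  # year slopes at even, SDI slopes at odd columns
        pos = np.arange(offset, 2 * n_bins, 2)
        S[np.ix_(pos, pos)] = S7
    return S


def _null_projector(S: np.ndarray) -> np.ndarray:
    """Projector onto the penalty's null space (its unpenalized terms)."""
    w, U = np.linalg.eigh(S)
    U0 = U[:, w < max(w.max(), 1.0) * 1e-8]
    return U0 @ U0.T


def _block_sparse(n: int, rows: np.ndarray, vals: np.ndarray, k: int) -> sp.csr_matrix:
    if len(rows) == 0:
        return sp.csr_matrix((n, k))
    m = len(rows)
    coo = sp.coo_matrix(
        (vals.ravel(), (np.repeat(rows, k), np.tile(np.arange(k), m))), shape=(n, k)
    )
    return coo.tocsr()


@dataclass
class _Design:
    """Fitted design layout: scaling, smooths, levels, and column blocks."""

    spec: ModelSpec
    scheme: AgeBinScheme
    scaling: dict = field(default_factory=dict)
    g1: TensorSmooth | None = None
    g2: TensorSmooth | None = None
    survey_levels: list = field(default_factory=list)
    country_levels: list = field(default_factory=list)
    layout: list = field(default_factory=list)  # (name, start, stop, penalized)

    def standardize(self, df) -> dict:
        out = {}
        for c in COVARIATES:
            if c not in df.columns:
                continue
            center, scale = self.scaling[c]
            out[c] = (df[c].to_numpy(dtype=float) - center) / scale
        return out

    def fit(self, pp) -> None:
        A = self.scheme.n_bins
        for c in COVARIATES:
            x = pp[c].to_numpy(dtype=float)
            sd = float(np.std(x))
            self.scaling[c] = (float(np.mean(x)), sd if sd > 0 else 1.0)
        xs = self.standardize(pp)
        sdf = pp.copy()
        for c, v in xs.items():
            sdf[c] = v

        if self.spec.has_g1:
            self.g1 = TensorSmooth(
                covariates=["birth_year", "sdi"],
                margins=[
                    _make_marginal(xs["birth_year"], self.spec.k_year),
                    _make_marginal(xs["sdi"], self.spec.k_sdi),
                ],
            )
            self.g1.finalize(sdf)
        if self.spec.has_g2:
            self.g2 = TensorSmooth(
                covariates=["cd_over_ceb", "ceb_at_birth", "mother_age_at_birth"],
                margins=[
                    _make_marginal(xs["cd_over_ceb"], self.spec.k_g2[0]),
                    _make_marginal(xs["ceb_at_birth"], self.spec.k_g2[1]),
                    _make_marginal(xs["mother_age_at_birth"], self.spec.k_g2[2]),
                ],
            )
            self.g2.finalize(sdf)
        if self.spec.use_survey_re:
            self.survey_levels = sorted(pp["survey_id"].astype(str).unique())
        if self.spec.use_country_bin_re:
            self.country_levels = sorted(pp["country"].astype(str).unique())

        # column layout
        self.layout = []
        pos = 0

        def add(name, k, penalized):
            nonlocal pos
            self.layout.append((name, pos, pos + k, penalized))
            pos += k

        add("bins", A, False)
        if self.g1 is not None and self.g1.n_cols:
            # hierarchical trend: an unpenalized common (year, SDI, year*SDI)
            # trend, ridge-penalized per-bin slope deviations (random slopes
            # with a REML-chosen variance), and per-bin smooths carrying
            # curvature and interaction wiggle
            add("trend_linear", 3, False)
            add("g1_slopes", 2 * A, True)
            for a in range(A):
                add(f"g1_bin{a}", self.g1.n_cols, True)
        if self.g2 is not None and self.g2.n_cols:
            add("g2", self.g2.n_cols, True)
        if self.spec.variant == "ADD":
            add("linear", len(COVARIATES), False)
        if self.spec.variant == "INT":
            add("int_trend", 3 * A, False)  # per-bin year, SDI, year*SDI
            add("int_indiv", 6, False)  # 3 covariates + pairwise products
        if self.survey_levels:
            add("re_survey", len(self.survey_levels), True)
        if self.country_levels:
            add("re_country_bin", len(self.country_levels) * A, True)

    @property
    def n_cols(self) -> int:
        return self.layout[-1][2] if self.layout else 0

    def block(self, name: str):
        for nm, start, stop, _ in self.layout:
            if nm == name:
                return slice(start, stop)
        return None

    def penalty_blocks(self) -> list[PenaltyBlock]:
        blocks = []
        g1_spans = [(s, e) for nm, s, e, _ in self.layout if nm.startswith("g1_bin")]
        for name, start, stop, penalized in self.layout:
            if not penalized:
                blocks.append(PenaltyBlock(name, start, stop, None))
            elif name == "g1_slopes":
                S = _ordinal_slope_penalty(self.scheme.n_bins)
                blocks.append(PenaltyBlock(name, start, stop, S))
                if self.spec.select:
                    blocks.append(
                        PenaltyBlock(name + "_null", start, stop, _null_projector(S))
                    )
            elif name.startswith("g1_bin"):
                if not self.spec.share_g1_lambda:
                    blocks.append(PenaltyBlock(name, start, stop, self.g1.penalty_matrix))
                    if self.spec.select:
                        blocks.append(
                            PenaltyBlock(
                                name + "_null", start, stop,
                                _null_projector(self.g1.penalty_matrix),
                            )
                        )
            elif name == "g2":
                blocks.append(PenaltyBlock(name, start, stop, self.g2.penalty_matrix))
                if self.spec.select:
                    blocks.append(
                        PenaltyBlock(
                            "g2_null", start, stop, _null_projector(self.g2.penalty_matrix)
                        )
                    )
            else:  # random-effect ridge
                blocks.append(PenaltyBlock(name, start, stop, np.eye(stop - start)))
        if self.spec.share_g1_lambda and g1_spans:
            start, stop = g1_spans[0][0], g1_spans[-1][1]
            S = scipy.linalg.block_diag(*[self.g1.penalty_matrix] * len(g1_spans))
            blocks.append(PenaltyBlock("g1", start, stop, S))
            if self.spec.select:
                N = _null_projector(self.g1.penalty_matrix)
                blocks.append(
                    PenaltyBlock(
                        "g1_null", start, stop,
                        scipy.linalg.block_diag(*[N] * len(g1_spans)),
                    )
                )
        return blocks

    def transform(self, df):
        """Sparse design matrix + extrapolation and unseen-level flags."""
        n = len(df)
        A = self.scheme.n_bins
        xs = self.standardize(df)
        sdf = df.copy()
        for c, v in xs.items():
            sdf[c] = v
        bin_idx = df["bin_index"].to_numpy(int)
        parts = []
        extrap = np.zeros(n, dtype=bool)

        parts.append(
            sp.csr_matrix((np.ones(n), (np.arange(n), bin_idx)), shape=(n, A))
        )
        if self.g1 is not None and self.g1.n_cols:
            yr, sdi = xs["birth_year"], xs["sdi"]
            parts.append(sp.csr_matrix(np.column_stack([yr, sdi, yr * sdi])))
            lin = np.column_stack([yr, sdi])
            cols = []
            for a in range(A):
                rows = np.where(bin_idx == a)[0]
                cols.append(_block_sparse(n, rows, lin[rows], 2))
            parts.append(sp.hstack(cols, format="csr"))
            G1 = self.g1.design(sdf)
            extrap |= self.g1.out_of_range(sdf)
            for a in range(A):
                rows = np.where(bin_idx == a)[0]
                parts.append(_block_sparse(n, rows, G1[rows], self.g1.n_cols))
        if self.g2 is not None and self.g2.n_cols:
            G2 = self.g2.design(sdf)
            extrap |= self.g2.out_of_range(sdf)
            parts.append(sp.csr_matrix(G2))
        if self.spec.variant == "ADD":
            lin = np.column_stack([xs[c] for c in COVARIATES])
            parts.append(sp.csr_matrix(lin))
        if self.spec.variant == "INT":
            yr, sdi = xs["birth_year"], xs["sdi"]
            trend = np.column_stack([yr, sdi, yr * sdi])
            cols = []
            for a in range(A):
                rows = np.where(bin_idx == a)[0]
                cols.append(_block_sparse(n, rows, trend[rows], 3))
            parts.append(sp.hstack(cols, format="csr"))
            cc, cb, ma = xs["cd_over_ceb"], xs["ceb_at_birth"], xs["mother_age_at_birth"]
            parts.append(
                sp.csr_matrix(np.column_stack([cc, cb, ma, cc * cb, cc * ma, cb * ma]))
            )
        unseen_survey = np.zeros(n, dtype=bool)
        if self.survey_levels:
            lut = {lev: j for j, lev in enumerate(self.survey_levels)}
            codes = np.array([lut.get(s, -1) for s in df["survey_id"].astype(str)])
            seen = codes >= 0
            unseen_survey = ~seen
            parts.append(
                sp.csr_matrix(
                    (np.ones(seen.sum()), (np.where(seen)[0], codes[seen])),
                    shape=(n, len(self.survey_levels)),
                )
            )
        unseen_country = np.zeros(n, dtype=bool)
        if self.country_levels:
            lut = {lev: j for j, lev in enumerate(self.country_levels)}
            codes = np.array([lut.get(s, -1) for s in df["country"].astype(str)])
            seen = codes >= 0
            unseen_country = ~seen
            col = codes[seen] * A + bin_idx[seen]
            parts.append(
                sp.csr_matrix(
                    (np.ones(seen.sum()), (np.where(seen)[0], col)),
                    shape=(n, len(self.country_levels) * A),
                )
            )
        X = sp.hstack(parts, format="csr")
        return X, {"extrapolated": extrap, "unseen_survey": unseen_survey, "unseen_country": unseen_country}

    def to_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "scheme": [list(b) for b in self.scheme.bins],
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "g1": None if self.g1 is None else self.g1.to_dict(),
            "g2": None if self.g2 is None else self.g2.to_dict(),
            "survey_levels": self.survey_levels,
            "country_levels": self.country_levels,
            "layout": [list(b) for b in self.layout],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Design":
        obj = cls(
            spec=ModelSpec(**d["spec"]),
            scheme=AgeBinScheme(tuple(tuple(b) for b in d["scheme"])),
        )
        obj.scaling = {k: tuple(v) for k, v in d["scaling"].items()}
        obj.g1 = None if d["g1"] is None else TensorSmooth.from_dict(d["g1"])
        obj.g2 = None if d["g2"] is None else TensorSmooth.from_dict(d["g2"])
        obj.survey_levels = list(d["survey_levels"])
        obj.country_levels = list(d["country_levels"])
        obj.layout = [tuple(b) for b in d["layout"]]
        return obj


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class HazardPrediction:
    """Point hazards (and optional simulation draws) for prediction rows."""

    point: np.ndarray
    draws: np.ndarray | None = None
    extrapolated: np.ndarray | None = None
    unseen_survey: np.ndarray | None = None
    unseen_country: np.ndarray | None = None
    seed: int | None = None


@dataclass
class FittedDTSA:
    """A fitted discrete-time survival model.

    Carries everything prediction needs: coefficients, the joint Bayesian
    covariance of all fitted parameters (fixed effects, spline coefficients,
    and fitted random intercepts), the design layout with its scaling
    constants and spline bases, and the random-effect variance estimates used
    to simulate intercepts for unseen surveys / countries.
    """

    design: _Design
    beta: np.ndarray
    cov: np.ndarray
    lambdas: dict = field(default_factory=dict)
    sigma2_survey: float | None = None
    sigma2_country_bin: float | None = None
    region: str = "all"
    diagnostics: dict = field(default_factory=dict)
    baseline_q: np.ndarray | None = None
    baseline_flags: dict = field(default_factory=dict)

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    @property
    def scheme(self) -> AgeBinScheme:
        return self.design.scheme

    def predict(self, rows, n_draws: int = 0, seed: int | None = None) -> HazardPrediction:
        return predict_hazard(self, rows, n_draws=n_draws, seed=seed)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "lambdas": self.lambdas,
            "sigma2_survey": self.sigma2_survey,
            "sigma2_country_bin": self.sigma2_country_bin,
            "region": self.region,
            "diagnostics": self.diagnostics,
            "baseline_q": None if self.baseline_q is None else self.baseline_q.tolist(),
            "baseline_flags": {
                k: np.asarray(v).tolist() for k, v in self.baseline_flags.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDTSA":
        return cls(
            design=_Design.from_dict(d["design"]),
            beta=np.array(d["beta"]),
            cov=np.array(d["cov"]),
            lambdas=dict(d["lambdas"]),
            sigma2_survey=d["sigma2_survey"],
            sigma2_country_bin=d["sigma2_country_bin"],
            region=d["region"],
            diagnostics=dict(d["diagnostics"]),
            baseline_q=None if d["baseline_q"] is None else np.array(d["baseline_q"]),
            baseline_flags={k: np.array(v) for k, v in d["baseline_flags"].items()},
        )

    @classmethod
    def from_json(cls, path) -> "FittedDTSA":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting


def fit_baseline(person_period, scheme: AgeBinScheme = DEFAULT_SCHEME) -> FittedDTSA:
    """No-covariate baseline hazard: saturated logistic fit on bin dummies.

    Without an intercept the MLE is available in closed form — the inverse
    logit of each bin coefficient equals that bin's empirical death fraction
    ``d_a / n_a`` exactly.  Bins with no deaths (or all deaths) have divergent
    coefficients and are flagged; empty bins are reported as missing (NaN).
    """
    A = scheme.n_bins
    bin_idx = person_period["bin_index"].to_numpy(int)
    y = person_period["death"].to_numpy(float)
    n = np.bincount(bin_idx, minlength=A).astype(float)
    d = np.bincount(bin_idx, weights=y, minlength=A)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n > 0, d / np.maximum(n, 1), np.nan)
    divergent = (n > 0) & ((d == 0) | (d == n))
    missing = n == 0
    beta = logit(np.clip(q, _Q_FLOOR, _Q_CEIL))
    beta = np.where(missing, np.nan, beta)
    var = np.full(A, np.nan)
    ok = (n > 0) & ~divergent
    var[ok] = 1.0 / (n[ok] * q[ok] * (1 - q[ok]))
    design = _Design(spec=ModelSpec(variant="BASELINE", use_survey_re=False, use_country_bin_re=False), scheme=scheme)
    design.layout = [("bins", 0, A, False)]
    return FittedDTSA(
        design=design,
        beta=np.where(np.isnan(beta), 0.0, beta),
        cov=np.diag(np.where(np.isnan(var), 0.0, var)),
        baseline_q=q,
        baseline_flags={"divergent": divergent, "missing": missing},
        diagnostics={"n": n.tolist(), "d": d.tolist()},
    )


def fit_full(
    person_period,
    spec: ModelSpec | None = None,
    scheme: AgeBinScheme = DEFAULT_SCHEME,
    region: str = "all",
    max_outer: int = 6,
    fixed_lambdas: dict | None = None,
    irls_tol: float = 1e-9,
) -> FittedDTSA:
    """Fit the penalized additive DTSA model on person-period data.

    Data should be pre-stratified to one region (fit one model per region and
    keep a mapping; see :func:`fit_by_region`).  ``fixed_lambdas`` pins named
    smoothing parameters instead of estimating them.
    """
    spec = spec or ModelSpec()
    if spec.variant == "BASELINE":
        return fit_baseline(person_period, scheme)
    need = {"bin_index", "death", "survey_id", "country"} | set(COVARIATES)
    missing_cols = need - set(person_period.columns)
    if missing_cols:
        raise ValueError(f"person-period table lacks columns {sorted(missing_cols)}")
    design = _Design(spec=spec, scheme=scheme)
    design.fit(person_period)
    X, _ = design.transform(person_period)
    y = person_period["death"].to_numpy(float)
    if np.bincount(person_period["bin_index"].to_numpy(int), minlength=scheme.n_bins).min() == 0:
        raise ValueError("at least one person-period row per age bin is required")
    blocks = design.penalty_blocks()
    if fixed_lambdas:
        for b in blocks:
            if b.name in fixed_lambdas:
                b.lam = float(fixed_lambdas[b.name])
        max_outer = 1  # single penalized fit at the pinned lambdas
        for b in blocks:
            b.frozen = b.penalty is not None
    res = fit_penalized_glm(X, y, blocks, max_outer=max_outer, irls_tol=irls_tol)
    lam = res["lambdas"]
    return FittedDTSA(
        design=design,
        beta=res["beta"],
        cov=res["cov"],
        lambdas=lam,
        sigma2_survey=1.0 / lam["re_survey"] if "re_survey" in lam else None,
        sigma2_country_bin=1.0 / lam["re_country_bin"] if "re_country_bin" in lam else None,
        region=region,
        diagnostics={"edf": res["edf"], "n_outer": res["n_outer"], "n_rows": int(X.shape[0])},
    )


def fit_by_region(
    person_period,
    spec: ModelSpec | None = None,
    scheme: AgeBinScheme = DEFAULT_SCHEME,
    region_map: dict | None = None,
) -> dict[str, FittedDTSA]:
    """Fit one model per region (default: a single pooled region)."""
    pp = person_period.copy()
    pp["region"] = pp["country"].map(region_map).fillna("all") if region_map else "all"
    return {
        str(region): fit_full(sub, spec, scheme, region=str(region))
        for region, sub in pp.groupby("region")
    }


# ---------------------------------------------------------------------------
# prediction


def predict_hazard(
    fitted: FittedDTSA, rows, n_draws: int = 0, seed: int | None = None
) -> HazardPrediction:
    """Per-row hazard q-hat, with optional multivariate-normal draws.

    Point predictions use the fitted random intercepts for seen levels and 0
    for unseen levels.  Draws sample all fitted parameters jointly from
    ``N(beta, V)``; for unseen survey / country levels, independent normal
    draws with the estimated variance components are added (one draw sequence
    per unseen level, shared by that level's rows).  Covariates outside the
    training range are predicted with linear extension and flagged, never
    refused.
    """
    design = fitted.design
    if fitted.spec.variant == "BASELINE":
        bin_idx = np.asarray(rows["bin_index"], dtype=int)
        point = fitted.baseline_q[bin_idx]
        draws = None
        if n_draws:
            rng = np.random.default_rng(seed)
            se = np.sqrt(np.diag(fitted.cov))[bin_idx]
            eta = logit(np.clip(point, _Q_FLOOR, _Q_CEIL))
            z = rng.standard_normal((len(point), n_draws))
            draws = expit(eta[:, None] + se[:, None] * z)
            fixed = fitted.baseline_flags["divergent"][bin_idx] | fitted.baseline_flags["missing"][bin_idx]
            draws[fixed] = point[fixed, None]
        return HazardPrediction(point=point, draws=draws, seed=seed)

    X, flags = design.transform(rows)
    eta = np.asarray(X @ fitted.beta)
    point = np.clip(expit(eta), _Q_FLOOR, _Q_CEIL)
    draws = None
    if n_draws:
        rng = np.random.default_rng(seed)
        p = len(fitted.beta)
        jitter = 1e-10 * max(np.trace(fitted.cov) / max(p, 1), 1e-10)
        L = np.linalg.cholesky(fitted.cov + jitter * np.eye(p))
        delta = L @ rng.standard_normal((p, n_draws))
        eta_draws = eta[:, None] + np.asarray(X @ delta)
        # unseen random-effect levels: independent normals at sigma-hat
        for which, mask, sigma2, key in (
            ("survey_id", flags["unseen_survey"], fitted.sigma2_survey, None),
            ("country", flags["unseen_country"], fitted.sigma2_country_bin, "bin_index"),
        ):
            if sigma2 is None or not mask.any():
                continue
            sd = float(np.sqrt(sigma2))
            lab = rows.loc[mask, which].astype(str)
            if key is not None:  # one intercept per (country, bin)
                lab = lab + "|" + rows.loc[mask, key].astype(str)
            levels = sorted(lab.unique())
            z = {lev: rng.standard_normal(n_draws) * sd for lev in levels}
            add = np.vstack([z[v] for v in lab])
            eta_draws[np.where(mask)[0]] += add
        draws = np.clip(expit(eta_draws), _Q_FLOOR, _Q_CEIL)
    return HazardPrediction(
        point=point,
        draws=draws,
        extrapolated=flags["extrapolated"],
        unseen_survey=flags["unseen_survey"],
        unseen_country=flags["unseen_country"],
        seed=seed,
    )
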