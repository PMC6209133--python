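"""Penalized logistic regression with automatic smoothness selection.

The additive hazard model is a penalized GLM: the design matrix is assembled
from blocks (age-bin dummies, spline tensor bases, random-effect dummies),
each penalized block j carrying a quadratic penalty ``lambda_j * B' S_j B``.
Coefficients are estimated by penalized IRLS and the smoothing parameters by
the generalized Fellner-Schall update

    lambda_j  <-  [ rank(S_j) - lambda_j * tr(V_jj S_j) ] / ( b_j' S_j b_j )

with ``V = (X'WX + S_lambda)^-1``, iterated to a fixed point.  This is the
standard efficient approximation to REML for penalized GLMs; for identity
penalties (random intercepts) the fixed point is the classic Fellner-Schall
variance-component estimate, so ``1 / lambda_j`` estimates the random-effect
variance.  ``V`` at convergence is the usual Bayesian posterior covariance
used for simulation-based prediction intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.special import expit

_LAM_MIN, _LAM_MAX = 1e-7, 1e9


@dataclass
class PenaltyBlock:
    """A contiguous column block of the design matrix.

    ``penalty`` is the (unscaled) quadratic penalty within the block, or
    ``None`` for unpenalized blocks.  ``lam`` holds the current / fitted
    smoothing parameter.
    """

    name: str
    start: int
    stop: int
    penalty: np.ndarray | None = None
    lam: float = 1.0
    rank: int = field(default=0)
    frozen: bool = False

    def __post_init__(self) -> None:
        if self.penalty is not None and self.rank == 0:
            ev = np.linalg.eigvalsh(np.asarray(self.penalty))
            tol = max(ev.max(), 1.0) * 1e-10
            self.rank = int((ev > tol).sum())

    @property
    def sl(self) -> slice:
        return slice(self.start, self.stop)


def _total_penalty(p: int, blocks: list[PenaltyBlock]) -> np.ndarray:
    S = np.zeros((p, p))
    for b in blocks:
        if b.penalty is not None:
            S[b.sl, b.sl] += b.lam * b.penalty
    return S


def _irls(X, y, S, beta0=None, max_iter=50, tol=1e-9):
    """Penalized IRLS for Bernoulli-logit.  Returns (beta, A=X'WX, dev_pen)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    Xt = X.T if sp.issparse(X) else None

    def penalized_deviance(b, eta):
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))
        return dev + b @ S @ b

    eta = X @ beta
    obj = penalized_deviance(beta, eta)
    A = None
    for _ in range(max_iter):
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        if sp.issparse(X):
            Xw = X.copy()
            Xw.data *= np.repeat(w, np.diff(X.indptr))
            A = (Xt @ Xw).toarray()
            rhs = Xt @ (w * z)
        else:
            Xw = X * w[:, None]
            A = X.T @ Xw
            rhs = X.T @ (w * z)
        try:
            beta_new = scipy.linalg.solve(A + S, rhs, assume_a="pos")
        except scipy.linalg.LinAlgError:
            beta_new = scipy.linalg.lstsq(A + S, rhs)[0]
        # step halving if the penalized deviance worsens
        step = 1.0
        for _ in range(12):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            obj_c = penalized_deviance(cand, eta_c)
            if np.isfinite(obj_c) and obj_c <= obj + 1e-10:
                break
            step *= 0.5
        delta = abs(obj - obj_c)
        beta, eta, obj = cand, eta_c, obj_c
        if delta < tol * (abs(obj) + 1.0):
            break
    return beta, A, obj


def fit_penalized_glm(
    X,
    y,
    blocks: list[PenaltyBlock],
    max_outer: int = 6,
    outer_tol: float = 0.1,
    irls_tol: float = 1e-9,
    verbose: bool = False,
):
    """Fit the penalized logistic model, selecting lambdas by Fellner-Schall.

    Returns a dict with ``beta``, Bayesian covariance ``cov``, the blocks with
    fitted ``lam``, effective degrees of freedom, and iteration diagnostics.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    penalized = [b for b in blocks if not b.frozen and b.penalty is not None]
    spans = _merged_spans([b for b in blocks if b.penalty is not None])
    beta = None
    A = None
    n_outer = 0
    # Alternate full coefficient fits with lambda sweeps run to convergence
    # against the fixed working-likelihood Hessian (performance iteration):
    # the expensive X'WX is only rebuilt between cycles, while each lambda
    # sweep costs only p x p solves, so the REML fixed point is actually
    # reached instead of being cut off mid-climb.
    for cycle in range(1, max_outer + 1):
        n_outer = cycle
        S = _total_penalty(p, blocks)
        beta, A, _ = _irls(X, y, S, beta0=beta, max_iter=30 if cycle == 1 else 8, tol=irls_tol)
        if not penalized:
            break
        cycle_change = 0.0
        rhs = (A + S) @ beta  # X'Wz of the current working model
        for sweep in range(60):
            S = _total_penalty(p, blocks)
            V = _safe_inv(A + S)
            # coefficients implied by the new lambdas at fixed working weights
            beta = V @ rhs
            Spinv = _blockwise_pinv(S, spans)
            max_change = 0.0
            for b in penalized:
                # generalized Fellner-Schall with possibly overlapping
                # penalties (wiggliness + null-space shrinkage on the same
                # columns): lam* = lam [tr(S^- S_j) - tr(V S_j)] / (b'S_j b)
                num = b.lam * float(
                    np.sum(Spinv[b.sl, b.sl] * b.penalty)
                    - np.sum(V[b.sl, b.sl] * b.penalty)
                )
                den = float(beta[b.sl] @ b.penalty @ beta[b.sl])
                if den <= 1e-12:
                    # fully smoothed block: push lambda to the ceiling; its
                    # exact value no longer moves the fit
                    b.lam = min(b.lam * 100.0, _LAM_MAX)
                    continue
                if num <= 0.0:  # numerically possible mid-iteration
                    num = den * b.lam * np.e**2
                lam_new = float(np.clip(num / den, _LAM_MIN, _LAM_MAX))
                log_step = np.clip(np.log(lam_new) - np.log(b.lam), -3.0, 3.0)
                b.lam = float(np.exp(np.log(b.lam) + log_step))
                max_change = max(max_change, abs(log_step))
            cycle_change = max(cycle_change, max_change)
            if max_change < 0.02:
                break
        if verbose:
            print(f"cycle {cycle}: max |dlog lam| = {cycle_change:.4f}")
        if cycle_change < outer_tol:
            break
    S = _total_penalty(p, blocks)
    beta, A, _ = _irls(X, y, S, beta0=beta, max_iter=60, tol=irls_tol)
    cov = _safe_inv(A + S)
    cov = 0.5 * (cov + cov.T)
    edf = p - float(np.sum(cov * S)) if p else 0.0
    return {
        "beta": beta,
        "cov": cov,
        "blocks": blocks,
        "edf": edf,
        "n_outer": n_outer,
        "lambdas": {b.name: b.lam for b in penalized},
    }


def _merged_spans(penalized: list[PenaltyBlock]) -> list[tuple[int, int]]:
    """Merge overlapping penalized column spans into connected groups."""
    spans = sorted((b.start, b.stop) for b in penalized)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(e, merged[-1][1])
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def _blockwise_pinv(S: np.ndarray, spans: list[tuple[int, int]]) -> np.ndarray:
    """Pseudo-inverse of the total penalty, computed per connected group.

    Working groupwise keeps the eigenvalue cutoff relative to each group's own
    scale, so a near-infinite lambda in one smooth cannot mask another
    smooth's small but genuine penalty.
    """
    out = np.zeros_like(S)
    for s, e in spans:
        Sg = S[s:e, s:e]
        w, U = np.linalg.eigh(Sg)
        tol = max(w.max(), 0.0) * 1e-10
        winv = np.where(w > tol, 1.0 / np.where(w > tol, w, 1.0), 0.0)
        out[s:e, s:e] = (U * winv) @ U.T
    return out


def _safe_inv(M: np.ndarray) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(M)
        return scipy.linalg.cho_solve((c, low), np.eye(M.shape[0]))
    except scipy.linalg.LinAlgError:
        return np.linalg.pinv(M)
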