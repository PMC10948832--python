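"""Multivariable MR: joint direct effects of K exposures from shared
instruments.

The design regresses the J outcome effects on the J x K matrix of exposure
effects with inverse-variance weights 1/se_out^2.  Variants:

* ``mvmr_ivw`` — no intercept; the workhorse adjustment model.
* ``mvmr_egger`` — adds a free intercept after orienting all SNPs to a
  non-negative effect on a chosen exposure; the intercept tests
  directional pleiotropy.
* ``mvmr_lasso`` — gives every SNP its own intercept penalized by an L1
  term; SNPs whose intercept is shrunk exactly to zero form the candidate
  valid-instrument set, and the reported estimate is post-selection
  ``mvmr_ivw`` on the largest set that passes a heterogeneity check.

A per-exposure conditional instrument-strength F (from regressing one
exposure's instrument effects on the others') is reported as a weak-
instrument guard; values below 10 are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import MultiExposureSet
from .svmr import Z95, EstimationError, _norm_p


@dataclass
class MVMREstimate:
    """Per-exposure joint causal estimates with diagnostics."""

    method: str
    exposure_names: list
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_snp: int
    q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    valid_set: list = field(default_factory=list)
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_p: float = np.nan
    conditional_f: np.ndarray | None = None
    outcome: str = ""


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column for the error message
        bad = []
        for k in range(X.shape[1]):
            others = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[k] if k < len(names) else f"col{k}")
        raise EstimationError(f"collinear exposure design; offending columns: {bad}")


def conditional_f(ms: MultiExposureSet) -> np.ndarray:
    """Sanderson-Windmeijer-style conditional instrument strength.

    For each exposure k, regress its instrument effects on the other
    exposures' and convert the residual signal to an F statistic.
    """
    j, k = ms.beta_exp.shape
    out = np.empty(k)
    for kk in range(k):
        y = ms.beta_exp[:, kk]
        if k == 1:
            resid = y
            df = j
        else:
            X = np.delete(ms.beta_exp, kk, axis=1)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            df = j - (k - 1)
        se_k = ms.se_exp[:, kk]
        out[kk] = float(np.sum((resid / se_k) ** 2) / max(df, 1))
    return out


def mvmr_ivw(ms: MultiExposureSet,
             effects_model: str = "multiplicative_random") -> MVMREstimate:
    """Multivariable IVW: weighted regression of Gamma on all K exposure
    columns with no intercept, weights 1/se_out^2."""
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    j, k = ms.beta_exp.shape
    if j <= k:
        raise EstimationError(f"under-identified: J={j} <= K={k}")
    _check_rank(ms.beta_exp, ms.exposure_names)
    w = 1.0 / ms.se_out ** 2
    X = ms.beta_exp
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * ms.beta_out))
    resid = ms.beta_out - X @ coef
    q = float(np.sum(w * resid ** 2))
    q_df = j - k
    scale = 1.0
    if effects_model == "multiplicative_random":
        scale = max(1.0, np.sqrt(q / q_df))
    cov = np.linalg.inv(xtwx) * scale ** 2
    se = np.sqrt(np.diag(cov))
    p = np.array([_norm_p(b / s) for b, s in zip(coef, se)])
    return MVMREstimate("mvmr_ivw", list(ms.exposure_names), coef, se, p,
                        coef - Z95 * se, coef + Z95 * se, j,
                        q=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)),
                        valid_set=list(ms.snp_ids),
                        conditional_f=conditional_f(ms), outcome=ms.outcome_name)


def mvmr_egger(ms: MultiExposureSet, orient_on: int = 0) -> MVMREstimate:
    """Multivariable Egger: IVW design plus a free intercept, after
    re-orienting every SNP so its effect on exposure ``orient_on`` is
    non-negative."""
    j, k = ms.beta_exp.shape
    if j <= k + 1:
        raise EstimationError(f"under-identified: J={j} <= K+1={k + 1}")
    sign = np.where(ms.beta_exp[:, orient_on] < 0, -1.0, 1.0)
    X = sign[:, None] * ms.beta_exp
    y = sign * ms.beta_out
    _check_rank(X, ms.exposure_names)
    w = 1.0 / ms.se_out ** 2
    Xi = np.column_stack([np.ones(j), X])
    xtwx = Xi.T @ (w[:, None] * Xi)
    coef = np.linalg.solve(xtwx, Xi.T @ (w * y))
    resid = y - Xi @ coef
    q = float(np.sum(w * resid ** 2))
    q_df = j - k - 1
    scale = max(1.0, np.sqrt(q / q_df))
    cov = np.linalg.inv(xtwx) * scale ** 2
    se = np.sqrt(np.diag(cov))
    beta, se_b = coef[1:], se[1:]
    p = np.array([_norm_p(b / s) for b, s in zip(beta, se_b)])
    return MVMREstimate("mvmr_egger", list(ms.exposure_names), beta, se_b, p,
                        beta - Z95 * se_b, beta + Z95 * se_b, j,
                        q=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)),
                        valid_set=list(ms.snp_ids),
                        intercept=float(coef[0]), intercept_se=float(se[0]),
                        intercept_p=_norm_p(coef[0] / se[0]),
                        conditional_f=conditional_f(ms), outcome=ms.outcome_name)


def _lasso_path(ms: MultiExposureSet, lam: float, alpha0: np.ndarray,
                tol: float = 1e-8, max_iter: int = 10_000) -> np.ndarray:
    """Per-SNP intercepts minimizing
    sum_j w_j (Gamma_j - alpha_j - x_j . theta)^2 + lam * sum_j |alpha_j|
    by blockwise alternation: exact soft-threshold update of alpha given
    theta, exact WLS update of theta given alpha."""
    w = 1.0 / ms.se_out ** 2
    X = ms.beta_exp
    y = ms.beta_out
    alpha = alpha0.copy()
    for _ in range(max_iter):
        xtwx = X.T @ (w[:, None] * X)
        theta = np.linalg.solve(xtwx, X.T @ (w * (y - alpha)))
        r = y - X @ theta
        # soft threshold at lam/(2 w_j)
        thr = lam / (2.0 * w)
        new_alpha = np.sign(r) * np.maximum(np.abs(r) - thr, 0.0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha


def mvmr_lasso(ms: MultiExposureSet,
               lambda_grid: np.ndarray | None = None) -> MVMREstimate:
    """Valid-instrument selection by L1-penalized per-SNP intercepts.

    For each penalty on a descending grid, SNPs whose intercept shrinks
    exactly to zero form a candidate valid set.  The chosen set is the
    largest one whose post-selection heterogeneity Q falls below the
    chi-square 95th percentile at (J_valid - K) df; the reported estimate
    is ``mvmr_ivw`` on that set.
    """
    j, k = ms.beta_exp.shape
    if j <= k + 1:
        raise EstimationError(f"under-identified: J={j} <= K+1={k + 1}")
    _check_rank(ms.beta_exp, ms.exposure_names)
    w = 1.0 / ms.se_out ** 2
    if lambda_grid is None:
        # smallest lambda zeroing every intercept: residuals at alpha = 0
        base = mvmr_ivw(ms, "fixed")
        resid = ms.beta_out - ms.beta_exp @ base.beta
        lam_max = float(np.max(2.0 * w * np.abs(resid))) * 1.0001
        if lam_max <= 0:
            lam_max = 1.0
        lambda_grid = np.geomspace(lam_max, lam_max / 1000.0, 50)
    alpha = np.zeros(j)
    best_ids: list | None = None
    for lam in lambda_grid:
        alpha = _lasso_path(ms, lam, alpha)      # warm start down the path
        valid = np.abs(alpha) <= 1e-12
        if valid.sum() <= k:
            continue
        ids = [s for s, v in zip(ms.snp_ids, valid) if v]
        sub = ms.subset(ids)
        est = mvmr_ivw(sub, "fixed")
        if est.q <= stats.chi2.ppf(0.95, est.q_df):
            if best_ids is None or len(ids) > len(best_ids):
                best_ids = ids
    if best_ids is None:
        raise EstimationError("no penalty yields a valid instrument set "
                              "with an acceptable heterogeneity Q")
    final = mvmr_ivw(ms.subset(best_ids), "multiplicative_random")
    final.method = "mvmr_lasso"
    final.valid_set = best_ids
    return final
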