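"""Single-variable two-sample MR estimators and diagnostics.

All estimators consume a :class:`~mrkit.harmonize.HarmonizedPair` of J
instrument effects (gamma_j on the exposure, Gamma_j on the outcome) and
return the causal effect on the beta scale — log odds ratio per unit
exposure for binary outcomes.  Implemented methods:

* Wald ratio (single SNP), first-order delta-method SE
* inverse-variance weighted (IVW): weighted regression of Gamma on gamma
  through the origin with weights 1/se_out^2, fixed or multiplicative
  random effects
* MR-Egger: the same regression with a free intercept; a non-zero
  intercept is evidence of directional pleiotropy
* weighted median: consistent when >= 50% of the weight comes from valid
  instruments; SE by seeded parametric bootstrap

Two-sided p-values use the normal distribution throughout, the summary-data
MR convention.  The multiplicative random-effects model inflates fixed
SEs by max(1, sqrt(Q/df)) and never deflates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair

Z95 = stats.norm.ppf(0.975)


class EstimationError(Exception):
    pass


@dataclass
class MREstimate:
    """A causal-effect estimate with Wald CI and heterogeneity diagnostics."""

    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    ci_low: float = field(default=np.nan)
    ci_high: float = field(default=np.nan)
    q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    exposure: str = ""
    outcome: str = ""

    def __post_init__(self) -> None:
        if np.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if np.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _labels(hp: HarmonizedPair) -> dict:
    return {"exposure": hp.exposure_name, "outcome": hp.outcome_name}


def wald_ratio(hp: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with delta-method SE."""
    if hp.n_snp != 1:
        raise EstimationError("wald_ratio requires exactly one SNP")
    g, G = hp.beta_exp[0], hp.beta_out[0]
    if g == 0:
        raise EstimationError("undefined Wald ratio: exposure effect is zero")
    beta = G / g
    se = hp.se_out[0] / abs(g)
    return MREstimate("wald", 1, float(beta), float(se), _norm_p(beta / se),
                      **_labels(hp))


def cochran_q(hp: HarmonizedPair, beta: float, df: int | None = None):
    """Weighted residual heterogeneity Q about a fitted slope.

    Q = sum_j w_j (Gamma_j - beta * gamma_j)^2 with w_j = 1/se_out_j^2;
    p from chi-square with ``df`` (default J - 1).
    """
    if hp.n_snp < 2:
        raise EstimationError("Cochran's Q needs J >= 2")
    w = 1.0 / hp.se_out ** 2
    q = float(np.sum(w * (hp.beta_out - beta * hp.beta_exp) ** 2))
    q_df = (hp.n_snp - 1) if df is None else df
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
    return q, q_df, q_p


def ivw(hp: HarmonizedPair, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of Gamma on gamma through the origin with
    weights 1/se_out^2.  ``fixed`` uses the analytic SE
    (sum w gamma^2)^(-1/2); ``multiplicative_random`` (default) scales it
    by max(1, sqrt(Q/(J-1))).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    if hp.n_snp < 2:
        if hp.n_snp == 1:
            est = wald_ratio(hp)
            est.method = "wald"
            return est
        raise EstimationError("ivw needs at least one SNP")
    w = 1.0 / hp.se_out ** 2
    denom = float(np.sum(w * hp.beta_exp ** 2))
    beta = float(np.sum(w * hp.beta_exp * hp.beta_out)) / denom
    se = denom ** -0.5
    q, q_df, q_p = cochran_q(hp, beta)
    method = "ivw_fe"
    if effects_model == "multiplicative_random":
        se *= max(1.0, np.sqrt(q / q_df))
        method = "ivw_re"
    return MREstimate(method, hp.n_snp, beta, float(se), _norm_p(beta / se),
                      q=q, q_df=q_df, q_p=q_p, **_labels(hp))


def egger(hp: HarmonizedPair) -> MREstimate:
    """MR-Egger regression: weighted fit of Gamma = alpha + beta*gamma.

    Instruments are first re-oriented so every exposure effect is
    non-negative (negating both betas of negative-gamma SNPs), the
    convention that makes the intercept interpretable.  SEs carry the
    multiplicative random-effects inflation max(1, sqrt(Q'/(J-2))).
    """
    if hp.n_snp < 3:
        raise EstimationError("MR-Egger needs J >= 3")
    sign = np.where(hp.beta_exp < 0, -1.0, 1.0)
    g = sign * hp.beta_exp
    G = sign * hp.beta_out
    w = 1.0 / hp.se_out ** 2
    X = np.column_stack([np.ones_like(g), g])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = G - X @ coef
    q = float(np.sum(w * resid ** 2))
    q_df = hp.n_snp - 2
    scale = max(1.0, np.sqrt(q / q_df))
    cov = np.linalg.inv(xtwx) * scale ** 2
    a, b = float(coef[0]), float(coef[1])
    se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MREstimate("egger", hp.n_snp, b, se_b, _norm_p(b / se_b),
                      q=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)),
                      egger_intercept=a, egger_intercept_se=se_a,
                      egger_intercept_p=_norm_p(a / se_a), **_labels(hp))


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Linear interpolation of the weighted empirical CDF at 0.5."""
    order = np.argsort(theta)
    theta = theta[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - 0.5 * w
    if 0.5 <= p[0]:
        return float(theta[0])
    if 0.5 >= p[-1]:
        return float(theta[-1])
    j = int(np.searchsorted(p, 0.5, side="right")) - 1
    if p[j] == 0.5:
        return float(theta[j])
    frac = (0.5 - p[j]) / (p[j + 1] - p[j])
    return float(theta[j] + frac * (theta[j + 1] - theta[j]))


def weighted_median(hp: HarmonizedPair, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Per-SNP Wald ratios are ordered and the estimate is the interpolated
    weighted empirical CDF at 0.5, weights gamma^2/se_out^2.  The SE is the
    standard deviation of the estimator over ``n_boot`` resamples of
    (gamma_hat, Gamma_hat) from their normal sampling distributions.
    """
    if hp.n_snp < 3:
        raise EstimationError("weighted median needs J >= 3")
    theta = hp.beta_out / hp.beta_exp
    w = hp.beta_exp ** 2 / hp.se_out ** 2
    beta = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        g = rng.normal(hp.beta_exp, hp.se_exp)
        G = rng.normal(hp.beta_out, hp.se_out)
        ok = g != 0
        boots[b] = _weighted_median(G[ok] / g[ok], g[ok] ** 2 / hp.se_out[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return MREstimate("weighted_median", hp.n_snp, beta, se,
                      _norm_p(beta / se) if se > 0 else 1.0, **_labels(hp))


def leave_one_out(hp: HarmonizedPair,
                  effects_model: str = "multiplicative_random") -> list[MREstimate]:
    """J IVW estimates, each omitting one instrument in turn."""
    if hp.n_snp < 3:
        raise EstimationError("leave-one-out needs J >= 3")
    out = []
    for j in range(hp.n_snp):
        mask = np.ones(hp.n_snp, dtype=bool)
        mask[j] = False
        est = ivw(hp.subset(mask), effects_model)
        est.method = f"ivw_loo[{hp.snp_ids[j]}]"
        out.append(est)
    return out


def estimate_to_or(est: MREstimate, decimals: int = 4):
    """(OR, CI low, CI high) rounded half-even, the report display form."""
    def r(x):
        return float(np.round(x, decimals))
    return r(np.exp(est.beta)), r(np.exp(est.ci_low)), r(np.exp(est.ci_high))
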