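"""Bayesian model averaging over exposure subsets (MR-BMA style).

Given J approximately independent instruments and K candidate exposures,
every non-empty exposure subset S defines an origin-constrained linear
model for the inverse-variance standardized data
(y_j = Gamma_j/se_out_j on x_jk = gamma_jk/se_out_j).  Under a Zellner
g-prior the marginal likelihood of S is available in closed form,

    ML(S) ∝ (1+g)^(-|S|/2) * [y'y - g/(1+g) * y'X_S(X_S'X_S)^-1 X_S'y]^(-J/2),

and combined with an independent-inclusion prior it yields model posterior
probabilities (PP), per-exposure marginal inclusion probabilities (MIP)
and model-averaged causal effects (MACE).  Exposures are ranked by MIP.
Because standardization divides y and x by the same se_out, g-prior
posterior-mean coefficients are already on the unstandardized causal
scale.

Influence diagnostics follow the MR-BMA convention: for each model above
a PP threshold, per-SNP Cook's distances are compared with the median of
the F(|S|, J-|S|) distribution and standardized squared residuals
(heterogeneity contributions) with a Bonferroni chi-square(1) cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import MultiExposureSet
from .sumstats_io import LDMatrix, SummaryDataset
from .instruments import greedy_clump
from .svmr import EstimationError

logger = logging.getLogger(__name__)


@dataclass
class BMAResult:
    """Ranked exposure-subset posterior and its marginal summaries."""

    models: pd.DataFrame        # columns: subset (tuple), pp, estimates (tuple)
    mip: pd.Series              # per exposure
    mace: pd.Series             # per exposure
    ranking: list               # exposures by MIP descending
    prior_inclusion: float
    g: float
    exposure_names: list = field(default_factory=list)

    def top_models(self, n: int = 10) -> pd.DataFrame:
        return self.models.head(n)


@dataclass
class InfluenceDiagnostics:
    """Per (model, SNP) influence and heterogeneity-contribution measures."""

    table: pd.DataFrame          # model, snp, cook_distance, q_contribution, flags
    flagged_snps: list
    cook_threshold_df: str = "median F(p, J-p)"
    q_threshold: str = "chi2(1) at 0.05/J"


def _standardize(ms: MultiExposureSet) -> tuple[np.ndarray, np.ndarray]:
    y = ms.beta_out / ms.se_out
    X = ms.beta_exp / ms.se_out[:, None]
    return y, X


def bma_enumerate(ms: MultiExposureSet, prior_inclusion: float = 0.1,
                  g: float | None = None) -> BMAResult:
    """Exhaustively enumerate all 2^K - 1 non-empty exposure subsets.

    ``g`` defaults to J (unit-information prior).  Models are sorted by
    PP descending, ties broken by smaller subset then lexicographic
    exposure names.  A singular subset design gets PP 0 with a warning.
    """
    j, k = ms.beta_exp.shape
    if k > 20:
        raise EstimationError("exhaustive enumeration limited to K <= 20")
    if j <= k:
        raise EstimationError(f"under-identified: J={j} <= K={k}")
    if not 0 < prior_inclusion < 1:
        raise ValueError("prior_inclusion must be in (0, 1)")
    gg = float(j) if g is None else float(g)
    if gg <= 0:
        raise ValueError("g must be positive")
    y, X = _standardize(ms)
    yty = float(y @ y)
    shrink = gg / (1.0 + gg)

    rows = []
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            Xs = X[:, subset]
            xtx = Xs.T @ Xs
            try:
                xtx_inv = np.linalg.inv(xtx)
            except np.linalg.LinAlgError:
                logger.warning("singular design for subset %s; PP set to 0",
                               [ms.exposure_names[i] for i in subset])
                rows.append((subset, -np.inf, tuple(np.zeros(size))))
                continue
            xty = Xs.T @ y
            fit = float(xty @ xtx_inv @ xty)
            rss_g = yty - shrink * fit
            if rss_g <= 0:
                rss_g = np.finfo(float).tiny
            log_ml = -0.5 * size * np.log1p(gg) - 0.5 * j * np.log(rss_g)
            log_prior = (size * np.log(prior_inclusion)
                         + (k - size) * np.log1p(-prior_inclusion))
            est = shrink * (xtx_inv @ xty)
            rows.append((subset, log_ml + log_prior, tuple(est)))

    logw = np.array([r[1] for r in rows])
    m = np.max(logw[np.isfinite(logw)])
    w = np.where(np.isfinite(logw), np.exp(logw - m), 0.0)
    pp = w / w.sum()

    names = list(ms.exposure_names)
    models = pd.DataFrame({
        "subset": [tuple(names[i] for i in r[0]) for r in rows],
        "subset_idx": [r[0] for r in rows],
        "pp": pp,
        "estimates": [r[2] for r in rows],
    })
    models = models.sort_values(
        by=["pp", "subset"],
        key=lambda s: s if s.name == "pp" else s.map(lambda t: (len(t), t)),
        ascending=[False, True], kind="mergesort").reset_index(drop=True)

    mip = np.zeros(k)
    mace = np.zeros(k)
    for subset, p_model, est in zip(models["subset_idx"], models["pp"],
                                    models["estimates"]):
        for pos, idx in enumerate(subset):
            mip[idx] += p_model
            mace[idx] += p_model * est[pos]
    mip_s = pd.Series(mip, index=names)
    mace_s = pd.Series(mace, index=names)
    ranking = list(mip_s.sort_values(ascending=False, kind="mergesort").index)
    return BMAResult(models, mip_s, mace_s, ranking, prior_inclusion, gg, names)


def bma_diagnostics(ms: MultiExposureSet, result: BMAResult,
                    pp_threshold: float = 0.02) -> InfluenceDiagnostics:
    """Cook's-distance and heterogeneity-contribution diagnostics.

    Applied to every enumerated model with PP >= ``pp_threshold``, using
    the ordinary (g-free) origin-constrained fit on the standardized data.
    """
    y, X = _standardize(ms)
    j = len(y)
    cook_rows = []
    flagged: set = set()
    q_cut = stats.chi2.ppf(1 - 0.05 / j, 1)
    for subset, pp in zip(result.models["subset_idx"], result.models["pp"]):
        if pp < pp_threshold:
            continue
        p_s = len(subset)
        Xs = X[:, subset]
        H = Xs @ np.linalg.inv(Xs.T @ Xs) @ Xs.T
        h = np.diag(H)
        e = y - H @ y
        dof = j - p_s
        s2 = float(e @ e) / dof if dof > 0 else np.nan
        if s2 <= 1e-20 * max(1.0, float(y @ y) / j):
            cook = np.zeros(j)         # numerically exact fit
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                cook = (e ** 2 / (p_s * s2)) * (h / (1 - h) ** 2)
        qc = e ** 2
        cook_cut = stats.f.ppf(0.5, p_s, max(dof, 1))
        name = tuple(result.exposure_names[i] for i in subset)
        for snp, d, q, hh in zip(ms.snp_ids, cook, qc, h):
            flag_cook = bool(d > cook_cut)
            flag_q = bool(q > q_cut)
            cook_rows.append((name, snp, float(d), float(q), flag_cook, flag_q))
            if flag_cook or flag_q:
                flagged.add(snp)
    table = pd.DataFrame(cook_rows, columns=["model", "snp", "cook_distance",
                                             "q_contribution", "flag_cook",
                                             "flag_q"])
    ordered = [s for s in ms.snp_ids if s in flagged]
    return InfluenceDiagnostics(table, ordered)


def bma_rerun_without(ms: MultiExposureSet, flagged: list,
                      prior_inclusion: float = 0.1,
                      g: float | None = None) -> BMAResult:
    """Re-run enumeration after removing flagged instruments.

    Errors when the reduced instrument count no longer exceeds K.
    """
    drop = set(flagged)
    keep = [s for s in ms.snp_ids if s not in drop]
    if len(keep) <= ms.n_exposure:
        raise EstimationError(
            f"removing {len(drop)} SNPs leaves J'={len(keep)} <= K={ms.n_exposure}")
    return bma_enumerate(ms.subset(keep), prior_inclusion, g)


def joint_clump_for_bma(exposures: list[SummaryDataset], ld: LDMatrix | None,
                        r2_threshold: float = 0.001,
                        window_kb: float = 10_000) -> list:
    """Clump the pooled instrument candidates of all exposures jointly.

    Each SNP is ranked by its minimum p-value across exposures, then
    clumped greedily so the surviving set is approximately independent —
    the instrument-independence requirement of the BMA model.
    """
    if len(exposures) < 2:
        raise ValueError("joint clump needs K >= 2 exposures")
    frames = [ds.records[["snp", "chr", "pos", "pval"]] for ds in exposures]
    pool = pd.concat(frames, ignore_index=True)
    if len(pool) == 0:
        raise EstimationError("empty instrument pool")
    pool = (pool.sort_values("pval", kind="mergesort")
                .groupby("snp", as_index=False, sort=False).first())
    sel = greedy_clump(pool, ld, r2_threshold, window_kb)
    return sel.kept
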