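"""Instrument selection: significance screening, greedy LD clumping,
F-statistics and simulation-based pleiotropic-outlier elimination.

The selection chain mirrors standard two-sample MR practice: keep
genome-wide-significant variants (p < 5e-8 by default), clump them to an
approximately independent set (pairwise r2 < 0.001 within 10 Mb by
default), check instrument strength via per-SNP F = (gamma/se)^2, and
remove pleiotropic outliers with a leave-one-out residual simulation in
the spirit of MR-PRESSO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedPair
from .sumstats_io import LDMatrix, SummaryDataset

logger = logging.getLogger(__name__)


class SelectionError(Exception):
    pass


@dataclass
class InstrumentSelection:
    """Outcome of a selection stage: kept ids, removals with reasons,
    and instrument-strength summaries."""

    kept: list
    removed: list = field(default_factory=list)   # (snp, stage, reason)
    per_snp_f: np.ndarray | None = None
    mean_f: float = np.nan


def significance_screen(ds: SummaryDataset, p_threshold: float = 5e-8) -> SummaryDataset:
    """Subset to variants with p below the relevance threshold (order kept)."""
    keep = ds.records[ds.records["pval"] < p_threshold].reset_index(drop=True)
    if len(keep) == 0:
        raise SelectionError(
            f"{ds.trait_name}: no variant passes p < {p_threshold:g}")
    return SummaryDataset(ds.trait_name, keep, ds.trait_type, ds.unit_label)


def _clump_order(df: pd.DataFrame) -> pd.DataFrame:
    # p ascending; ties broken by (chr, pos, snp) for determinism
    return df.sort_values(["pval", "chr", "pos", "snp"],
                          kind="mergesort").reset_index(drop=True)


def greedy_clump(candidates: pd.DataFrame, ld: LDMatrix | None,
                 r2_threshold: float = 0.001, window_kb: float = 10_000,
                 strict: bool = False) -> InstrumentSelection:
    """Greedy LD clumping over a candidate table (needs snp/chr/pos/pval).

    Variants are visited by ascending p; one is accepted iff, against every
    already-accepted variant, its r2 is below the threshold or the pair is
    outside the window (different chromosome or > window_kb apart).
    Pairs absent from the LD matrix count as independent unless ``strict``.
    """
    kept: list = []
    removed: list = []
    accepted_rows: list = []
    for row in _clump_order(candidates).itertuples(index=False):
        independent = True
        for acc in accepted_rows:
            outside = (row.chr != acc.chr) or (
                not (np.isnan(row.pos) or np.isnan(acc.pos))
                and abs(row.pos - acc.pos) > window_kb * 1000)
            if outside:
                continue
            r2 = ld.get(row.snp, acc.snp) if ld is not None else None
            if r2 is None:
                if strict:
                    independent = False
                    removed.append((row.snp, "clump", f"no_ld_info_vs_{acc.snp}"))
                    break
                logger.warning("no LD info for (%s, %s); treating as independent",
                               row.snp, acc.snp)
                continue
            if r2 >= r2_threshold:
                independent = False
                removed.append((row.snp, "clump", f"r2_{r2:.3g}_with_{acc.snp}"))
                break
        if independent:
            kept.append(row.snp)
            accepted_rows.append(row)
    return InstrumentSelection(kept, removed)


def ld_clump(ds: SummaryDataset, ld: LDMatrix | None,
             r2_threshold: float = 0.001, window_kb: float = 10_000,
             strict: bool = False) -> InstrumentSelection:
    """Greedy LD clumping of a summary dataset by ascending p-value."""
    return greedy_clump(ds.records, ld, r2_threshold, window_kb, strict)


def f_statistics(hp: HarmonizedPair) -> InstrumentSelection:
    """Per-SNP instrument strength F_j = (gamma_j/se_j)^2 and its mean.

    Mean F below ~10 conventionally signals weak instruments.
    """
    if hp.n_snp < 1:
        raise SelectionError("f_statistics needs J >= 1")
    per = (hp.beta_exp / hp.se_exp) ** 2
    return InstrumentSelection(list(hp.snp_ids), per_snp_f=per,
                               mean_f=float(per.mean()))


@dataclass
class OutlierReport:
    """Result of the simulation-based pleiotropic-outlier test."""

    global_rss: float
    global_p: float
    outlier_p: pd.Series          # Bonferroni-adjusted per SNP
    flagged: list
    n_sim: int
    seed: int


def _loo_ivw_betas(hp: HarmonizedPair) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the omitted index."""
    w = 1.0 / hp.se_out ** 2
    num = np.sum(w * hp.beta_exp * hp.beta_out)
    den = np.sum(w * hp.beta_exp ** 2)
    num_j = num - w * hp.beta_exp * hp.beta_out
    den_j = den - w * hp.beta_exp ** 2
    return num_j / den_j


def presso_outliers(hp: HarmonizedPair, n_sim: int = 1000,
                    alpha: float = 0.05, seed: int = 0) -> OutlierReport:
    """Detect pleiotropic outlier instruments by residual simulation.

    For each SNP j the leave-one-out IVW slope theta_-j gives the residual
    r_j = Gamma_j - theta_-j * gamma_j; the observed weighted RSS is
    compared with its parametric-bootstrap null distribution: each
    replicate redraws gamma_j* ~ N(gamma_j, se_exp_j^2) and
    Gamma_j* ~ N(theta_-j * gamma_j, se_out_j^2) and recomputes the
    leave-one-out residuals, so the null distribution carries both the
    sampling noise of the data and the variability of the leave-one-out
    estimator itself.  Per-SNP exceedance p-values are Bonferroni-adjusted
    over J; SNPs below ``alpha`` are flagged.  Fully reproducible under a
    fixed seed.
    """
    j = hp.n_snp
    if j < 4:
        raise SelectionError("outlier test needs J >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    w = 1.0 / hp.se_out ** 2
    theta_loo = _loo_ivw_betas(hp)
    resid = hp.beta_out - theta_loo * hp.beta_exp
    obs_sq = w * resid ** 2
    rss = float(np.sum(obs_sq))

    rng = np.random.default_rng(seed)
    g_star = rng.normal(hp.beta_exp, hp.se_exp, size=(n_sim, j))
    G_star = rng.normal(theta_loo * hp.beta_exp, hp.se_out, size=(n_sim, j))
    num = np.sum(w * g_star * G_star, axis=1, keepdims=True)
    den = np.sum(w * g_star ** 2, axis=1, keepdims=True)
    theta_star = (num - w * g_star * G_star) / (den - w * g_star ** 2)
    sim_sq = w * (G_star - theta_star * g_star) ** 2
    sim_rss = sim_sq.sum(axis=1)
    global_p = float((1 + np.sum(sim_rss >= rss)) / (n_sim + 1))

    exceed = (1 + np.sum(sim_sq >= obs_sq, axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, exceed * j)
    outlier_p = pd.Series(adj, index=list(hp.snp_ids))
    flagged = [s for s, p in outlier_p.items() if p < alpha]
    return OutlierReport(rss, global_p, outlier_p, flagged, n_sim, seed)
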