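"""Study orchestration: SVMR screen over many outcomes, MVMR adjustment
of the significant ones, BMA ranking, fixed-effect meta-analysis across
cohorts, and paper-style report rendering.

The flow mirrors the emulated study design: a two-sample single-variable
screen of every exposure against every outcome, a nominal significance
gate (IVW p < 0.05) selecting outcomes for multivariable adjustment, and
a Bayesian model-averaging step that ranks the exposures.  Every excluded
SNP is logged with its stage and reason, so the audit identity
"input SNPs = used + dropped" holds for each exposure/outcome pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .bma import bma_diagnostics, bma_enumerate, bma_rerun_without
from .harmonize import harmonize_multi, harmonize_pair
from .instruments import ld_clump, presso_outliers, significance_screen
from .mvmr import mvmr_egger, mvmr_ivw, mvmr_lasso
from .sumstats_io import LDMatrix, SummaryDataset, read_ld_matrix, read_sumstats
from .svmr import MREstimate, Z95, egger, estimate_to_or, ivw, wald_ratio, \
    weighted_median, _norm_p

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    pass


@dataclass
class StudyConfig:
    """Run configuration for the full pipeline (paths + all thresholds)."""

    exposures: dict = field(default_factory=dict)     # label -> path
    outcomes: dict = field(default_factory=dict)      # label -> path (discovery)
    validation_outcomes: dict = field(default_factory=dict)
    ld_path: str | None = None
    ld_format: str = "square"
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000
    palindrome_eaf_window: float = 0.42
    effects_model: str = "multiplicative_random"
    methods: tuple = ("ivw", "egger", "weighted_median")
    n_sim: int = 1000
    n_boot: int = 1000
    prior_inclusion: float = 0.1
    g: float | None = None
    pp_threshold: float = 0.02
    svmr_gate: float = 0.05
    outlier_alpha: float = 0.05
    remove_outliers: bool = True
    seed: int = 0
    out_dir: str = "mrkit_out"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, p in {**self.exposures, **self.outcomes,
                         **self.validation_outcomes}.items():
            if not Path(p).exists():
                raise ConfigError(f"{label}: path {p} does not exist")
        if self.ld_path is not None and not Path(self.ld_path).exists():
            raise ConfigError(f"LD path {self.ld_path} does not exist")
        for name, val, lo, hi in [("p_threshold", self.p_threshold, 0, 1),
                                  ("clump_r2", self.clump_r2, 0, 1),
                                  ("palindrome_eaf_window",
                                   self.palindrome_eaf_window, 0, 0.5),
                                  ("svmr_gate", self.svmr_gate, 0, 1),
                                  ("prior_inclusion", self.prior_inclusion, 0, 1)]:
            if not lo < val <= hi:
                raise ConfigError(f"{name}={val} outside ({lo}, {hi}]")


@dataclass
class MetaEstimate:
    """Inverse-variance pooled estimate across cohorts."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    q: float
    q_df: int
    q_p: float
    n_cohorts: int
    cohort_betas: list = field(default_factory=list)
    cohort_ses: list = field(default_factory=list)


def meta_fixed(estimates: list[MREstimate]) -> MetaEstimate:
    """Fixed-effect inverse-variance meta-analysis of causal estimates."""
    if not estimates:
        raise ValueError("meta_fixed needs at least one estimate")
    b = np.array([e.beta for e in estimates])
    s = np.array([e.se for e in estimates])
    w = 1.0 / s ** 2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - beta) ** 2))
    q_df = len(estimates) - 1
    q_p = float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan
    return MetaEstimate(beta, se, beta - Z95 * se, beta + Z95 * se,
                        _norm_p(beta / se), q, q_df, q_p, len(estimates),
                        list(map(float, b)), list(map(float, s)))


def _prepare_instruments(exposure: SummaryDataset, outcome: SummaryDataset,
                         ld: LDMatrix | None, cfg: StudyConfig,
                         audit: list):
    """Screen, clump, harmonize and outlier-filter one exposure/outcome pair."""
    screened = significance_screen(exposure, cfg.p_threshold)
    for snp in set(exposure.records["snp"]) - set(screened.records["snp"]):
        audit.append((exposure.trait_name, outcome.trait_name, snp,
                      "screen", "above_p_threshold"))
    sel = ld_clump(screened, ld, cfg.clump_r2, cfg.clump_kb)
    for snp, stage, reason in sel.removed:
        audit.append((exposure.trait_name, outcome.trait_name, snp, stage, reason))
    clumped = screened.subset(sel.kept)
    hp = harmonize_pair(clumped, outcome, cfg.palindrome_eaf_window)
    kept = set(hp.snp_ids)
    for snp, action in hp.actions.itertuples(index=False):
        if snp not in kept:
            audit.append((exposure.trait_name, outcome.trait_name, snp,
                          "harmonize", action))
    if cfg.remove_outliers and hp.n_snp >= 4:
        rep = presso_outliers(hp, cfg.n_sim, cfg.outlier_alpha, cfg.seed)
        if rep.flagged:
            for snp in rep.flagged:
                audit.append((exposure.trait_name, outcome.trait_name, snp,
                              "outlier", "presso_flagged"))
            hp = hp.subset([s for s in hp.snp_ids if s not in set(rep.flagged)])
    for snp in hp.snp_ids:
        audit.append((exposure.trait_name, outcome.trait_name, snp, "used", "used"))
    return hp


def _estimate_row(est: MREstimate, gate: float) -> dict:
    o, lo, hi = estimate_to_or(est, 4)
    return {"exposure": est.exposure, "outcome": est.outcome,
            "method": est.method, "nsnp": est.n_snp,
            "beta": est.beta, "se": est.se,
            "or": o, "or_lo95": lo, "or_hi95": hi, "pval": est.pvalue,
            "q": est.q, "q_df": est.q_df, "q_pval": est.q_p,
            "egger_intercept": est.egger_intercept,
            "egger_intercept_p": est.egger_intercept_p,
            "significant": bool(est.pvalue < gate)}


def run_svmr_screen(cfg: StudyConfig, exposures: list[SummaryDataset],
                    outcomes: list[SummaryDataset],
                    ld: LDMatrix | None = None):
    """SVMR screen of every exposure x outcome pair.

    Returns (results table, audit table).  Per-pair failures are logged
    and skipped; the run only aborts on configuration errors.  Rows are
    flagged ``significant`` when the IVW p-value beats the gate, and a
    Benjamini-Hochberg FDR column over IVW rows is appended for reference.
    """
    rows: list = []
    audit: list = []
    for exposure in exposures:
        for outcome in outcomes:
            try:
                hp = _prepare_instruments(exposure, outcome, ld, cfg, audit)
                if hp.n_snp == 1:
                    rows.append(_estimate_row(wald_ratio(hp), cfg.svmr_gate))
                    continue
                rows.append(_estimate_row(ivw(hp, cfg.effects_model),
                                          cfg.svmr_gate))
                if "egger" in cfg.methods and hp.n_snp >= 3:
                    rows.append(_estimate_row(egger(hp), cfg.svmr_gate))
                if "weighted_median" in cfg.methods and hp.n_snp >= 3:
                    rows.append(_estimate_row(
                        weighted_median(hp, cfg.n_boot, cfg.seed), cfg.svmr_gate))
            except Exception as exc:   # per-pair failure: log, continue
                logger.warning("pair (%s, %s) skipped: %s",
                               exposure.trait_name, outcome.trait_name, exc)
                audit.append((exposure.trait_name, outcome.trait_name,
                              "*", "pair_skipped", str(exc)))
    table = pd.DataFrame(rows)
    if len(table):
        ivw_mask = table["method"].str.startswith(("ivw", "wald"))
        table["fdr_bh"] = np.nan
        p = table.loc[ivw_mask, "pval"].to_numpy()
        if p.size:
            order = np.argsort(p)
            ranked = p[order] * p.size / (np.arange(p.size) + 1)
            adj = np.minimum.accumulate(ranked[::-1])[::-1]
            out = np.empty_like(adj)
            out[order] = np.minimum(adj, 1.0)
            table.loc[ivw_mask, "fdr_bh"] = out
    audit_df = pd.DataFrame(audit, columns=["exposure", "outcome", "snp",
                                            "stage", "reason"])
    return table, audit_df


def flagged_outcomes(svmr_table: pd.DataFrame) -> list:
    """Outcomes whose IVW (or Wald) row beat the significance gate."""
    if len(svmr_table) == 0:
        return []
    mask = svmr_table["method"].str.startswith(("ivw", "wald")) \
        & svmr_table["significant"]
    return sorted(svmr_table.loc[mask, "outcome"].unique())


def run_mvmr_adjust(cfg: StudyConfig, exposures: list[SummaryDataset],
                    outcomes: list[SummaryDataset], flagged: list,
                    ld: LDMatrix | None = None,
                    methods: tuple = ("ivw", "egger", "lasso")) -> pd.DataFrame:
    """MVMR adjustment of each flagged outcome by all K exposures jointly.

    Instruments are the union of each exposure's screened-and-clumped
    variants; the attenuation verdict compares each exposure's MVMR
    significance with its SVMR row.  Under-identified outcomes are logged
    and skipped.
    """
    if len(exposures) < 2:
        raise ConfigError("MVMR adjustment needs K >= 2 exposures; use the "
                          "single-variable screen for one exposure")
    pool: set = set()
    for exposure in exposures:
        try:
            screened = significance_screen(exposure, cfg.p_threshold)
        except Exception:
            continue
        sel = ld_clump(screened, ld, cfg.clump_r2, cfg.clump_kb)
        pool |= set(sel.kept)
    rows = []
    out_by_name = {o.trait_name: o for o in outcomes}
    for name in flagged:
        outcome = out_by_name.get(name)
        if outcome is None:
            continue
        try:
            subs = [e.subset(pool) for e in exposures]
            ms = harmonize_multi(subs, outcome, cfg.palindrome_eaf_window)
            fits = {}
            if "ivw" in methods:
                fits["mvmr_ivw"] = mvmr_ivw(ms, cfg.effects_model)
            if "egger" in methods:
                fits["mvmr_egger"] = mvmr_egger(ms)
            if "lasso" in methods:
                fits["mvmr_lasso"] = mvmr_lasso(ms)
        except Exception as exc:
            logger.warning("MVMR for outcome %s skipped: %s", name, exc)
            continue
        for method, est in fits.items():
            for kk, exp_name in enumerate(est.exposure_names):
                rows.append({
                    "outcome": name, "method": method, "exposure": exp_name,
                    "nsnp": est.n_snp,
                    "beta": float(est.beta[kk]), "se": float(est.se[kk]),
                    "or": float(np.round(np.exp(est.beta[kk]), 4)),
                    "or_lo95": float(np.round(np.exp(est.ci_low[kk]), 4)),
                    "or_hi95": float(np.round(np.exp(est.ci_high[kk]), 4)),
                    "pval": float(est.pvalue[kk]),
                    "q": est.q, "q_df": est.q_df, "q_pval": est.q_p,
                    "significant": bool(est.pvalue[kk] < cfg.svmr_gate),
                })
    return pd.DataFrame(rows)


def attenuation_verdicts(svmr_table: pd.DataFrame,
                         mvmr_table: pd.DataFrame) -> pd.DataFrame:
    """Per exposure/outcome: did an SVMR signal survive MVMR adjustment?"""
    rows = []
    if len(mvmr_table) == 0:
        return pd.DataFrame(columns=["exposure", "outcome", "svmr_significant",
                                     "mvmr_significant", "verdict"])
    sv = svmr_table[svmr_table["method"].str.startswith(("ivw", "wald"))]
    sv_sig = {(r.exposure, r.outcome): bool(r.significant)
              for r in sv.itertuples()}
    mv = mvmr_table[mvmr_table["method"] == "mvmr_ivw"]
    for r in mv.itertuples():
        key = (r.exposure, r.outcome)
        was = sv_sig.get(key, False)
        now = bool(r.significant)
        verdict = ("retained" if was and now else
                   "attenuated" if was and not now else
                   "emergent" if now else "null")
        rows.append({"exposure": r.exposure, "outcome": r.outcome,
                     "svmr_significant": was, "mvmr_significant": now,
                     "verdict": verdict})
    return pd.DataFrame(rows)


def run_bma(cfg: StudyConfig, exposures: list[SummaryDataset],
            outcome: SummaryDataset, ld: LDMatrix | None = None):
    """BMA exposure ranking for one outcome, with influence-based rerun."""
    pool: set = set()
    for exposure in exposures:
        try:
            screened = significance_screen(exposure, cfg.p_threshold)
        except Exception:
            continue
        sel = ld_clump(screened, ld, cfg.clump_r2, cfg.clump_kb)
        pool |= set(sel.kept)
    subs = [e.subset(pool) for e in exposures]
    ms = harmonize_multi(subs, outcome, cfg.palindrome_eaf_window)
    result = bma_enumerate(ms, cfg.prior_inclusion, cfg.g)
    diag = bma_diagnostics(ms, result, cfg.pp_threshold)
    rerun = None
    if diag.flagged_snps and ms.n_snp - len(diag.flagged_snps) > ms.n_exposure:
        rerun = bma_rerun_without(ms, diag.flagged_snps,
                                  cfg.prior_inclusion, cfg.g)
    return result, diag, rerun, ms


def render_report(tables: dict, out_dir, cfg: StudyConfig | None = None) -> list:
    """Write result tables as TSV plus a human-readable summary.

    ``tables`` maps name -> DataFrame.  A run-metadata file records the
    configuration, seed and software version for reproducibility.
    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(str(p))
    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        for name, df in tables.items():
            fh.write(f"== {name} ==\n")
            if {"exposure", "outcome", "method", "or"}.issubset(df.columns):
                for _, r in df.iterrows():
                    fh.write(f"{r['exposure']}\t{r['outcome']}\t{r['method']}\t"
                             f"{r['nsnp']}\t{r['or']:.4f}\t"
                             f"[{r['or_lo95']:.4f}-{r['or_hi95']:.4f}]\t"
                             f"{r['pval']:.4g}\n")
            else:
                fh.write(df.to_string(index=False) + "\n")
            fh.write("\n")
    written.append(str(summary))
    meta = out / "run_metadata.yaml"
    with open(meta, "w") as fh:
        payload = {"mrkit_version": __version__}
        if cfg is not None:
            payload["config"] = {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in cfg.__dict__.items()}
        yaml.safe_dump(payload, fh, sort_keys=True)
    written.append(str(meta))
    return written


def load_study(cfg: StudyConfig):
    """Read every dataset named by the config."""
    exposures = [read_sumstats(p, trait_name=label)
                 for label, p in cfg.exposures.items()]
    outcomes = [read_sumstats(p, trait_name=label, trait_type="binary")
                for label, p in cfg.outcomes.items()]
    validation = [read_sumstats(p, trait_name=label, trait_type="binary")
                  for label, p in cfg.validation_outcomes.items()]
    ld = read_ld_matrix(cfg.ld_path, cfg.ld_format) if cfg.ld_path else None
    return exposures, outcomes, validation, ld


def run_full_study(cfg: StudyConfig) -> dict:
    """Execute the complete design: screen, gate, adjust, rank, report."""
    exposures, outcomes, validation, ld = load_study(cfg)
    svmr_table, audit = run_svmr_screen(cfg, exposures, outcomes, ld)
    flagged = flagged_outcomes(svmr_table)
    tables = {"svmr": svmr_table, "audit": audit}
    if len(exposures) >= 2 and flagged:
        mvmr_table = run_mvmr_adjust(cfg, exposures, outcomes, flagged, ld)
        tables["mvmr"] = mvmr_table
        tables["attenuation"] = attenuation_verdicts(svmr_table, mvmr_table)
        out_by_name = {o.trait_name: o for o in outcomes}
        bma_rows = []
        for name in flagged:
            try:
                result, diag, rerun, _ = run_bma(cfg, exposures,
                                                 out_by_name[name], ld)
            except Exception as exc:
                logger.warning("BMA for outcome %s skipped: %s", name, exc)
                continue
            for exp_name in result.mip.index:
                bma_rows.append({"outcome": name, "exposure": exp_name,
                                 "mip": float(result.mip[exp_name]),
                                 "mace": float(result.mace[exp_name]),
                                 "n_flagged_snps": len(diag.flagged_snps)})
        tables["bma"] = pd.DataFrame(bma_rows)
    if validation:
        meta_rows = []
        val_table, _ = run_svmr_screen(cfg, exposures, validation, ld)
        tables["svmr_validation"] = val_table
    render_report(tables, cfg.out_dir, cfg)
    return tables
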