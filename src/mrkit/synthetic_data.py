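"""Simulation of two-sample GWAS summary statistics with known truth.

The generator emulates the study design this package analyses: a panel of
continuous aging exposures (telomere length plus five epigenetic
age-acceleration measures) instrumented by common variants, and binary
haematologic-disease outcomes measured in a separate, much larger sample.
Summary statistics are simulated directly — no individual-level genotypes —
because two-sample MR consumes nothing else.

Model
-----
For each variant j with effect-allele frequency p_j ~ U(0.05, 0.95):

* true exposure effects ``gamma_jk`` are zero except for instrument
  variants, where they are drawn with a configurable spread and
  cross-exposure correlation;
* observed effects add sampling noise,
  ``gamma_hat = gamma + N(0, se^2)`` with
  ``se = 1/sqrt(n_exp * 2 p (1-p))`` (the standard-error of a per-allele
  regression coefficient for a variance-standardized trait);
* the true outcome log-odds effect is
  ``Gamma_j = sum_k theta_k gamma_jk + alpha_j`` where the direct
  (pleiotropic) effect ``alpha_j`` is zero for valid instruments and
  ``N(alpha_mean, alpha_sd^2)`` for an invalid fraction, optionally
  correlated with the instrument strength (an InSIDE violation);
* the binary-outcome scale uses
  ``se_out = 1/sqrt(n_out * cf (1-cf) * 2 p (1-p))`` with case fraction
  ``cf`` — the log-odds SE of a balanced logistic score test.

When per-exposure instrument counts are given, a block-k instrument
affects other exposures only through the exposure-effect correlation
matrix (via a shared latent factor); a single count draws all K effects
jointly multivariate-normal.  Every true quantity is recorded in a
manifest that estimators never read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import CANONICAL_COLUMNS, LDMatrix, SummaryDataset

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass
class SimulationTruth:
    """Ground-truth configuration of one simulated two-sample study."""

    theta: np.ndarray                      # true causal log-OR per exposure
    n_snp: int = 500
    n_instruments: int | list = 50
    gamma_dist: float | np.ndarray = 0.05  # SD of true instrument effects
    proportion_invalid: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_violated: bool = False
    n_exp: int | np.ndarray = 100_000
    n_out: int = 300_000
    case_fraction: float = 0.01
    ld_blocks: list | None = None          # [(size, r2), ...]; None = independent
    exposure_corr: np.ndarray | None = None
    exposure_names: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        k = self.theta.size
        self.gamma_dist = np.broadcast_to(
            np.asarray(self.gamma_dist, float), (k,)).copy()
        self.n_exp = np.broadcast_to(np.asarray(self.n_exp, float), (k,)).copy()
        if self.exposure_corr is None:
            self.exposure_corr = np.eye(k)
        self.exposure_corr = np.asarray(self.exposure_corr, float)
        if self.exposure_corr.shape != (k, k):
            raise ValueError("exposure_corr must be K x K")
        if not np.allclose(np.diag(self.exposure_corr), 1.0):
            raise ValueError("exposure_corr diagonal must be 1")
        if np.linalg.eigvalsh(self.exposure_corr).min() < -1e-10:
            raise ValueError("exposure_corr must be positive semi-definite")
        if not 0 <= self.proportion_invalid <= 1:
            raise ValueError("proportion_invalid must lie in [0, 1]")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not self.exposure_names:
            self.exposure_names = [f"exposure_{i + 1}" for i in range(k)]
        if self.ld_blocks is not None:
            total = sum(size for size, _ in self.ld_blocks)
            if total != self.n_snp:
                raise ValueError(
                    f"ld_blocks sizes sum to {total}, expected n_snp={self.n_snp}")

    @property
    def n_exposure(self) -> int:
        return self.theta.size

    @property
    def instrument_counts(self) -> list:
        if isinstance(self.n_instruments, (list, tuple, np.ndarray)):
            return [int(c) for c in self.n_instruments]
        return [int(self.n_instruments)]

    @property
    def total_instruments(self) -> int:
        return sum(self.instrument_counts)


def _variant_frame(truth: SimulationTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Shared variant scaffold: ids, map positions consistent with the LD
    block layout, alleles and effect-allele frequencies."""
    n = truth.n_snp
    blocks = truth.ld_blocks or [(1, 0.0)] * n
    chrom, pos = [], []
    chr_cursor = {}
    for b, (size, _) in enumerate(blocks):
        c = str(b % 22 + 1)
        start = chr_cursor.get(c, 1_000_000)
        for i in range(size):
            chrom.append(c)
            pos.append(start + i * 10_000)
        # separate blocks on the same chromosome by far more than any window
        chr_cursor[c] = start + size * 10_000 + 50_000_000
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    eaf = rng.uniform(0.05, 0.95, size=n)
    return pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(n)],
        "chr": chrom,
        "pos": pos,
        "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "eaf": eaf,
    })


def _true_gammas(truth: SimulationTruth, rng: np.random.Generator,
                 instrument_idx: np.ndarray, block_of: np.ndarray) -> np.ndarray:
    """Draw the n_snp x K matrix of true per-allele exposure effects."""
    k = truth.n_exposure
    gamma = np.zeros((truth.n_snp, k))
    sd = truth.gamma_dist
    corr = truth.exposure_corr
    if len(truth.instrument_counts) == 1:
        cov = np.diag(sd) @ corr @ np.diag(sd)
        chol = np.linalg.cholesky(cov + 1e-14 * np.eye(k))
        z = rng.standard_normal((instrument_idx.size, k))
        gamma[instrument_idx] = z @ chol.T
    else:
        u = rng.standard_normal(instrument_idx.size)
        for row, j, blk in zip(u, instrument_idx, block_of):
            gamma[j] = sd * corr[blk] * row
    return gamma


def simulate_exposure_panel(truth: SimulationTruth
                            ) -> tuple[list[SummaryDataset], pd.DataFrame]:
    """Simulate one summary dataset per exposure plus the truth manifest.

    Deterministic given ``truth.seed``; the manifest records every true
    effect and instrument flag and is never consumed by estimators.
    """
    rng = np.random.default_rng(truth.seed)
    variants = _variant_frame(truth, rng)
    counts = truth.instrument_counts
    total = truth.total_instruments
    if total > truth.n_snp:
        raise ValueError("more instruments than variants")
    instrument_idx = np.sort(rng.choice(truth.n_snp, size=total, replace=False))
    block_of = np.repeat(np.arange(len(counts)), counts)
    gamma = _true_gammas(truth, rng, instrument_idx, block_of)

    eaf = variants["eaf"].to_numpy()
    var_g = 2.0 * eaf * (1.0 - eaf)
    datasets = []
    manifest = variants.copy()
    is_inst = np.zeros(truth.n_snp, dtype=bool)
    is_inst[instrument_idx] = True
    manifest["is_instrument"] = is_inst
    blk = np.full(truth.n_snp, -1)
    blk[instrument_idx] = block_of
    manifest["instrument_block"] = blk
    for kk, name in enumerate(truth.exposure_names):
        se = 1.0 / np.sqrt(truth.n_exp[kk] * var_g)
        beta_hat = gamma[:, kk] + rng.normal(0.0, se)
        pval = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        rec = variants.copy()
        rec["beta"] = beta_hat
        rec["se"] = se
        rec["pval"] = pval
        rec["n"] = int(truth.n_exp[kk])
        datasets.append(SummaryDataset(name, rec[CANONICAL_COLUMNS],
                                       "continuous", "per 1-SD"))
        manifest[f"gamma_true_{name}"] = gamma[:, kk]
    return datasets, manifest


def simulate_outcome(truth: SimulationTruth, manifest: pd.DataFrame,
                     outcome_name: str = "outcome",
                     randomize_orientation: bool = False
                     ) -> tuple[SummaryDataset, pd.DataFrame]:
    """Simulate the binary-outcome summary dataset implied by a manifest.

    Valid instruments act on the outcome only through the exposures
    (exclusion restriction); an invalid fraction receives a direct effect
    alpha_j, optionally correlated with instrument strength.  With
    ``randomize_orientation`` a random half of the rows is reported on the
    opposite effect allele (beta negated, frequency complemented), which
    harmonization must undo.
    """
    rng = np.random.default_rng((truth.seed + 1_000_003) % 2**31)
    k = truth.n_exposure
    gcols = [f"gamma_true_{n}" for n in truth.exposure_names]
    gamma = manifest[gcols].to_numpy()
    n_snp = len(manifest)

    alpha = np.zeros(n_snp)
    inst = np.flatnonzero(manifest["is_instrument"].to_numpy())
    n_invalid = int(round(truth.proportion_invalid * inst.size))
    invalid = rng.choice(inst, size=n_invalid, replace=False) if n_invalid else \
        np.array([], dtype=int)
    if n_invalid:
        z = rng.standard_normal(n_invalid)
        direct = truth.alpha_mean + truth.alpha_sd * z
        if truth.inside_violated and truth.gamma_dist[0] > 0:
            rho = 0.5
            gstd = gamma[invalid, 0] / truth.gamma_dist[0]
            direct = truth.alpha_mean + truth.alpha_sd * (
                rho * gstd + np.sqrt(1 - rho ** 2) * z)
        alpha[invalid] = direct

    Gamma = gamma @ truth.theta + alpha
    eaf = manifest["eaf"].to_numpy()
    var_g = 2.0 * eaf * (1.0 - eaf)
    cf = truth.case_fraction
    se_out = 1.0 / np.sqrt(truth.n_out * cf * (1.0 - cf) * var_g)
    beta_hat = Gamma + rng.normal(0.0, se_out)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(beta_hat / se_out)),
                   np.finfo(float).tiny, 1.0)

    rec = manifest[["snp", "chr", "pos", "effect_allele", "other_allele",
                    "eaf"]].copy()
    rec["beta"] = beta_hat
    rec["se"] = se_out
    rec["pval"] = pval
    rec["n"] = int(truth.n_out)
    if randomize_orientation:
        swap = rng.random(n_snp) < 0.5
        ea = rec["effect_allele"].to_numpy().copy()
        oa = rec["other_allele"].to_numpy().copy()
        rec.loc[swap, "effect_allele"] = oa[swap]
        rec.loc[swap, "other_allele"] = ea[swap]
        rec.loc[swap, "beta"] = -rec.loc[swap, "beta"]
        rec.loc[swap, "eaf"] = 1.0 - rec.loc[swap, "eaf"]

    out_manifest = manifest.copy()
    out_manifest["alpha_true"] = alpha
    out_manifest["Gamma_true"] = Gamma
    valid = manifest["is_instrument"].to_numpy().copy()
    valid[invalid] = False
    out_manifest["valid_instrument"] = valid
    ds = SummaryDataset(outcome_name, rec[CANONICAL_COLUMNS].reset_index(drop=True),
                        "binary", "log-odds")
    return ds, out_manifest


def simulate_ld(truth: SimulationTruth) -> LDMatrix:
    """Block-diagonal r2 matrix matching the configured LD blocks."""
    n = truth.n_snp
    blocks = truth.ld_blocks or [(1, 0.0)] * n
    mat = np.zeros((n, n))
    start = 0
    for size, r2 in blocks:
        mat[start:start + size, start:start + size] = r2
        start += size
    np.fill_diagonal(mat, 1.0)
    return LDMatrix([f"rs{i + 1}" for i in range(n)], mat)


def simulate_study(truth: SimulationTruth, outcome_name: str = "outcome",
                   randomize_orientation: bool = False):
    """One-call convenience: (exposures, outcome, ld, manifest)."""
    exposures, manifest = simulate_exposure_panel(truth)
    outcome, manifest = simulate_outcome(truth, manifest, outcome_name,
                                         randomize_orientation)
    return exposures, outcome, simulate_ld(truth), manifest


#: the six aging exposures of the emulated study, in report order
PAPER_LIKE_EXPOSURES = ["telomere_length", "grimage_accel", "hannum_accel",
                        "intrinsic_eaa", "dnam_pai1", "phenoage_accel"]


def paper_like_truth(seed: int = 0, n_snp: int = 1200,
                     theta: np.ndarray | None = None) -> SimulationTruth:
    """Scenario shaped like the emulated study.

    Six exposures: telomere length measured in a very large biobank
    (n ~ 472k) with 121 instruments, and five DNA-methylation ageing
    measures from a meta-analysis of ~34.5k with 4/7/22/4/10 instruments.
    The default causal vector gives telomere length a lymphoid-leukaemia-
    scale effect (log 2.4249 per SD) and leaves the ageing measures null.
    The outcome emulates a rare-disease FinnGen-style GWAS
    (1493 cases / 299,952 controls).
    """
    if theta is None:
        theta = np.array([np.log(2.4249), 0.0, 0.0, 0.0, 0.0, 0.0])
    return SimulationTruth(
        theta=theta,
        n_snp=n_snp,
        n_instruments=[121, 4, 7, 22, 4, 10],
        gamma_dist=np.array([0.04, 0.10, 0.10, 0.10, 0.10, 0.10]),
        n_exp=np.array([472_174, 34_467, 34_449, 34_461, 34_448, 34_463]),
        n_out=301_445,
        case_fraction=1493 / 301_445,
        exposure_names=list(PAPER_LIKE_EXPOSURES),
        seed=seed,
    )
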