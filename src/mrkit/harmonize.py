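"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR needs each instrument's exposure effect (gamma) and outcome
effect (Gamma) expressed per copy of the *same* effect allele.  For each
shared SNP the outcome record is oriented to the exposure's effect allele:
matching allele pairs are kept, swapped pairs have the outcome beta negated
and the frequency complemented, and complementary-strand reports (A<->T,
C<->G relabelling) are corrected before the same logic applies.
Palindromic SNPs (A/T or C/G) cannot be oriented from alleles alone; they
are resolved from allele-frequency agreement when frequencies are
informative (minor-allele frequency below the ``palindrome_eaf_window``
bound on both sides) and dropped otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats_io import SummaryDataset

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: per-SNP harmonization action codes
ACTIONS = ("kept", "flipped", "strand_corrected", "dropped_palindromic",
           "dropped_mismatch", "dropped_missing")


class HarmonizationError(Exception):
    pass


@dataclass
class HarmonizedPair:
    """J instruments with exposure and outcome effects on a common allele."""

    snp_ids: list
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray | None = None
    actions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "action"]))
    exposure_name: str = ""
    outcome_name: str = ""
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, float)
        self.se_exp = np.asarray(self.se_exp, float)
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        j = len(self.snp_ids)
        for v in (self.beta_exp, self.se_exp, self.beta_out, self.se_out):
            if v.shape != (j,):
                raise ValueError("harmonized vectors must all have length J")
        if (self.se_exp <= 0).any() or (self.se_out <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, mask) -> "HarmonizedPair":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            keep = set(mask.tolist())
            mask = np.array([s in keep for s in self.snp_ids])
        eaf = self.eaf_exp[mask] if self.eaf_exp is not None else None
        ids = [s for s, m in zip(self.snp_ids, mask) if m]
        return HarmonizedPair(ids, self.beta_exp[mask], self.se_exp[mask],
                              self.beta_out[mask], self.se_out[mask], eaf,
                              self.actions, self.exposure_name,
                              self.outcome_name, self.outcome_type)


@dataclass
class MultiExposureSet:
    """J x K exposure-effect design plus outcome vector for MVMR/BMA."""

    snp_ids: list
    beta_exp: np.ndarray          # J x K
    se_exp: np.ndarray            # J x K
    beta_out: np.ndarray          # J
    se_out: np.ndarray            # J
    exposure_names: list = field(default_factory=list)
    outcome_name: str = ""

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, float))
        self.beta_out = np.asarray(self.beta_out, float)
        self.se_out = np.asarray(self.se_out, float)
        j, k = self.beta_exp.shape
        if self.se_exp.shape != (j, k) or self.beta_out.shape != (j,) \
                or self.se_out.shape != (j,):
            raise ValueError("inconsistent MultiExposureSet shapes")
        if not self.exposure_names:
            self.exposure_names = [f"exposure_{i + 1}" for i in range(k)]
        if np.isnan(self.beta_exp).any() or np.isnan(self.beta_out).any():
            raise ValueError("MultiExposureSet admits no missing entries")

    @property
    def n_snp(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def n_exposure(self) -> int:
        return self.beta_exp.shape[1]

    def subset(self, snp_ids) -> "MultiExposureSet":
        keep = set(snp_ids)
        mask = np.array([s in keep for s in self.snp_ids])
        return MultiExposureSet([s for s in self.snp_ids if s in keep],
                                self.beta_exp[mask], self.se_exp[mask],
                                self.beta_out[mask], self.se_out[mask],
                                list(self.exposure_names), self.outcome_name)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def _orient(ea_x, oa_x, ea_y, oa_y, eaf_x, eaf_y, window):
    """Decide how to orient one outcome record onto the exposure alleles.

    Returns (action, sign) with sign +1/-1 applied to the outcome beta,
    or (drop_action, 0).
    """
    if _is_palindromic(ea_x, oa_x):
        # alleles cannot resolve strand; fall back on frequency agreement
        if {ea_y, oa_y} not in ({ea_x, oa_x},):
            return "dropped_mismatch", 0
        if eaf_x is None or eaf_y is None or np.isnan(eaf_x) or np.isnan(eaf_y):
            return "dropped_palindromic", 0
        if min(eaf_x, 1 - eaf_x) > window or min(eaf_y, 1 - eaf_y) > window:
            return "dropped_palindromic", 0
        eaf_aligned = eaf_y if ea_y == ea_x else 1 - eaf_y
        same = abs(eaf_x - eaf_aligned) <= abs(eaf_x - (1 - eaf_aligned))
        base = +1 if ea_y == ea_x else -1
        return ("kept" if base * (1 if same else -1) > 0 else "flipped",
                base if same else -base)
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "kept", +1
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "flipped", -1
    cea, coa = COMPLEMENT.get(ea_y, "?"), COMPLEMENT.get(oa_y, "?")
    if (cea, coa) == (ea_x, oa_x):
        return "strand_corrected", +1
    if (cea, coa) == (oa_x, ea_x):
        return "strand_corrected", -1
    return "dropped_mismatch", 0


def harmonize_pair(exposure: SummaryDataset, outcome: SummaryDataset,
                   palindrome_eaf_window: float = 0.42) -> HarmonizedPair:
    """Orient outcome effects onto the exposure's effect alleles.

    The result is ordered by exposure p-value ascending; every shared SNP
    receives exactly one action code, and exposure SNPs absent from the
    outcome are logged as ``dropped_missing``.
    """
    exp = exposure.records.set_index("snp", drop=False)
    out = outcome.records.set_index("snp", drop=False)
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise HarmonizationError(
            f"no shared SNPs between {exposure.trait_name} and {outcome.trait_name}")

    log_rows = [(s, "dropped_missing") for s in exp.index.difference(out.index)]
    kept_rows = []
    for snp in shared:
        ex, oy = exp.loc[snp], out.loc[snp]
        action, sign = _orient(ex.effect_allele, ex.other_allele,
                               oy.effect_allele, oy.other_allele,
                               ex.eaf, oy.eaf, palindrome_eaf_window)
        log_rows.append((snp, action))
        if sign != 0:
            kept_rows.append((snp, ex.beta, ex.se, sign * oy.beta, oy.se,
                              ex.eaf, ex.pval))
    actions = pd.DataFrame(log_rows, columns=["snp", "action"])
    if not kept_rows:
        raise HarmonizationError("no SNP survived harmonization")
    kept_rows.sort(key=lambda r: (r[6], str(r[0])))
    ids = [r[0] for r in kept_rows]
    arr = np.array([r[1:6] for r in kept_rows], dtype=float)
    return HarmonizedPair(ids, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3],
                          arr[:, 4], actions, exposure.trait_name,
                          outcome.trait_name, outcome.trait_type)


def harmonize_multi(exposures: list[SummaryDataset], outcome: SummaryDataset,
                    palindrome_eaf_window: float = 0.42) -> MultiExposureSet:
    """Joint harmonization of K >= 2 exposures and one outcome.

    The first exposure fixes the reference orientation; only SNPs present
    and orientable in every dataset survive.  Fails when fewer than K+1
    SNPs remain (the MVMR design would be under-identified).
    """
    if len(exposures) < 2:
        raise ValueError("harmonize_multi needs K >= 2 exposures")
    ref = exposures[0]
    pairs = [harmonize_pair(ref, other, palindrome_eaf_window)
             for other in exposures[1:] + [outcome]]
    common = set(pairs[0].snp_ids)
    for hp in pairs[1:]:
        common &= set(hp.snp_ids)
    k = len(exposures)
    if len(common) < k + 1:
        raise HarmonizationError(
            f"only {len(common)} SNPs orientable across all datasets; need > {k}")
    # order by reference-exposure p-value
    ref_p = ref.records.set_index("snp")["pval"]
    ids = sorted(common, key=lambda s: (ref_p[s], str(s)))
    ref_rec = ref.records.set_index("snp")
    beta = np.empty((len(ids), k))
    se = np.empty((len(ids), k))
    beta[:, 0] = ref_rec.loc[ids, "beta"].to_numpy()
    se[:, 0] = ref_rec.loc[ids, "se"].to_numpy()
    for kk, hp in enumerate(pairs[:-1], start=1):
        pos = {s: i for i, s in enumerate(hp.snp_ids)}
        rows = [pos[s] for s in ids]
        beta[:, kk] = hp.beta_out[rows]
        se[:, kk] = hp.se_out[rows]
    out_hp = pairs[-1]
    pos = {s: i for i, s in enumerate(out_hp.snp_ids)}
    rows = [pos[s] for s in ids]
    return MultiExposureSet(ids, beta, se, out_hp.beta_out[rows],
                            out_hp.se_out[rows],
                            [e.trait_name for e in exposures],
                            outcome.trait_name)
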