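"""Reading, validating and writing GWAS summary statistics and LD matrices.

The canonical on-disk dialect is tab-separated text with a header row and
columns ``snp chr pos effect_allele other_allele eaf beta se pval n``;
missing values are encoded ``NA``.  Positions are 1-based and chromosomes
are stored as strings so that ``X`` and ``MT`` are admissible.  Rows that
violate basic invariants (non-positive SE, identical alleles, frequencies
outside [0,1], ...) are dropped with a machine-readable reason code rather
than aborting the read: real summary exports are dirty and reproducibility
requires logging every exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order of the summary-statistics dialect
CANONICAL_COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

REQUIRED_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

VALID_ALLELES = frozenset("ACGT")


class SumstatsError(Exception):
    """Structural problem with a summary-statistics or LD input."""


@dataclass
class SummaryDataset:
    """One trait's GWAS summary associations.

    ``records`` is a DataFrame in canonical column order, one row per
    variant.  For binary traits ``beta`` is on the log-odds scale; for
    continuous traits it is in the trait's (usually SD) units.
    """

    trait_name: str
    records: pd.DataFrame
    trait_type: str = "continuous"       # continuous | binary
    unit_label: str = ""
    drop_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type}")

    @property
    def n_snp(self) -> int:
        return len(self.records)

    def subset(self, snp_ids) -> "SummaryDataset":
        """Restrict to the given SNP ids, preserving current row order."""
        keep = self.records[self.records["snp"].isin(set(snp_ids))].reset_index(drop=True)
        return SummaryDataset(self.trait_name, keep, self.trait_type, self.unit_label)


@dataclass
class LDMatrix:
    """Pairwise squared correlations (r2) between variants."""

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise SumstatsError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise SumstatsError("LD matrix is not symmetric")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise SumstatsError("LD r2 values outside [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise SumstatsError("LD matrix diagonal must be exactly 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def get(self, snp_a: str, snp_b: str) -> float | None:
        """r2 between two variants; None when either is absent."""
        ia = self._index.get(snp_a)
        ib = self._index.get(snp_b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def _coerce_float(series: pd.Series) -> pd.Series:
    # float() is correctly rounded, so write -> read round-trips exactly
    def parse(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan
    return series.map(parse).astype(float)


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply row-level invariants; return (kept, drop_log).

    Reason codes: ``missing_required``, ``bad_allele``, ``same_alleles``,
    ``nonpositive_se``, ``bad_eaf``, ``bad_pval``, ``bad_n``,
    ``duplicate_snp``.  A row is logged once, under the first failing check.
    """
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("eaf", "beta", "se", "pval", "n"):
        if col in df.columns:
            df[col] = _coerce_float(df[col])
        else:
            df[col] = np.nan
    if "chr" not in df.columns:
        df["chr"] = "NA"
    df["chr"] = df["chr"].astype(str)
    if "pos" not in df.columns:
        df["pos"] = np.nan
    df["pos"] = _coerce_float(df["pos"])

    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask, code):
        fresh = mask & (reasons == "")
        reasons[fresh] = code

    _flag(df["snp"].isna() | df["beta"].isna() | df["se"].isna() | df["pval"].isna(),
          "missing_required")
    _flag(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES),
          "bad_allele")
    _flag(df["effect_allele"] == df["other_allele"], "same_alleles")
    _flag(df["se"] <= 0, "nonpositive_se")
    _flag(df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1)), "bad_eaf")
    _flag((df["pval"] <= 0) | (df["pval"] > 1), "bad_pval")
    _flag(df["n"].notna() & (df["n"] <= 0), "bad_n")
    _flag(df.duplicated(subset="snp", keep="first"), "duplicate_snp")

    bad = reasons != ""
    drop_log = pd.DataFrame({"snp": df.loc[bad, "snp"].astype(str),
                             "reason": reasons[bad]}).reset_index(drop=True)
    kept = df.loc[~bad].reset_index(drop=True)

    # soft check: p implied by |beta/se| should match the stated p within 2x
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(kept["beta"] / kept["se"])
        implied = 2.0 * stats.norm.sf(z)
    ratio = np.where(implied > 0, kept["pval"] / implied, np.inf)
    off = (ratio > 2.0) | (ratio < 0.5)
    # tiny p-values underflow; only warn where the implied p is representable
    off &= implied > 1e-300
    if off.any():
        logger.warning("%d rows have pval inconsistent with beta/se (>2x off)", int(off.sum()))

    return kept[CANONICAL_COLUMNS], drop_log


def read_sumstats(path, column_map: dict | None = None, trait_name: str | None = None,
                  trait_type: str = "continuous", unit_label: str = "") -> SummaryDataset:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"effect_allele": "EA", "other_allele": "NEA"}``.  Rows failing the
    row-level invariants are dropped with a logged reason; a missing
    required column or an empty surviving dataset is fatal.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", "nan", ""])
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{path}: missing required column(s) {missing}")
    kept, drop_log = validate_records(raw)
    if len(kept) == 0:
        raise SumstatsError(f"{path}: zero valid rows after validation")
    if len(drop_log):
        logger.info("%s: dropped %d rows (%s)", path, len(drop_log),
                    drop_log["reason"].value_counts().to_dict())
    name = trait_name if trait_name is not None else str(path)
    return SummaryDataset(name, kept, trait_type, unit_label, drop_log)


def write_sumstats(ds: SummaryDataset, path) -> str:
    """Write a dataset in the canonical dialect; read∘write is the identity."""
    out = ds.records[CANONICAL_COLUMNS].copy()
    # format floats compactly but losslessly
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            vals = []
            for col, v in zip(CANONICAL_COLUMNS, row):
                if col in ("eaf", "beta", "se", "pval"):
                    vals.append("NA" if pd.isna(v) else repr(float(v)))
                elif col in ("pos", "n"):
                    vals.append("NA" if pd.isna(v) else str(int(v)))
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
    return str(path)


def read_ld_matrix(path, format: str = "square") -> LDMatrix:
    """Read an LD (r2) matrix.

    ``square``: first column is ``snp_id``, remaining header names are the
    variant ids in order.  ``long``: columns ``snp_a snp_b r2``; pairs not
    listed default to r2 = 0.  Asymmetry beyond 1e-8 or values outside
    [0, 1] are fatal.
    """
    if format == "square":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        mat = df.to_numpy(dtype=float)
        np.fill_diagonal(mat, 1.0)
        return LDMatrix(ids, mat)
    if format == "long":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise SumstatsError(f"{path}: long LD format needs column {col}")
        ids = sorted(set(df["snp_a"]) | set(df["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)))
        for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"].astype(float)):
            i, j = idx[a], idx[b]
            if mat[i, j] != 0.0 and abs(mat[i, j] - r2) > 1e-8:
                raise SumstatsError(f"{path}: conflicting r2 entries for ({a},{b})")
            mat[i, j] = mat[j, i] = r2
        np.fill_diagonal(mat, 1.0)
        return LDMatrix(ids, mat)
    raise ValueError(f"unknown LD format {format!r}")


def write_ld_matrix(ld: LDMatrix, path) -> str:
    """Write an LD matrix in the square dialect."""
    df = pd.DataFrame(ld.r2, index=pd.Index(ld.snp_ids, name="snp_id"),
                      columns=ld.snp_ids)
    df.to_csv(path, sep="\t")
    return str(path)
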