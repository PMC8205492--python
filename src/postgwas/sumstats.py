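"""GWAS summary statistics: data model, I/O, QC filters, genomic control,
and Bonferroni threshold bookkeeping.

A summary-statistics table holds one row per variant with the marginal
additive effect ``beta`` (trait units per copy of the effect allele, or
log-odds for case/control traits), its standard error ``se`` (so the
effect variance is ``V = se**2``), the two-sided p-value, the effect-allele
frequency ``eaf``, per-variant sample size ``n`` and imputation quality
``info`` (1.0 for genotyped or simulated variants).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "SummaryStats",
    "ThresholdLedger",
    "MHC_GRCH37",
    "CHI2_1_MEDIAN",
    "load_sumstats",
    "write_sumstats",
    "apply_variant_qc",
    "mask_region",
    "genomic_inflation",
    "bonferroni_threshold",
    "format_sig",
]

#: Major histocompatibility complex on GRCh37, 1-based, closed on both ends.
#: Conventionally excluded from post-GWAS analyses because of its extreme
#: long-range LD structure.
MHC_GRCH37: tuple[str, int, int] = ("6", 28477797, 33448354)

#: Median of the chi-square distribution with 1 degree of freedom,
#: 0.4549364 to 7 decimals. Used as the null reference for lambda_GC.
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, 1))

CANONICAL_COLUMNS = ("chrom", "pos", "ref", "alt", "eaf", "beta", "se", "p", "n", "info")

# p-values this small do not round-trip reliably through the normal quantile,
# so the p/z consistency check degrades to a one-sided sanity bound there.
_P_CHECK_FLOOR = 1e-280


@dataclass(frozen=True)
class VariantRecord:
    """One variant's identity, frequency and marginal association summary."""

    chrom: str
    pos: int
    ref: str
    alt: str  # effect allele
    eaf: float
    beta: float
    se: float
    p: float
    n: float
    info: float = 1.0

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def variance(self) -> float:
        """Variance of the effect estimate, V = se**2."""
        return self.se * self.se


@dataclass
class SummaryStats:
    """Position-sorted per-variant association results for one trait.

    ``df`` holds the canonical columns; ``qc_log`` records, in order, each
    filter applied and how many variants it removed.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "case_control"
    df: pd.DataFrame
    build: str = "GRCh37"
    qc_log: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        self.df = _canonicalise(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[VariantRecord]:
        return [VariantRecord(**row) for row in self.df.to_dict("records")]

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def replace(self, df: pd.DataFrame, log_entry: tuple[str, int] | None = None) -> "SummaryStats":
        log = list(self.qc_log)
        if log_entry is not None:
            log.append(log_entry)
        return SummaryStats(self.trait_id, self.trait_type, df.reset_index(drop=True),
                            build=self.build, qc_log=log)


def _chrom_rank(chrom: pd.Series) -> pd.Series:
    """Numeric-first chromosome ordering (1..22 before X, Y, MT, others)."""
    def rank(c: str) -> tuple[int, str]:
        c = str(c)
        c2 = c[3:] if c.lower().startswith("chr") else c
        try:
            return (int(c2), "")
        except ValueError:
            return (1000, c2)
    return chrom.map(rank)


def _canonicalise(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "info"]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if "info" not in df.columns:
        df["info"] = 1.0
    df = df[list(CANONICAL_COLUMNS)]
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    for c in ("eaf", "beta", "se", "p", "n", "info"):
        df[c] = df[c].astype(float)
    order = np.lexsort((df["pos"].to_numpy(), _chrom_rank(df["chrom"]).to_numpy()))
    return df.iloc[order].reset_index(drop=True)


@dataclass(frozen=True)
class ThresholdLedger:
    """Bonferroni-corrected significance threshold with its provenance."""

    alpha: float
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    @property
    def formatted(self) -> str:
        return format_sig(self.threshold, 3)

    def to_json(self) -> str:
        return json.dumps({"alpha": self.alpha, "n_tests": self.n_tests,
                           "threshold": self.threshold})


def bonferroni_threshold(alpha: float, n_tests: int) -> ThresholdLedger:
    """Family-wise error control: per-test threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return ThresholdLedger(float(alpha), int(n_tests))


def format_sig(x: float, sig: int = 3) -> str:
    """Format ``x`` in scientific notation truncated to ``sig`` significant
    figures, e.g. ``format_sig(5e-8 / 11) == "4.54e-9"``.

    Truncation rather than rounding: the printed threshold is then never
    looser (larger) than the computed one, so a p-value that beats the
    printed string always beats the exact threshold.
    """
    if x <= 0 or not np.isfinite(x):
        raise ValueError("format_sig requires a positive finite value")
    d = Decimal(float(x))
    e = d.adjusted()
    mantissa = d.scaleb(-e).quantize(Decimal(1).scaleb(-(sig - 1)), rounding=ROUND_DOWN)
    return f"{mantissa}e{e}"


# ---------------------------------------------------------------------------
# I/O


def _row_validity(df: pd.DataFrame, z_tol: float) -> tuple[pd.Series, pd.Series]:
    """Masks of rows with invalid fields and rows whose p disagrees with
    beta/se under a two-sided normal test (tolerance on the z-score)."""
    invalid = (
        ~np.isfinite(df["beta"]) | ~np.isfinite(df["se"]) | (df["se"] <= 0)
        | ~df["eaf"].between(0.0, 1.0)
        | ~((df["p"] > 0.0) & (df["p"] <= 1.0))
        | (df["pos"] < 1)
        | ~df["info"].between(0.0, 1.0)
        | (df["n"] <= 0)
    )
    z_calc = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
    with np.errstate(divide="ignore", over="ignore"):
        z_from_p = stats.norm.isf(np.clip(df["p"].to_numpy(), 0.0, 1.0) / 2.0)
    small_p = df["p"].to_numpy() <= _P_CHECK_FLOOR
    mismatch = np.abs(z_from_p - z_calc) > z_tol * (1.0 + z_calc)
    # beyond the floor, only require the z-score to be extreme as well
    mismatch = np.where(small_p, z_calc < stats.norm.isf(_P_CHECK_FLOOR / 2.0) - 1.0, mismatch)
    inconsistent = pd.Series(mismatch, index=df.index) & ~invalid
    return invalid, inconsistent


def load_sumstats(
    path,
    dialect: dict[str, str] | None = None,
    trait_id: str = "trait",
    trait_type: str = "quantitative",
    build: str = "GRCh37",
    z_tol: float = 1e-6,
) -> SummaryStats:
    """Read a tab-delimited (optionally gzipped) summary-statistics file.

    ``dialect`` maps canonical column names (chrom, pos, ref, alt, eaf, beta,
    se, p, n, info) to the file's column names; unmapped names are taken
    verbatim. Rows violating the record invariants — including a stored
    p-value inconsistent with beta/se under a two-sided normal test, at
    relative tolerance ``z_tol`` on the z-score — are rejected and counted in
    the QC log. Published files with heavily rounded p-values may need a
    looser ``z_tol``.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    dialect = dialect or {}
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        src = dialect.get(canonical, canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical != "info":
            raise ValueError(f"missing mandatory column {src!r} (for {canonical!r})")
    df = raw.rename(columns=rename)
    if "info" not in df.columns:
        df["info"] = 1.0
    df = df[list(CANONICAL_COLUMNS)]

    qc_log: list[tuple[str, int]] = []
    coerced = df.copy()
    coerced["chrom"] = coerced["chrom"].astype(str)
    for c in ("pos", "eaf", "beta", "se", "p", "n", "info"):
        coerced[c] = pd.to_numeric(coerced[c], errors="coerce")
    unparseable = coerced[[c for c in CANONICAL_COLUMNS if c != "chrom"]].isna().any(axis=1)
    if unparseable.any():
        qc_log.append(("unparseable_row", int(unparseable.sum())))
        coerced = coerced[~unparseable]
    coerced["pos"] = coerced["pos"].astype(np.int64)

    invalid, inconsistent = _row_validity(coerced, z_tol)
    if invalid.any():
        qc_log.append(("invalid_field", int(invalid.sum())))
    if inconsistent.any():
        qc_log.append(("p_beta_se_inconsistent", int(inconsistent.sum())))
    coerced = coerced[~(invalid | inconsistent)]

    dup = coerced.duplicated(subset=["chrom", "pos", "ref", "alt"], keep="first")
    if dup.any():
        qc_log.append(("duplicate_variant", int(dup.sum())))
        coerced = coerced[~dup]

    return SummaryStats(trait_id, trait_type, coerced.reset_index(drop=True),
                        build=build, qc_log=qc_log)


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write the canonical tab-delimited format at full float precision."""
    out = ss.df.copy()
    for c in ("eaf", "beta", "se", "p", "n", "info"):
        out[c] = out[c].map(repr)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filters


def apply_variant_qc(ss: SummaryStats, maf_min: float = 0.01,
                     info_min: float = 0.9) -> SummaryStats:
    """Drop variants with MAF below ``maf_min`` or imputation quality below
    ``info_min``. Boundaries are inclusive for passing (MAF of exactly
    ``maf_min`` is retained). Filters are applied sequentially so the QC-log
    counts sum to the total removed.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= info_min <= 1.0):
        raise ValueError("maf_min and info_min must lie in [0, 1]")
    df = ss.df
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = maf >= maf_min
    out = ss.replace(df[keep], (f"maf<{maf_min}", int((~keep).sum())))
    keep2 = out.df["info"] >= info_min
    return out.replace(out.df[keep2], (f"info<{info_min}", int((~keep2).sum())))


def mask_region(ss: SummaryStats,
                region: tuple[str, int, int] = MHC_GRCH37) -> SummaryStats:
    """Remove variants inside a closed 1-based interval (default: the MHC)."""
    chrom, start, end = region
    if start > end:
        raise ValueError("region start must not exceed end")
    df = ss.df
    inside = (df["chrom"] == str(chrom)) & df["pos"].between(start, end)
    return ss.replace(df[~inside], (f"mask_{chrom}:{start}-{end}", int(inside.sum())))


# ---------------------------------------------------------------------------
# Genomic control


def genomic_inflation(ss: SummaryStats | Sequence[float] | np.ndarray) -> float:
    """Genomic-control inflation factor lambda_GC.

    The median association chi-square, (beta/se)^2, divided by the median of
    the 1-df chi-square distribution (0.4549364). Approximately 1 under the
    null; values above ~1.1 suggest confounding or strong polygenicity. The
    caller is responsible for passing an LD-pruned variant set; accepts
    either a SummaryStats or a raw array of z-scores.
    """
    if isinstance(ss, SummaryStats):
        if len(ss) == 0:
            raise ValueError("cannot compute lambda_GC on an empty set")
        z = ss.df["beta"].to_numpy() / ss.df["se"].to_numpy()
    else:
        z = np.asarray(ss, dtype=float)
        if z.size == 0:
            raise ValueError("cannot compute lambda_GC on an empty set")
    return float(np.median(z * z) / CHI2_1_MEDIAN)
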