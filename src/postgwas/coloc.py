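"""Two-trait Bayesian colocalisation from per-variant Wakefield ABFs.

Over the l variants of a shared region, five hypotheses are compared:
H0 no association with either trait; H1/H2 association with trait 1/2
only; H3 two distinct causal variants; H4 one shared causal variant.
With per-variant prior probabilities p1, p2 (single-trait association) and
p12 (shared association), the unnormalised evidence terms are

    H0: 1
    H1: p1  * sum_j BF1_j
    H2: p2  * sum_j BF2_j
    H3: p1 * p2 * sum_{j != k} BF1_j BF2_k
    H4: p12 * sum_j BF1_j BF2_j

computed in log space. Posterior probabilities PP0..PP4 follow by
normalisation. A pair of signals shows *strong* colocalisation when
PP3 + PP4 >= 0.99 and PP4 / PP3 >= 5; the symmetric "distinct" label
(PP3 + PP4 >= 0.99 and PP3 / PP4 >= 5) is a convenience addition of this
package rather than part of the published rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import log_abf
from .sumstats import SummaryStats

__all__ = ["ColocPriors", "ColocResult", "harmonise_pair",
           "coloc_posteriors", "coloc_decision"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

# below this region size the distinct-variant sum is enumerated directly;
# above it, computed as lse-subtraction of the diagonal from the product
_ENUM_MAX = 200


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities (coloc's documented defaults)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) < 1.0):
            raise ValueError("require 0 < p12 <= p1, p2 < 1")


@dataclass
class ColocResult:
    pp: np.ndarray        # PP0..PP4
    n_variants: int
    decision: str         # strong_coloc | distinct | inconclusive

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        assert self.pp.shape == (5,)


def harmonise_pair(ss1: SummaryStats, ss2: SummaryStats,
                   region: tuple[str, int, int] | None = None) -> pd.DataFrame:
    """Intersect two traits' variants on (chrom, pos) and align effect
    alleles.

    When the second file's ref/alt are swapped relative to the first, its
    beta is negated and eaf complemented. Variants whose alleles match
    neither way are dropped, as are strand-ambiguous (A/T, C/G) variants
    with eaf in [0.4, 0.6] in either study (their orientation cannot be
    resolved from frequency). Returns a merged frame with _1/_2 suffixed
    statistics; the ``flipped``/``dropped_*`` bookkeeping is attached in
    ``DataFrame.attrs["log"]``.
    """
    d1, d2 = ss1.df, ss2.df
    if region is not None:
        chrom, start, end = region
        d1 = d1[(d1["chrom"] == str(chrom)) & d1["pos"].between(start, end)]
        d2 = d2[(d2["chrom"] == str(chrom)) & d2["pos"].between(start, end)]
    merged = d1.merge(d2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no shared variants between the two traits in the region")

    same = (merged["ref_1"] == merged["ref_2"]) & (merged["alt_1"] == merged["alt_2"])
    swapped = (merged["ref_1"] == merged["alt_2"]) & (merged["alt_1"] == merged["ref_2"])
    log = {"flipped": int((swapped & ~same).sum()),
           "dropped_allele_mismatch": int((~same & ~swapped).sum())}
    merged = merged[same | swapped].copy()
    flip = (~same & swapped)[same | swapped]
    merged.loc[flip, "beta_2"] = -merged.loc[flip, "beta_2"]
    merged.loc[flip, "eaf_2"] = 1.0 - merged.loc[flip, "eaf_2"]

    pairs = list(zip(merged["ref_1"].astype(str).str.upper(),
                     merged["alt_1"].astype(str).str.upper()))
    ambiguous = np.array([p in _AMBIGUOUS for p in pairs])
    mid_freq = (merged["eaf_1"].between(0.4, 0.6) | merged["eaf_2"].between(0.4, 0.6)).to_numpy()
    drop = ambiguous & mid_freq
    log["dropped_strand_ambiguous"] = int(drop.sum())
    merged = merged[~drop].reset_index(drop=True)
    if merged.empty:
        raise ValueError("no variants left after allele harmonisation")
    merged.attrs["log"] = log
    return merged


def _log_s3(lam1: np.ndarray, lam2: np.ndarray) -> float:
    """log sum over ordered pairs j != k of exp(lam1_j + lam2_k)."""
    l = lam1.size
    if l == 1:
        return -np.inf
    if l <= _ENUM_MAX:
        M = lam1[:, None] + lam2[None, :]
        np.fill_diagonal(M, -np.inf)
        return float(logsumexp(M))
    s_all = float(logsumexp(lam1) + logsumexp(lam2))
    s_diag = float(logsumexp(lam1 + lam2))
    # guarded subtraction; falls back to enumeration on catastrophic cancellation
    delta = s_diag - s_all
    if delta > -1e-12:
        M = lam1[:, None] + lam2[None, :]
        np.fill_diagonal(M, -np.inf)
        return float(logsumexp(M))
    return s_all + float(np.log1p(-np.exp(delta)))


def coloc_posteriors(paired: pd.DataFrame, priors: ColocPriors = ColocPriors(),
                     omega1: float = 0.0225, omega2: float = 0.0225) -> ColocResult:
    """Posterior probabilities PP0..PP4 from harmonised paired records.

    ``omega1``/``omega2`` are the Wakefield prior effect variances for the
    two traits — (0.15 * sdY)^2 for quantitative traits (0.0225 at sdY = 1),
    0.04 for case/control.
    """
    lam1 = log_abf(paired["beta_1"].to_numpy(), paired["se_1"].to_numpy() ** 2, omega1)
    lam2 = log_abf(paired["beta_2"].to_numpy(), paired["se_2"].to_numpy() ** 2, omega2)
    lam1 = np.atleast_1d(lam1)
    lam2 = np.atleast_1d(lam2)
    s1 = float(logsumexp(lam1))
    s2 = float(logsumexp(lam2))
    s4 = float(logsumexp(lam1 + lam2))
    s3 = _log_s3(lam1, lam2)
    logh = np.array([
        0.0,
        np.log(priors.p1) + s1,
        np.log(priors.p2) + s2,
        np.log(priors.p1) + np.log(priors.p2) + s3,
        np.log(priors.p12) + s4,
    ])
    pp = np.exp(logh - logsumexp(logh))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_variants=int(lam1.size), decision=coloc_decision(pp))


def coloc_decision(pp: np.ndarray | "ColocResult") -> str:
    """Categorical call from PP3 and PP4.

    strong_coloc when PP3 + PP4 >= 0.99 and PP4/PP3 >= 5 (PP3 = 0 counts as
    satisfied); distinct when PP3 + PP4 >= 0.99 and PP3/PP4 >= 5; otherwise
    inconclusive.
    """
    if isinstance(pp, ColocResult):
        pp = pp.pp
    pp3, pp4 = float(pp[3]), float(pp[4])
    if pp3 + pp4 >= 0.99:
        if pp3 == 0.0 or pp4 / pp3 >= 5.0:
            return "strong_coloc"
        if pp4 == 0.0 or pp3 / pp4 >= 5.0:
            return "distinct"
    return "inconclusive"
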