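"""Locus definition, approximate conditional (joint) analysis from summary
statistics plus a reference LD panel, and nearest-gene annotation.

The conditional analysis reconstructs multiple-regression fits of selected
variants from marginal summary statistics: with D_j an estimate of the
centred sum of squares of variant j's dosage (default: the LD panel's
empirical dosage variance scaled by n_j) and r_jk the panel correlation,

    (X'X)_jk ~= r_jk * sqrt(D_j * D_k),    (X'y)_j = D_j * beta_j,

and the phenotype sum of squares y'y is recovered per variant from the
marginal-fit identity y'y = D_j * (se_j^2 * (n_j - 2) + beta_j^2) (median
over variants). Joint coefficients, standard errors and p-values then
follow from ordinary least-squares algebra. When the panel is the
association sample itself this reproduces the exact in-sample joint fit.

Forward stepwise selection over a locus keeps adding the candidate with the
smallest conditional p-value while it stays below the joint-significance
threshold (default 1e-8) and is not collinear (r^2 < 0.9) with the
selected set; the surviving variants are the locus's conditionally
independent signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldpanel import LDPanel
from .sumstats import SummaryStats, VariantRecord

__all__ = ["Locus", "Signal", "find_loci", "stepwise_conditional",
           "nearest_gene", "load_gene_table"]


@dataclass
class Locus:
    """Window around an index variant (default +/- 500 kb, clipped at 1)."""

    index: int                   # row position of the index variant in ss.df
    chrom: str
    start: int
    end: int
    member_indices: np.ndarray   # row positions of all window members
    index_p: float


@dataclass
class Signal:
    """One conditionally independent association signal at a locus."""

    locus: Locus
    lead: VariantRecord
    lead_index: int              # row position in ss.df
    joint_beta: float
    joint_se: float
    p_joint: float
    conditional_on: list[tuple[str, int]] = field(default_factory=list)
    gene: str | None = None
    gene_distance: int | None = None


def find_loci(ss: SummaryStats, p_threshold: float,
              flank_bp: int = 500_000) -> list[Locus]:
    """Greedy locus definition around significant index variants.

    Iteratively take the smallest-p unassigned variant with p < p_threshold
    as an index and assign every variant within ``flank_bp`` of it to that
    locus; overlapping windows merge transitively into one locus that keeps
    the smallest-p index. Deterministic and invariant to input record order
    (records are kept position-sorted; p ties break on genomic position).
    """
    df = ss.df
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].to_numpy()
    p = df["p"].to_numpy()
    assigned = np.zeros(len(df), dtype=bool)
    raw: list[Locus] = []
    while True:
        eligible = np.nonzero(~assigned & (p < p_threshold))[0]
        if eligible.size == 0:
            break
        idx = int(eligible[np.argmin(p[eligible])])  # ties: first in position order
        lo, hi = max(1, pos[idx] - flank_bp), pos[idx] + flank_bp
        members = np.nonzero((chrom == chrom[idx]) & (pos >= lo) & (pos <= hi))[0]
        assigned[members] = True
        raw.append(Locus(idx, str(chrom[idx]), int(lo), int(hi), members, float(p[idx])))

    # transitive merge of overlapping windows on the same chromosome
    raw.sort(key=lambda L: (L.chrom, L.start))
    merged: list[Locus] = []
    for loc in raw:
        if merged and merged[-1].chrom == loc.chrom and loc.start <= merged[-1].end:
            prev = merged[-1]
            keep, other = (prev, loc) if prev.index_p <= loc.index_p else (loc, prev)
            members = np.union1d(prev.member_indices, loc.member_indices)
            merged[-1] = Locus(keep.index, keep.chrom, min(prev.start, loc.start),
                               max(prev.end, loc.end), members, keep.index_p)
        else:
            merged.append(loc)
    merged.sort(key=lambda L: L.index_p)
    return merged


# ---------------------------------------------------------------------------
# Approximate conditional / joint analysis


class _JointModel:
    """Summary-statistic reconstruction of joint least-squares fits."""

    def __init__(self, ss: SummaryStats, panel: LDPanel, locus: Locus,
                 freq_diff_max: float, var_mode: str):
        df = ss.df
        self.rows = np.asarray(locus.member_indices, dtype=int)
        pidx = panel.variant_index()
        keys = [
            (str(df["chrom"].iat[i]), int(df["pos"].iat[i]),
             str(df["ref"].iat[i]), str(df["alt"].iat[i]))
            for i in self.rows
        ]
        self.panel_col = np.array([pidx.get(k, -1) for k in keys])
        self.log: list[str] = []

        eaf_ss = df["eaf"].to_numpy()[self.rows]
        self.n = df["n"].to_numpy()[self.rows]
        self.beta = df["beta"].to_numpy()[self.rows]
        self.se = df["se"].to_numpy()[self.rows]
        self.p_marg = df["p"].to_numpy()[self.rows]

        panel_eaf = panel.eaf()
        self.usable = self.panel_col >= 0
        freq_ok = np.zeros(len(self.rows), dtype=bool)
        has = self.usable
        freq_ok[has] = np.abs(eaf_ss[has] - panel_eaf[self.panel_col[has]]) <= freq_diff_max
        n_mismatch = int(has.sum() - freq_ok[has].sum())
        if n_mismatch:
            self.log.append(f"excluded {n_mismatch} variant(s) with panel allele-frequency mismatch")
        self.usable &= freq_ok

        if var_mode == "panel":
            var_g = np.full(len(self.rows), np.nan)
            var_g[self.usable] = panel.variances()[self.panel_col[self.usable]]
        elif var_mode == "hwe":
            var_g = 2.0 * eaf_ss * (1.0 - eaf_ss)
        else:
            raise ValueError("var_mode must be 'panel' or 'hwe'")
        self.D = self.n * var_g
        if self.usable.any():
            with np.errstate(invalid="ignore"):
                yty_j = self.D * (self.se ** 2 * (self.n - 2.0) + self.beta ** 2)
            self.yty = float(np.nanmedian(yty_j[self.usable]))
            self.n_eff = float(np.median(self.n[self.usable]))
        else:
            self.yty = self.n_eff = float("nan")
        self.panel = panel

    def r_matrix(self, local: list[int]) -> np.ndarray:
        return self.panel.corr(self.panel_col[local])

    def fit(self, local: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Joint beta, se and two-sided normal p for the given member
        subset (positions within the locus member list)."""
        k = len(local)
        R = self.r_matrix(local)
        d = self.D[local]
        B = R * np.sqrt(np.outer(d, d))
        Xy = d * self.beta[local]
        cond = np.linalg.cond(B)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError(f"ill-conditioned joint LD matrix (cond={cond:.2g})")
        b = np.linalg.solve(B, Xy)
        dof = self.n_eff - k - 1
        sigma2 = (self.yty - float(b @ Xy)) / dof
        sigma2 = max(sigma2, 1e-12 * self.yty / dof)  # guard against negative residual SS
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(B)))
        z = b / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return b, se, p


def stepwise_conditional(ss: SummaryStats, panel: LDPanel, locus: Locus,
                         p_joint_max: float = 1e-8, r2_collinear: float = 0.9,
                         freq_diff_max: float = 0.2,
                         var_mode: str = "panel") -> list[Signal]:
    """Forward stepwise selection of conditionally independent signals.

    Starts from the marginal lead; at each step fits, from summary data and
    panel LD, the joint model of the selected set plus each candidate and
    adds the candidate with the smallest conditional p if it is below
    ``p_joint_max`` and has r^2 below ``r2_collinear`` with every selected
    variant. Candidates absent from the panel, or whose allele frequency
    disagrees with the panel's by more than ``freq_diff_max``, are excluded.
    A final backward sweep refits the selected set and drops variants whose
    joint p rose above the threshold, so every reported signal satisfies
    p_joint < p_joint_max.
    """
    model = _JointModel(ss, panel, locus, freq_diff_max, var_mode)
    # the index variant must be resolvable in the panel
    index_local = np.nonzero(model.rows == locus.index)[0]
    if index_local.size and model.panel_col[index_local[0]] < 0:
        raise ValueError("LD panel does not cover the locus index variant")
    usable = np.nonzero(model.usable)[0]
    if usable.size == 0:
        return []

    lead = int(usable[np.argmin(model.p_marg[usable])])
    selected = [lead]
    _, _, p0 = model.fit(selected)
    if p0[0] >= p_joint_max:
        return []

    while True:
        best: tuple[float, int] | None = None
        for cand in usable:
            if cand in selected:
                continue
            try:
                r_with_sel = model.panel.corr(
                    np.append(model.panel_col[selected], model.panel_col[cand])
                )[-1, :-1]
            except ValueError:
                continue  # degenerate column
            if np.any(r_with_sel ** 2 >= r2_collinear):
                continue
            try:
                _, _, p = model.fit(selected + [int(cand)])
            except np.linalg.LinAlgError as err:
                model.log.append(f"candidate {int(cand)} skipped: {err}")
                continue
            p_cond = float(p[-1])
            if best is None or p_cond < best[0]:
                best = (p_cond, int(cand))
        if best is None or best[0] >= p_joint_max:
            break
        selected.append(best[1])

    # backward sweep: enforce p_joint < p_joint_max for every reported signal
    while True:
        b, se, p = model.fit(selected)
        if len(selected) == 1 or np.all(p < p_joint_max):
            break
        worst = int(np.argmax(p))
        model.log.append(f"dropped variant {selected[worst]} in backward sweep (p_joint={p[worst]:.3g})")
        del selected[worst]
    if len(selected) == 1 and p[0] >= p_joint_max:
        return []

    signals = []
    leads = [(str(ss.df['chrom'].iat[model.rows[i]]), int(ss.df['pos'].iat[model.rows[i]]))
             for i in selected]
    for k, i in enumerate(selected):
        row = int(model.rows[i])
        lead_rec = VariantRecord(**ss.df.iloc[row].to_dict())
        signals.append(Signal(
            locus=locus, lead=lead_rec, lead_index=row,
            joint_beta=float(b[k]), joint_se=float(se[k]), p_joint=float(p[k]),
            conditional_on=[leads[j] for j in range(len(selected)) if j != k],
        ))
    signals.sort(key=lambda s: s.p_joint)
    return signals


def conditional_estimates(ss: SummaryStats, panel: LDPanel, locus: Locus,
                          condition_on: list[int],
                          var_mode: str = "panel") -> pd.DataFrame:
    """Per-variant effect estimates conditioned on a set of locus variants.

    ``condition_on`` are row positions in ``ss.df``. For each other usable
    member, the joint model of {conditioning set + variant} is fitted and
    the variant's joint estimate reported. A variant uncorrelated with the
    conditioning set keeps its marginal beta exactly.
    """
    model = _JointModel(ss, panel, locus, freq_diff_max=0.2, var_mode=var_mode)
    local_of_row = {int(r): i for i, r in enumerate(model.rows)}
    sel = [local_of_row[int(r)] for r in condition_on]
    out = []
    for i in np.nonzero(model.usable)[0]:
        if i in sel:
            continue
        try:
            b, se, p = model.fit(sel + [int(i)])
        except np.linalg.LinAlgError:
            continue
        row = int(model.rows[i])
        out.append({"row": row, "chrom": ss.df["chrom"].iat[row],
                    "pos": int(ss.df["pos"].iat[row]),
                    "beta_cond": float(b[-1]), "se_cond": float(se[-1]),
                    "p_cond": float(p[-1])})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Nearest-gene annotation


def load_gene_table(path) -> pd.DataFrame:
    """BED-like gene table: chrom, txStart, txEnd, strand, name (TSV)."""
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "txStart", "txEnd", "strand", "name"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return genes


def nearest_gene(chrom: str, pos: int,
                 genes: pd.DataFrame) -> tuple[str | None, int | None]:
    """Nearest protein-coding gene by TSS distance.

    The TSS is txStart on the + strand and txEnd on the - strand. Distance
    is 0 when the position lies inside the transcript body; ties break on
    smaller TSS, then lexicographic name. Returns (None, None) when the
    chromosome has no gene.
    """
    sub = genes[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return None, None
    tss = np.where(sub["strand"].to_numpy() == "+",
                   sub["txStart"].to_numpy(), sub["txEnd"].to_numpy())
    inside = (sub["txStart"].to_numpy() <= pos) & (pos <= sub["txEnd"].to_numpy())
    dist = np.where(inside, 0, np.abs(tss - pos))
    key = sorted(zip(dist, tss, sub["name"].to_numpy()))
    d, _, name = key[0]
    return str(name), int(d)


def annotate_signals(signals: list[Signal], genes: pd.DataFrame) -> list[Signal]:
    for s in signals:
        s.gene, s.gene_distance = nearest_gene(s.lead.chrom, s.lead.pos, genes)
    return signals
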