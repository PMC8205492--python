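"""Reference-panel handling: dosage matrices, pairwise LD, greedy LD
pruning, and panel subsampling.

Dosages (expected alternate-allele counts in [0, 2]) are the native
representation so imputed panels work unchanged; hard calls are the special
case of integer dosages. Missing dosages are NaN and handled
pairwise-complete in correlation computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LDPanel", "pairwise_r", "ld_prune", "subsample_panel",
           "save_panel", "load_panel", "panel_from_vcf"]

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class LDPanel:
    """samples x variants dosage matrix with aligned variant identities."""

    dosages: np.ndarray
    variants: pd.DataFrame  # columns chrom, pos, ref, alt (one row per matrix column)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not np.issubdtype(self.dosages.dtype, np.floating):
            self.dosages = self.dosages.astype(float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants matrix")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant table length must equal dosage column count")
        self.variants = self.variants.reset_index(drop=True)
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> np.ndarray:
        """Effect (alt) allele frequency per variant, ignoring missing."""
        return np.nanmean(self.dosages, axis=0, dtype=np.float64) / 2.0

    def variances(self) -> np.ndarray:
        """Per-variant empirical dosage variance (ddof=0, missing ignored)."""
        return np.nanvar(self.dosages.astype(np.float64, copy=False), axis=0)

    def variant_index(self) -> dict[tuple[str, int, str, str], int]:
        v = self.variants
        return {
            (str(c), int(p), str(r), str(a)): i
            for i, (c, p, r, a) in enumerate(
                zip(v["chrom"], v["pos"], v["ref"], v["alt"])
            )
        }

    def corr(self, indices: np.ndarray | list[int]) -> np.ndarray:
        """Correlation matrix of the given variant columns.

        Complete-case across the selected columns (simulated panels have no
        missingness, so this is exact there); degenerate columns raise.
        """
        cols = self.dosages[:, list(indices)].astype(np.float64, copy=False)
        ok = ~np.isnan(cols).any(axis=1)
        cols = cols[ok]
        sd = cols.std(axis=0)
        if np.any(sd == 0):
            bad = [int(i) for i, s in zip(indices, sd) if s == 0]
            raise ValueError(f"zero-variance variant column(s) {bad}")
        return np.corrcoef(cols, rowvar=False).reshape(len(sd), len(sd))


def pairwise_r(panel: LDPanel, i: int, j: int) -> float:
    """Pearson correlation of dosage columns i and j over pairwise-complete
    samples. r(i, i) = 1 and r is symmetric by construction."""
    x = panel.dosages[:, i]
    y = panel.dosages[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x = x[ok].astype(np.float64, copy=False)
    y = y[ok].astype(np.float64, copy=False)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx, syy = float(xc @ xc), float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise ValueError(f"zero-variance variant column ({i if sxx == 0 else j})")
    # explicit two-pass form: symmetric in (i, j) to the last ulp
    return float(np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0))


def ld_prune(panel: LDPanel, r2_max: float = 0.8,
             window_bp: int = 1_000_000,
             order: np.ndarray | list[int] | None = None) -> list[int]:
    """Greedy keep-first LD pruning.

    Scan variants in ``order`` (default: genomic position); drop a variant if
    its squared correlation with any already-retained variant within
    ``window_bp`` reaches ``r2_max``. Deterministic for a fixed order; the
    retained set never contains a pair with r^2 >= r2_max inside the window.
    """
    if not (0.0 < r2_max <= 1.0):
        raise ValueError("r2_max must lie in (0, 1]")
    v = panel.variants
    if order is None:
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].astype(str).to_numpy()))
    retained: list[int] = []
    for idx in order:
        idx = int(idx)
        chrom, pos = v["chrom"].iat[idx], v["pos"].iat[idx]
        drop = False
        for kept in retained:
            if v["chrom"].iat[kept] != chrom:
                continue
            if abs(int(v["pos"].iat[kept]) - int(pos)) > window_bp:
                continue
            if pairwise_r(panel, kept, idx) ** 2 >= r2_max:
                drop = True
                break
        if not drop:
            retained.append(idx)
    return sorted(retained)


def subsample_panel(panel: LDPanel, n: int, seed: int) -> LDPanel:
    """Uniform sampling of ``n`` panel samples without replacement,
    reproducible under ``seed``. Mirrors drawing a random LD reference
    subset from a larger cohort."""
    if n > panel.n_samples:
        raise ValueError(f"requested {n} samples from a panel of {panel.n_samples}")
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(panel.n_samples, size=n, replace=False))
    return LDPanel(panel.dosages[rows], panel.variants.copy(),
                   [panel.sample_ids[i] for i in rows])


# ---------------------------------------------------------------------------
# I/O


def save_panel(panel: LDPanel, matrix_path, variants_path) -> None:
    """NPZ dosage matrix plus a sidecar variant TSV."""
    np.savez_compressed(matrix_path, dosages=panel.dosages,
                        sample_ids=np.array(panel.sample_ids, dtype=object))
    panel.variants.to_csv(variants_path, sep="\t", index=False)


def load_panel(matrix_path, variants_path) -> LDPanel:
    with np.load(matrix_path, allow_pickle=True) as z:
        dosages = z["dosages"]
        sample_ids = [str(s) for s in z["sample_ids"]]
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    return LDPanel(dosages, variants, sample_ids)


def panel_from_vcf(path, region: str | None = None) -> LDPanel:
    """Ingest a VCF into dosages: DS field when present, else summed GT
    alleles; missing genotypes become NaN. Requires pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    records = vf.fetch(region=region) if region else vf
    for rec in records:
        if rec.alts is None or len(rec.alts) != 1:
            continue  # biallelic only
        dose = np.full(len(sample_ids), np.nan)
        for k, sample in enumerate(rec.samples.values()):
            if "DS" in sample and sample["DS"] is not None:
                dose[k] = float(sample["DS"])
            elif sample.get("GT") is not None:
                alleles = [a for a in sample["GT"] if a is not None]
                if alleles:
                    dose[k] = float(sum(alleles))
        rows.append({"chrom": str(rec.chrom), "pos": int(rec.pos),
                     "ref": str(rec.ref), "alt": str(rec.alts[0])})
        cols.append(dose)
    if not cols:
        raise ValueError("no biallelic records found in VCF")
    return LDPanel(np.column_stack(cols), pd.DataFrame(rows), sample_ids)
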