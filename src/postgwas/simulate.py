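"""Synthetic GWAS generator: LD-structured genotypes, quantitative and
liability-threshold binary traits with known causal architecture, and
per-variant regression summary statistics.

Genotypes come from a Gaussian-copula haplotype model: within each LD
block, a latent stationary AR(1) Gaussian process with neighbour
correlation rho is thresholded at the MAF-matching quantile to give one
haplotype's alleles, and two independent haplotypes are summed to a dosage
in {0, 1, 2}. Blocks are mutually independent, Hardy-Weinberg holds by
construction, and the implied genotype LD is analytically checkable via
bivariate-normal orthant probabilities. This provides controlled LD for
testing the statistical machinery; it does not emulate population-genetic
realism (recombination hotspots, allele-frequency/LD coupling,
relatedness, imputation error).

Determinism: each stage consumes a single ``numpy.random.default_rng``
stream seeded from the config. Draw order in ``simulate_genotypes``:
(1) per-variant MAFs, (2) haplotype-1 latents, (3) haplotype-2 latents.
In ``simulate_trait``: (1) noise / liability noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from .ldpanel import LDPanel
from .sumstats import SummaryStats

__all__ = ["SimConfig", "simulate_genotypes", "simulate_trait",
           "compute_sumstats", "make_paired_studies", "save_truth", "load_truth"]


@dataclass
class SimConfig:
    """Generating conditions for one synthetic study.

    ``blocks`` lists (block_length, rho) pairs tiling the variants; a final
    short block is truncated. ``causal`` maps variant index to the fraction
    of trait variance it explains (or to a fixed standardised effect via
    ``causal_beta``). Positions are laid out every ``pos_step`` bp on one
    chromosome so 200 variants at the default 2.5 kb spacing span a 500 kb
    locus window.
    """

    n_samples: int = 5000
    n_variants: int = 100
    blocks: list[tuple[int, float]] = field(default_factory=lambda: [(25, 0.95)])
    maf_range: tuple[float, float] = (0.01, 0.5)
    causal: dict[int, float] = field(default_factory=dict)          # index -> variance explained
    causal_beta: dict[int, float] = field(default_factory=dict)     # index -> standardised beta
    trait_type: str = "quantitative"
    prevalence: float = 0.1
    chrom: str = "1"
    pos_start: int = 1_000_001
    pos_step: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        h2 = sum(self.causal.values()) + sum(b * b for b in self.causal_beta.values())
        if h2 > 1.0:
            raise ValueError(f"total variance explained {h2:.3f} exceeds 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if set(self.causal) & set(self.causal_beta):
            raise ValueError("a variant may appear in causal or causal_beta, not both")

    @property
    def h2(self) -> float:
        return sum(self.causal.values()) + sum(b * b for b in self.causal_beta.values())

    def causal_effects(self) -> dict[int, float]:
        """Standardised per-variant effects beta_k (sqrt of variance explained)."""
        eff = {int(k): float(np.sqrt(q)) for k, q in self.causal.items()}
        eff.update({int(k): float(b) for k, b in self.causal_beta.items()})
        for k in eff:
            if not (0 <= k < self.n_variants):
                raise ValueError(f"causal index {k} out of range")
        return eff


def _block_bounds(config: SimConfig) -> list[tuple[int, int, float]]:
    bounds, start = [], 0
    i = 0
    while start < config.n_variants:
        length, rho = config.blocks[i % len(config.blocks)]
        end = min(start + length, config.n_variants)
        bounds.append((start, end, float(rho)))
        start = end
        i += 1
    return bounds


def _haplotype_latents(rng: np.random.Generator, n: int,
                       bounds: list[tuple[int, int, float]], m: int) -> np.ndarray:
    """Stationary unit-variance AR(1) latents, independent across blocks."""
    z = rng.standard_normal((n, m), dtype=np.float32)
    for start, end, rho in bounds:
        first = z[:, start].copy()
        x = z[:, start:end]
        x *= np.float32(np.sqrt(1.0 - rho * rho))
        x[:, 0] = first
        z[:, start:end] = _signal.lfilter([1.0], [1.0, -rho], x, axis=1)
    return z


def simulate_genotypes(config: SimConfig, seed: int | None = None,
                       mafs: np.ndarray | None = None) -> LDPanel:
    """LD-structured biallelic dosages in {0, 1, 2} (ref 'A', alt 'G').

    ``mafs`` overrides the per-variant target minor-allele frequencies
    (used to hold the allele-frequency law fixed across paired cohorts);
    the MAF draw is consumed from the stream regardless so genotypes stay
    comparable with and without the override.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m, n = config.n_variants, config.n_samples
    drawn = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    mafs = drawn if mafs is None else np.asarray(mafs, dtype=float)
    tau = stats.norm.ppf(mafs).astype(np.float32)  # P(latent < tau) = maf
    bounds = _block_bounds(config)
    dosages = np.zeros((n, m), dtype=np.float32)
    for _hap in range(2):
        z = _haplotype_latents(rng, n, bounds, m)
        dosages += (z < tau)
    variants = pd.DataFrame({
        "chrom": config.chrom,
        "pos": config.pos_start + config.pos_step * np.arange(m),
        "ref": "A",
        "alt": "G",
    })
    return LDPanel(dosages, variants)


def implied_genotype_r(maf_i: float, maf_j: float, latent_r: float) -> float:
    """Copula-implied genotype correlation between two variants.

    Alleles are indicators of bivariate-normal orthants, so the allele
    (and dosage) correlation is (Phi2(t_i, t_j; r) - m_i m_j) /
    sqrt(m_i (1 - m_i) m_j (1 - m_j)).
    """
    ti, tj = stats.norm.ppf([maf_i, maf_j])
    p_both = stats.multivariate_normal.cdf(
        [ti, tj], mean=[0.0, 0.0], cov=[[1.0, latent_r], [latent_r, 1.0]])
    return float((p_both - maf_i * maf_j)
                 / np.sqrt(maf_i * (1 - maf_i) * maf_j * (1 - maf_j)))


def simulate_trait(panel: LDPanel, config: SimConfig,
                   seed: int | None = None) -> np.ndarray:
    """Additive trait on standardised causal dosages.

    Quantitative: y = sum_k beta_k * std(g_k) + N(0, 1 - h2), so the trait
    variance is ~1 and each causal variant explains its configured share.
    Binary: the same construction is the liability; cases are liabilities
    above the (1 - prevalence) normal quantile.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    n = panel.n_samples
    effects = config.causal_effects()
    y = np.zeros(n)
    for k, beta in effects.items():
        g = panel.dosages[:, k].astype(float)
        sd = g.std()
        if sd == 0:
            raise ValueError(f"causal variant {k} is monomorphic in this draw")
        y += beta * (g - g.mean()) / sd
    h2 = config.h2
    y += rng.standard_normal(n) * np.sqrt(max(0.0, 1.0 - h2))
    if config.trait_type == "case_control":
        return (y > stats.norm.isf(config.prevalence)).astype(float)
    return y


def compute_sumstats(panel: LDPanel, phenotype: np.ndarray, trait_type: str,
                     trait_id: str = "sim", covariates: np.ndarray | None = None,
                     binary_model: str = "linear") -> SummaryStats:
    """Marginal per-variant association scan.

    Simple linear regression of the phenotype on each dosage column (with
    optional residualisation of the phenotype on covariates first), giving
    beta, se, a two-sided normal p, eaf, n and info = 1. Binary traits use
    linear regression on the 0/1 outcome by default; ``binary_model=
    "logistic"`` fits per-variant logistic regressions (log-odds effects,
    considerably slower). Monomorphic variants get beta = 0, se = inf,
    p = 1 and are flagged in the QC log; the default MAF filter removes
    them downstream.
    """
    y = np.asarray(phenotype, dtype=float)
    n = panel.n_samples
    if covariates is not None:
        X = np.column_stack([np.ones(n), covariates])
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

    G = panel.dosages
    gmean = G.mean(axis=0, dtype=np.float64)
    eaf = gmean / 2.0
    yc = y - y.mean()
    # centred cross-products without materialising centred copies of G;
    # dosages are small integers, so float64 accumulation here is exact
    sxx = np.maximum(np.einsum("ij,ij->j", G, G, dtype=np.float64) - n * gmean ** 2, 0.0)
    sxy = np.einsum("i,ij->j", yc, G, dtype=np.float64)
    syy = float(yc @ yc)
    mono = sxx <= n * 1e-12

    if trait_type == "case_control" and binary_model == "logistic":
        import statsmodels.api as sm
        beta = np.zeros(panel.n_variants)
        se = np.full(panel.n_variants, np.inf)
        for j in range(panel.n_variants):
            if mono[j]:
                continue
            fit = sm.Logit(y, sm.add_constant(G[:, j])).fit(disp=0)
            beta[j], se[j] = fit.params[1], fit.bse[1]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
            rss = syy - beta * sxy
            sigma2 = rss / (n - 2)
            se = np.where(mono, np.inf, np.sqrt(sigma2 / np.where(mono, 1.0, sxx)))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(mono, 0.0, beta / se)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    df = panel.variants.copy()
    df["eaf"] = eaf
    df["beta"] = beta
    df["se"] = se
    df["p"] = p
    df["n"] = float(n)
    df["info"] = 1.0
    qc_log = [("monomorphic_flagged", int(mono.sum()))] if mono.any() else []
    return SummaryStats(trait_id, trait_type, df, qc_log=qc_log)


# ---------------------------------------------------------------------------
# Paired two-trait studies for colocalisation testing


def make_paired_studies(config: SimConfig, mode: str, seed: int | None = None,
                        r2_cap: float = 0.01,
                        ) -> tuple[SummaryStats, SummaryStats, dict]:
    """Two studies on non-overlapping cohorts drawn from one LD law.

    shared: the same causal variant drives both traits; distinct: the
    second trait's causal variant is the first candidate (scanning from the
    far end of the region) with panel r^2 below ``r2_cap`` to trait 1's
    causal variant; independent: the second trait is null. The returned
    truth record carries the mode, causal indices and seeds for scoring.
    """
    if mode not in ("shared", "distinct", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    if not config.causal and not config.causal_beta:
        raise ValueError("config must specify at least one causal variant for trait 1")
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(base)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_variants)

    panel1 = simulate_genotypes(config, seed=base + 1, mafs=mafs)
    panel2 = simulate_genotypes(config, seed=base + 2, mafs=mafs)

    causal1 = sorted(config.causal_effects())
    q1 = config.causal_effects()[causal1[0]] ** 2

    if mode == "shared":
        cfg2 = _with_causal(config, {k: v ** 2 for k, v in config.causal_effects().items()})
        causal2 = causal1
    elif mode == "independent":
        cfg2 = _with_causal(config, {})
        causal2 = []
    else:
        anchor = causal1[0]
        causal2 = None
        for j in range(config.n_variants - 1, -1, -1):
            if j in causal1:
                continue
            r = np.corrcoef(panel1.dosages[:, anchor], panel1.dosages[:, j])[0, 1]
            if r * r < r2_cap:
                causal2 = [j]
                break
        if causal2 is None:
            raise ValueError(f"no variant with r^2 < {r2_cap} to the trait-1 causal variant")
        cfg2 = _with_causal(config, {causal2[0]: q1})

    y1 = simulate_trait(panel1, config, seed=base + 3)
    y2 = simulate_trait(panel2, cfg2, seed=base + 4)
    ss1 = compute_sumstats(panel1, y1, config.trait_type, trait_id="trait1")
    ss2 = compute_sumstats(panel2, y2, cfg2.trait_type, trait_id="trait2")
    truth = {"mode": mode, "seed": int(base),
             "causal1": [int(k) for k in causal1],
             "causal2": [int(k) for k in causal2],
             "pos1": [int(panel1.variants["pos"].iat[k]) for k in causal1],
             "pos2": [int(panel1.variants["pos"].iat[k]) for k in causal2]}
    return ss1, ss2, truth


def _with_causal(config: SimConfig, causal: dict[int, float]) -> SimConfig:
    d = asdict(config)
    d["causal"] = causal
    d["causal_beta"] = {}
    d["blocks"] = [tuple(b) for b in d["blocks"]]
    return SimConfig(**d)


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def load_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
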