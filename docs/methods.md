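# Methods

This note records the statistical models implemented in `postgwas`, the
defaults and why they were chosen, the numerical decisions, what the
synthetic generator does and does not emulate, and known limitations.

## Summary-statistics model

A variant record carries the marginal additive effect β (trait units per
effect-allele copy; log-odds for case/control), its standard error SE
(V = SE²), a two-sided p-value, effect-allele frequency, per-variant
sample size n, and imputation quality in [0, 1]. Records are kept sorted
by (chromosome, position) and deduplicated on (chrom, pos, ref, alt).

The loader cross-checks p against β/SE under a two-sided normal test with
a relative tolerance of 10⁻⁶ on the z-score. This is deliberately strict:
it catches column mix-ups and unit errors in machine-precision files (such
as this package's own output, which round-trips bit-exactly), but it will
reject files whose p-values were rounded to a few significant figures —
for those, pass a looser `z_tol` (≈10⁻³ accommodates 3-figure rounding).
Below p ≈ 10⁻²⁸⁰ the normal quantile no longer round-trips in double
precision and the check degrades to a one-sided sanity bound.

### QC defaults

* MAF ≥ 0.01 and info ≥ 0.9, boundaries inclusive for passing (a variant
  at exactly 1% MAF is kept, since the exclusion rule is "< 1%").
* MHC mask: GRCh37 chr6:28,477,797–33,448,354, closed on both ends,
  reflecting the region's extreme LD.
* Filters are applied sequentially, so per-filter removal counts in the QC
  log sum exactly to the total removed; filters are idempotent and
  commute.

### Genomic control

λ_GC = median[(β/SE)²] / m₅₀ with m₅₀ = 0.4549364, the exact χ²₁ median
(computed from `scipy.stats.chi2.ppf(0.5, 1)`, not the rounded 0.456).
The caller supplies an LD-pruned variant set; the function does not prune.
Note the sampling SD of λ_GC from m independent variants is ≈ 2.33/√m
(≈0.023 at m = 10⁴), and larger under LD — single-draw λ values scatter
accordingly, which is why the calibration experiment reports a mean over
seeds.

### Threshold printing

Bonferroni ledgers store α and n exactly and print α/n in scientific
notation **truncated** (not rounded) to three significant figures, e.g.
5×10⁻⁸/11 → "4.54e-9". Truncation is conservative for display: the printed
threshold is never looser than the computed one, so a p-value that beats
the printed figure always beats the exact threshold.

## LD panel

Dosages (expected alternate-allele counts in [0, 2]) are the native
representation so imputed panels work unchanged; missing dosages are NaN
and correlations are computed pairwise-complete. `pairwise_r` uses an
explicit two-pass Pearson form that is exactly symmetric in its arguments.
LD pruning is greedy keep-first in genomic order with a 1 Mb window,
dropping a variant when r² ≥ the cutoff with any retained variant — a
deterministic rule matching common practice; the retained set provably
contains no within-window pair at or above the cutoff. Subsampling (for
building an LD reference of, say, 5,000 from a larger cohort) is uniform
without replacement and seed-reproducible.

## Locus discovery

Indices are chosen greedily by smallest p below the threshold; each locus
is the index ± 500 kb (clipped at position 1); overlapping windows merge
transitively and the merged locus keeps the smallest-p index, which
prevents double-counting signals when two strong variants sit within one
window of each other. The output is invariant to input record order.

## Approximate conditional analysis

Joint multiple-regression fits of a selected variant set are reconstructed
from marginal summary statistics plus panel LD:

* (X'X)_jk ≈ r_jk √(D_j D_k), (X'y)_j = D_j β_j, where D_j = n_j s²_j.
* **s²_j is the panel's empirical dosage variance (ddof 0) by default**,
  not the Hardy–Weinberg expectation 2f(1−f). When genotypes are in hand
  (as a reference panel always is here), the empirical variance is the
  strictly better estimate of the sample cross-product — and it makes the
  reconstruction *exact* when the panel is the association sample itself,
  a property the test suite exploits (joint β and SE match an in-sample
  OLS fit to machine precision). A `var_mode="hwe"` option provides the
  2f(1−f)n construction used when only frequencies are available.
* The phenotype sum of squares is recovered per variant from the marginal
  identity y'y = D_j (SE_j²(n_j−2) + β_j²) and summarised by the median
  across the locus, which is robust to the handful of variants whose
  marginal fit absorbs real signal.
* Joint SEs use residual variance (y'y − b'X'y)/(n − p − 1); p-values are
  two-sided normal, consistent with the marginal scan.

Forward selection starts at the marginal lead and at each step adds the
candidate with the smallest conditional p if it is below 10⁻⁸ and has
r² < 0.9 with every selected variant; candidates absent from the panel, or
whose allele frequency differs from the panel's by more than 0.2, are
excluded, and candidates yielding an ill-conditioned joint LD matrix
(condition number > 10⁸) are skipped with a log entry. A final backward
sweep refits the full set and drops any variant whose joint p rose above
the threshold, guaranteeing every reported signal satisfies the
conditional-independence criterion. Case/control traits are handled on the
log-odds scale with phenotypic variance fixed at 1.

Nearest-gene annotation minimises |TSS − lead| on the same chromosome
(TSS = txStart on +, txEnd on −), reports distance 0 inside a transcript
body, and breaks ties by smaller TSS then name.

## Fine-mapping

The log Wakefield ABF is Λ = ½ ln(V/(V+ω)) + ωβ²/(2V(V+ω)) — the exact
log of N(β̂; 0, V+ω)/N(β̂; 0, V) — with ω = 0.04 for case/control and
(0.15σ)² for quantitative traits. σ is the phenotypic SD recovered by
regressing 2 n_j f_j(1−f_j) on 1/V_j through the origin (slope σ²); the
estimate fails loudly on a non-positive slope.

Posteriors use an explicit null model with prior weight γ = 0.05 (matched
to the 5×10⁻⁸ locus-discovery threshold, i.e. an expected 5% of
fine-mapped regions harbour no true signal) and a uniform (1−γ)/l prior
per variant; all sums are log-sum-exp. The credible set sorts variants by
decreasing Λ (ties: decreasing |β|/√V, then position, then input index —
fully deterministic) and accumulates variant-renormalised mass
π_j/(1−π₀) until it reaches c = 0.95. Renormalising over variants means a
set always exists even when the null mass exceeds 1−c; π₀ is reported so
callers can gate on it. Two consequences worth knowing:

* The renormalised masses equal the γ = 0 posteriors, so γ affects π₀ but
  not set membership.
* Because the accumulation stops at the first prefix ≥ c, the set's
  attained mass overshoots c whenever posteriors are concentrated, and its
  realised coverage of the causal variant equals the *attained* mass, not
  c. Under the generating prior the implementation is exactly calibrated
  in that sense — empirical coverage matches mean attained mass to
  Monte-Carlo error — and is therefore conservative (≥ c) as a set-level
  guarantee. With strong signals (causal χ² median ≈ 30) attained mass
  averages ≈ 0.98, so observed coverage sits near 0.98, not 0.95; only in
  the diffuse-posterior regime does coverage approach c itself.

Only the single-causal model is implemented, so a region with several
causal variants should be fine-mapped per conditionally independent signal.

## Colocalisation

Variants are intersected on (chrom, pos); swapped-allele records have β
negated and frequency complemented; records whose alleles match neither
way are dropped, as are strand-ambiguous (A/T, C/G) variants with
frequency in [0.4, 0.6] in either study. Evidence sums for the five
hypotheses are computed in log space; the distinct-variants sum over
ordered pairs j ≠ k is enumerated directly for regions of ≤ 200 variants
and otherwise computed as log-sum-exp subtraction of the diagonal, falling
back to enumeration if the subtraction would cancel catastrophically.
Priors default to p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵ (the conventional
defaults) and are configurable, as is ω per trait (case/control traits may
use 0.04). The strong-colocalisation call is PP3+PP4 ≥ 0.99 and
PP4/PP3 ≥ 5 (satisfied vacuously when PP3 = 0); the symmetric "distinct"
label is this package's addition and is flagged as such.

## Synthetic data

The generator emulates exactly the structure the downstream statistics
assume: Hardy–Weinberg biallelic genotypes with controllable LD,
additive quantitative traits with unit variance and specified per-variant
variance explained, liability-threshold binary traits, and per-variant OLS
summary statistics (binary traits default to linear regression on the 0/1
outcome; a per-variant logistic mode exists for log-odds fidelity at a
runtime cost). Genotypes are Gaussian-copula haplotypes — blockwise
stationary AR(1) latents thresholded at the MAF quantile, two independent
haplotypes summed — chosen over coalescent simulation because the implied
LD is analytically checkable (bivariate-normal orthant probabilities, see
`implied_genotype_r`) and generation is cheap and seed-stable. Note the
genotype correlation is attenuated relative to the latent ρ (more so at
low MAF): latent ρ = 0.95 yields genotype r ≈ 0.8–0.9.

It does **not** emulate: recombination-hotspot LD geometry, the joint
allele-frequency/LD distribution of real populations, relatedness or
population structure, imputation error (info is always 1), or genotyping
artefacts. Passing calibration tests therefore validates the statistical
machinery under its stated model, not robustness to those real-data
features.

Determinism: one `numpy.random.default_rng` stream per stage with
documented draw order (MAFs, haplotype 1, haplotype 2; then trait noise).
Genotypes are stored as float32 (the values are exact small integers; all
downstream accumulations are float64). Paired two-trait studies draw two
disjoint cohorts from one LD law by fixing the MAF vector and varying the
genotype seed; the distinct-causal mode picks the second causal as the
first variant, scanning from the far end of the region, with panel
r² < 0.01 to the first.

## Calibration experiments (`postgwas.calibration`)

Problem sizes were chosen to keep every experiment desk-scale:

* ABF/quadrature identity: 1,000-point grid over z ∈ [−6, 6],
  V ∈ [10⁻⁴, 10⁻¹], ω ∈ [10⁻³, 0.25]; worst relative error ~4×10⁻⁹.
* Credible-set coverage: 50 LD-free variants, causal uniform,
  β ~ N(0, ω), V set so the causal's marginal χ² median is 30; run at the
  summary level (exact normal errors), 1,000–2,000 replicates.
* Conditional recovery: loci of 100 variants (blocks of 25, latent
  ρ = 0.95, 2.5 kb spacing), n = 5,000, 1% variance per causal, loci at
  p < 5×10⁻⁸, joint threshold 10⁻⁸; success requires signal leads tagging
  the causal at panel r² ≥ 0.8. At this effect size the causal z-statistic
  is ≈ N(7.11, 1), so per-causal power against the 10⁻⁸ cutoff is ≈ 0.92 —
  the recovery rates (~0.88 one-causal, ~0.85 both-of-two) are
  power-limited, not method-limited.
* Colocalisation: 200-variant regions, two cohorts of 5,000, shared or
  distinct (r² < 0.01) causals at 1% variance; shared pairs reach
  PP4 > 0.9 in ≳99% of replicates, distinct pairs PP3 > 0.9 in ≳92%.
* Null GWAS: n = 5,000, 10,000 variants in LD blocks (50, ρ = 0.9), no
  causal variants; mean λ_GC across seeds ≈ 1.00 and spurious
  study-wide loci essentially never occur.
* sdY recovery: n = 10,000, 500 variants, h² = 0.1 over five causals;
  the recovered SD is within ~0.5% of the generating value of 1.

## Known limitations

* Single-causal fine-mapping only; no functional priors; no multi-trait
  (> 2) colocalisation.
* No mixed-model association, LD-score methods, heritability estimation,
  cross-locus joint modelling, build liftover, or X-chromosome dosage
  model.
* Conditional analysis assumes the LD panel matches the association
  cohort's ancestry; panel-mismatch error is only guarded by the 0.2
  allele-frequency concordance filter.
* The p/z consistency default rejects heavily rounded published files
  (by design; relax `z_tol` to ingest them).
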