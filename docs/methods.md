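# Methods

This note documents the models behind each stage of the pipeline, the
numerical choices that matter, what the synthetic-data generators do and do
not emulate, and the design decisions taken where more than one defensible
convention exists.

## Phenotype processing

Raw input is one record per microtiter well: per-animal body lengths (TOF
units from a large-particle sorter), a brood count, the number of animals
originally sorted (three), assay/plate/well labels, condition (drug or
DMSO-only control) and an `exclude` flag. The processing chain runs in a
fixed order:

1. **Well summarization.** The 10th/25th/50th/75th/90th length quantiles per
   well (linear interpolation between order statistics, quantile type 7 — the
   dominant default in scientific software; the data source does not
   prescribe one) and the brood count divided by the number sorted.
2. **Assay regression.** Residuals of an ordinary least-squares fit of the
   trait on the assay factor. With a purely categorical design these are
   deviations from assay means, so residuals sum to zero within each assay
   and the operation is idempotent.
3. **Outlier pruning.** A value is flagged iff it exceeds Q75 + 2·IQR or
   falls below Q25 − 2·IQR, with quartiles computed once on the input
   (single pass, never iterated). If the flagged fraction exceeds 5% of
   strains nothing is removed. The strict ">" matters: it makes a single
   outlier in a 20-strain panel (exactly 5%) prunable while two outliers
   (10%) trigger the escape clause; an "at least 5%" reading would make the
   20-strain single-outlier case unprunable, which contradicts the rule's
   purpose of removing isolated extreme values.
4. **Control regression.** Residuals of a simple regression of the drug
   trait on the strain-matched control trait, removing carrier and baseline
   growth effects. Residuals are exactly orthogonal to the control values; a
   constant control degenerates to centering. Pruning runs before control
   regression by default (the chain's stated order); the order is a
   parameter of `process_trait` in the sense that each step is callable
   independently.

**Bubble/contamination filtering** from the original instrument software
(an SVM plus visual inspection) is not reproducible and is replaced by the
explicit `exclude` flag on well records.

**Broad-sense heritability** is estimated from replicated strain
measurements under the one-way random-effects model
*y_ij* = μ + *a_i* + *e_ij*, *a_i* ~ N(0, σ²_strain), by exact REML: the
strain incidence matrix turns the model into the kinship mixed model with
K = ZZ′, solved by the same eigendecomposition engine as the association
scan (profile over the variance ratio on a 100-interval log10 grid spanning
[−5, 5], then a bounded scalar refinement; tolerance 1e-10 on the log-ratio).
A genetic variance driven to the search boundary is clamped to zero. For
balanced designs the estimate coincides with the ANOVA moment estimator
(MSB − MSW)/k, which the tests verify. The estimate is invariant to affine
rescaling of the trait.

**Heterozygote gating** for dominance tests labels an animal heterozygous
iff its fluorescence lies strictly between the 95th percentile of the
non-fluorescent parent and the 5th percentile of the fluorescent parent;
overlapping gates raise an error rather than guessing.

**Strain comparisons** use one-way ANOVA followed by Tukey's honest
significant difference (statsmodels' implementation; Tukey–Kramer
harmonic-mean correction for unbalanced groups).

## Linkage mapping

The scan statistic is LOD = −*n* ln(1 − *r*²)/(2 ln 10) with *r* the Pearson
correlation between marker genotype and trait over the *n*
pairwise-complete strains (missing calls reduce *n* per marker — the natural
choice for a correlation statistic). The trait is standardized to mean zero
and unit variance before scanning; the statistic itself is invariant to
affine trait transforms and to swapping allele labels. One peak is retained
per chromosome (its maximum).

Genome-wide significance comes from permuting strain labels: rows of the
trait matrix move as units so correlations among traits are preserved. The
default threshold is the (1 − α) quantile of the per-permutation genome-wide
maximum LOD. A second mode implements an expected/observed peak-count
criterion — the smallest candidate LOD at which the mean number of
chromosome-wise permutation peaks above it drops to α — because "what counts
as a peak" is convention-dependent, this mode documents its reading
(chromosome maxima) and is not claimed to reproduce any particular published
cutoff.

Confidence intervals are maximal contiguous marker runs around the peak with
LOD ≥ peak − 1.5, reported at marker positions. Variance explained inverts
the LOD formula, ve = 1 − 10^(−2·LOD/*n*), and is also reported as a
fraction of broad-sense heritability. ve at the peak is upward-biased
(winner's curse) — the roundtrip identity is exact, the causal attribution
is not.

## Mixed-model association

**Kinship** is the VanRaden realized additive relationship: homozygous calls
coded −1/+1, columns centered at 2p − 1 (missing calls imputed to the
column mean), cross-product scaled by 2Σp(1 − p). Fully inbred panels have
diagonal ≈ 2. Off-diagonals of unrelated strains do not converge to zero
exactly: in-sample frequency centering forces them toward −diag/(n − 1).

**REML.** For y = Xb + u + e with u ~ N(0, σ²_g K): eigendecompose K once
(clamping eigenvalues more negative than −1e-6·max(1, λ_max) is an error;
smaller negatives are zeroed), rotate y and X, and maximize the Harville
restricted likelihood — including the log|X′X| normalization so the
criterion is invariant to reparameterizing X — over log10 δ ∈ [−5, 5] on a
100-interval grid with bounded local refinement. The eigen-path equals a
dense-matrix evaluation to machine precision; tests pin this at 1e-6 on all
small fixtures.

**Per-marker tests.** Each marker enters X as a fixed effect with its own
variance-component fit (the exact analysis; a faster mode reusing the
null-model ratio exists but is not the default). The marker test is the
t-statistic of the GLS coefficient at the per-marker optimum, df = n − 2.
Markers below 5% minor allele frequency are excluded before testing; the
genome-wide threshold is Bonferroni, −log10(α/m). Missing genotypes are
mean-imputed per marker so the kinship rotation is shared across markers.

**Region of interest.** For every retained marker, a trait is simulated in
which that marker explains 20% of variance; the scan is run and the SNV-rank
distance from the planted marker to the strongest association recorded
(ties including the planted marker count as zero). The ROI half-width is the
smallest W capturing 95% of these distances. Significant markers on one
chromosome separated by ≤ W ranks merge into one region, which is then
padded by W SNVs on each side and clipped at chromosome ends. Peak choice
within a region: smallest p, ties broken by leftmost position. The
calibrated W is a property of the panel's LD: on an LD-free panel it is
zero, and it shrinks as the planted effect grows.

## Fine mapping

The "kinship-corrected phenotype" is not uniquely defined by common usage;
this package subtracts the null-model BLUP of the polygenic effect
(ŷ = y − Xb̂ − û with û = σ̂²_g K V̂⁻¹(y − Xb̂)), which leaves a
pseudo-phenotype whose structure-axis variance is reduced; a whitening
alternative (multiplying the centered trait by V̂^(−1/2)) is available via
`method="whiten"`. Under K = I the variance split is non-identifiable and
the corrected trait is simply a positive multiple of the centered input.

Candidate variants are restricted to HIGH/MODERATE predicted functional
effect (annotation is consumed as input; no effect prediction is performed).
Spearman's ρ uses average ranks for ties; p-values are exact (full
enumeration of the n! rank orderings) for n ≤ 8 and Student-t otherwise.
Constant-genotype variants and variants with fewer than five complete
strains are excluded.

## Tajima's D

D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants
(a₁ = Σ1/i, a₂ = Σ1/i², b₁ = (n+1)/(3(n−1)), b₂ = 2(n²+n+3)/(9n(n−1)),
c₁ = b₁ − 1/a₁, c₂ = b₂ − (n+2)/(a₁n) + a₂/a₁², e₁ = c₁/a₁,
e₂ = c₂/(a₁² + a₂)). Inbred strain calls are treated as haploid sequences.
π is computed site-wise from pairwise-complete calls
(c(n_s − c)/C(n_s, 2) per site); constants use the full sample size. S = 0
returns NaN with the window flagged rather than a value. Windows advance in
SNV-rank units (default 300/100) and never span chromosome boundaries;
chromosomes shorter than one window are skipped with a warning. The
reference strain is excluded from the sample by default — a
sample-composition choice, not an ancestral-state polarization (the
statistic is folded and needs none); `include_outgroup=True` restores it.
Note that panels with strong population structure or non-neutral site
frequency spectra legitimately give D far from zero genome-wide; the neutral
expectation (mean ≈ 0) is verified against coalescent simulation, not
assumed for structured panels.

## Pooled-editing enrichment

Reads count toward an allele only on exact full-span equality with the
wild-type or edited reference; everything else is unmatched. The headline
statistic is the edited-allele-fraction fold change of each drug arm against
the no-drug control at the post-treatment timepoint (a post-vs-pre contrast
is also exposed), with a two-sided Fisher's exact test on the 2×2 table
using the minimum-likelihood rule (sum of probabilities of tables no more
likely than the observed one) — conventions differ, so this is stated
explicitly; the tests pin it to exhaustive enumeration. A control arm with
zero edited reads leaves the fold change undefined (NaN) but the p-value
defined. `detect_depletion_power` quantifies by Monte Carlo why depletion of
an allele present in under 1% of cells is hard to detect at practical
sequencing depths.

## Synthetic data: what it emulates, and what it does not

All generators draw from one seeded `numpy.random.Generator` per call and
are bit-reproducible.

- **RIAIL genotypes.** Each line is a homozygous mosaic of two parental
  haplotypes; crossovers are a Poisson process on the genetic map (no
  interference) at 1 + g breakpoints per Morgan after g intercross
  generations, with a fair coin for the left-telomere parent. This
  deliberately simple model gives the three properties downstream stages
  need — allele frequencies near 0.5, LD decaying with genetic distance, and
  map expansion with intercrossing — without modelling selfing-specific map
  expansion, segregation distortion, or residual heterozygosity.
- **Wild panels.** Balding–Nichols subpopulation divergence on top of
  latent Gaussian fields autocorrelated along the genetic map
  (`ld_scale_cm = 15` by default), so marginal frequencies follow the
  island model while neighboring markers are in LD (adjacent r² ≈ 0.6 at
  the default marker density) — without this, the ±W SNV region-of-interest
  construction is vacuous. Not modelled: admixture gradients, selfing
  depressions of diversity, chromosome-arm/center recombination contrast.
- **Phenotypes.** Sum of per-QTL standardized genotype effects
  (√ve each), a polygenic term from small effects at every marker, and
  Gaussian noise filling the remainder; each component standardized
  empirically so the realized decomposition matches the request up to
  sampling covariance.
- **Well records.** Each strain carries a drug-response effect and an
  independent baseline growth propensity; control wells measure the
  baseline, drug wells the effect plus a coupling (0.6) times the baseline —
  so the control regression has exactly the confounder it exists to remove.
  Per-assay shifts (SD 0.25 effect-SD), per-well biological noise (SD 0.5),
  50 animals per well at 30 TOF units per effect-SD, within-well SD 25,
  Poisson broods. Not modelled: plate-edge effects, instrument optics,
  starvation-induced transgenerational effects.
- **Pooled read counts.** Deterministic haploid selection
  f_t = f₀w^t/(f₀w^t + 1 − f₀), binomial sequencing at fixed depth, with a
  matched neutral no-drug arm.
- **Reference stand-ins.** Two builders construct labelled synthetic
  reference objects with ground truth fixed by construction: a balanced
  four-strain quadruplicate dose-response design whose realized variance
  components give an exact target H², and a read-count table inverted from
  target fold changes at sub-1% control editing and 10⁶ depth. They exist so
  the estimators can be validated against known truth; passing those tests
  shows the estimators are correct, not that any particular biological
  dataset was reproduced.

Because all tests run on these generators, they demonstrate statistical
correctness and calibration under the stated models — Gaussian noise,
homozygous biallelic markers, island-model structure — not robustness to
instrument artifacts, genotyping error, or selection in panel construction.

## Problem sizes and tolerances

The test suite and the reproduction script use study-scale synthetic
problems chosen to make Monte-Carlo assertions sharp while completing in
minutes on one CPU: 250 lines × ~500–600 markers for linkage calibration
(1000 permutations, 200 null scans, exceedance 0.05 ± 0.03), 100 replicates
for QTL localization (≥ 90 inside the 1.5-LOD interval), 150-strain
structured panels for association and fine mapping, 10⁴ neutral coalescent
replicates (n = 20) for the Tajima's D null (mean within ±0.1 of 0), and
exact oracles — dense-likelihood grids, rank-permutation and hypergeometric
enumeration, rational-arithmetic constants — wherever a quantity has a
closed form (agreement 1e-6 or better).

## Known limitations

- No multi-QTL or composite interval mapping; one peak per chromosome.
- No LOCO kinship; the tested marker also contributes to K.
- No genotype imputation; missing calls are handled pairwise (linkage) or
  by mean imputation (association).
- The peak-ratio threshold mode is one documented reading of an ambiguous
  convention.
- Exact Spearman p-values stop at n = 8 (40 320 enumerated orderings); the
  t-approximation is used beyond.
- BED exports are 0-based half-open; all other coordinates 1-based
  inclusive. Chromosomes sort in karyotype order (I, II, III, IV, V, X).
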