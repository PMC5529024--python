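# toxqtl

Quantitative-genetics pipeline for mapping natural variation in physiological
response to topoisomerase-II poisons (etoposide, teniposide, amsacrine,
dactinomycin, XK469) in *Caenorhabditis elegans*, with a companion module for
quantifying selection on edited alleles in pooled CRISPR experiments in human
cells.

The package is aimed at statistical geneticists who want the full analysis
chain — from raw plate-sorter well records to a fine-mapped candidate variant —
as tested, reusable library code, exercised end to end on synthetic panels
that carry the statistical structure of the real study designs (recombinant
inbred advanced intercross lines, structured wild-isolate panels with kinship
and local LD, QTL of stated variance explained, binomial read counts under
selection).

## What it computes

**Phenotype processing** (`phenotype_processing`). Per-well quantiles of
animal length (TOF) and normalized brood counts; assay-block regression
(residuals of *phenotype ~ assay*); single-pass IQR outlier pruning (drop
values beyond Q75 + 2·IQR or Q25 − 2·IQR unless more than 5% of strains are
flagged); control regression (residuals of *phenotype ~ control phenotype*).
Broad-sense heritability from replicated strain measurements by one-way
random-effects REML,

&nbsp;&nbsp;&nbsp;&nbsp;*H²* = σ²_strain / (σ²_strain + σ²_e),

plus fluorescence gating of heterozygotes and Tukey-HSD strain comparisons.

**Linkage mapping** (`linkage_mapping`). Correlation LOD score at each marker,

&nbsp;&nbsp;&nbsp;&nbsp;LOD = −*n* ln(1 − *r*²) / (2 ln 10),

with *r* the Pearson correlation between marker genotype and trait over the
*n* complete pairs; genome-wide significance from permutations of strain
labels (rows moved jointly across traits, preserving trait–trait
correlation); 1.5-LOD-drop confidence intervals; variance explained
*r*² = 1 − 10^(−2·LOD/*n*) and its share of broad-sense heritability.

**Mixed-model association** (`gwa_mapping`). VanRaden realized-relationship
kinship; exact REML of *y* = *Xb* + *u* + *e*, *u* ~ N(0, σ²_g **K**),
via one eigendecomposition of **K** and a 1-D search over
δ = σ²_e/σ²_g (per-marker re-estimation, the exact analysis); MAF ≥ 5%
filter and a Bonferroni threshold on the −log10 *p* scale; a
simulation-calibrated region of interest (plant a QTL of 20% variance
explained at every marker, take the SNV width capturing 95% of top-hit
displacements, pad significant clusters by that width).

**Fine mapping** (`fine_mapping`). Null-model BLUP subtraction to produce a
kinship-corrected phenotype, then Spearman's ρ between each HIGH/MODERATE
effect variant and the corrected trait — exact permutation p-values for
n ≤ 8, Student-t approximation otherwise.

**Selection scan** (`popgen_stats`). Sliding-window Tajima's D
(default 300-SNV windows, 100-SNV step, reference strain excluded),
D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants.

**Pooled-editing enrichment** (`crispr_enrichment`). Exact-match allele
counting, edited-fraction fold change of each drug arm against the no-drug
control, two-sided Fisher's exact tests, and Monte-Carlo power analysis of
depletion detection at low editing fractions.

**Synthetic data** (`synthetic_data`). First-class generators for every
input above, all deterministic given a seed.

## Worked example

Map a QTL explaining 27% of trait variance on a simulated panel of 250
recombinant inbred lines typed at 600 markers:

```python
import toxqtl

markers = toxqtl.make_marker_map(n_markers_per_chrom=100)        # 600 markers, I-V + X
riails  = toxqtl.simulate_riail_genotypes(250, markers, seed=0)  # 250 inbred lines
qtl     = riails.markers.query("chrom == 'II'").iloc[78]["marker"]
trait   = toxqtl.simulate_phenotypes(
    riails, [toxqtl.QTLSpec(qtl, 0.27)], polygenic_h2=0.2, seed=1
)

thr  = toxqtl.permutation_threshold(riails, trait, n_perm=1000, seed=2)
scan = toxqtl.genome_scan(riails, trait, threshold=thr)
peak = scan.markers.loc[scan.markers["lod"].idxmax()]
iv   = toxqtl.lod_drop_interval(scan, peak["chrom"])
ve, frac = toxqtl.variance_explained(peak["lod"], scan.n_strains, 0.47)

print(f"threshold (1000 permutations, 5%): LOD {thr:.2f}")
print(f"peak: {peak['marker']} on {peak['chrom']} at {peak['pos_bp']/1e6:.2f} Mb, LOD {peak['lod']:.2f}")
print(f"1.5-LOD interval: {iv.left_bp/1e6:.2f}-{iv.right_bp/1e6:.2f} Mb")
print(f"variance explained: {ve:.2f} ({frac:.0%} of H2 = 0.47)")
```

```
threshold (1000 permutations, 5%): LOD 3.19
peak: II_0079 on II at 12.04 Mb, LOD 21.65
1.5-LOD interval: 12.04-12.04 Mb
variance explained: 0.33 (70% of H2 = 0.47)
```

The permutation threshold (LOD ≈ 3.2 for 250 lines × 600 markers at 5%
genome-wide error) separates the chromosome II peak cleanly; the interval
collapses to the peak marker because the trait here is measured without
assay noise, and the realized variance explained (0.33) exceeds the planted
0.27 by the winner's-curse inflation expected when the peak marker also tags
part of the polygenic background.

The same stages are available as a CLI
(`toxqtl simulate|process|linkage|gwas|finemap|tajima|enrich|run`, each with
`--seed`/`--out`; `toxqtl run --config config.yaml` executes the whole
synthetic study and writes scan TSVs, a ROI BED, fine-mapping and Tajima's D
tables, and an enrichment CSV).

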