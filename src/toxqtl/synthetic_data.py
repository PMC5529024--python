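"""Synthetic input generators for the topoisomerase-II QTL pipeline.

Every downstream stage (phenotype processing, linkage mapping, mixed-model
association, fine mapping, selection scans, pooled-editing enrichment) is
exercised on data from this module, so each generator emulates the statistical
structure of the corresponding real input:

* recombinant inbred advanced intercross line (RIAIL) genotypes — homozygous
  mosaics of two parental genomes (Bristol/N2-like reference vs CB4856-like
  alternate) over a genetic map,
* structured wild-isolate panels with Balding–Nichols subpopulation divergence
  (so kinship correction has something to correct),
* strain phenotypes carrying one or more QTL of stated variance explained plus
  a polygenic term,
* well-level records shaped like COPAS BIOSORT output (per-animal length in
  TOF units, brood counts, fluorescence) with assay-block and control-condition
  nuisance effects,
* pooled amplicon read counts under deterministic haploid selection.

All generators draw from a single ``numpy.random.Generator`` seeded per call;
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

#: C. elegans chromosomes in karyotype order (never sorted lexically).
CHROM_ORDER = ("I", "II", "III", "IV", "V", "X")

#: Approximate chromosome physical lengths (bp) used for default marker maps.
CHROM_LENGTHS_BP = {
    "I": 15_072_000,
    "II": 15_279_000,
    "III": 13_784_000,
    "IV": 17_494_000,
    "V": 20_924_000,
    "X": 17_718_000,
}

#: Default genetic map length per chromosome (cM); ~50 cM is typical for
#: C. elegans autosomes.
CHROM_LENGTHS_CM = {c: 50.0 for c in CHROM_ORDER}


def chrom_sort_key(chrom: str) -> int:
    """Karyotype rank of a chromosome label (I < II < ... < V < X)."""
    try:
        return CHROM_ORDER.index(chrom)
    except ValueError as exc:
        raise ValueError(f"unknown chromosome label: {chrom!r}") from exc


# ---------------------------------------------------------------------------
# Marker maps and genotype matrices
# ---------------------------------------------------------------------------

def make_marker_map(
    n_markers_per_chrom: int = 50,
    chroms: tuple[str, ...] = CHROM_ORDER,
    chrom_lengths_bp: dict[str, int] | None = None,
    chrom_lengths_cm: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Build an evenly spaced marker map.

    Returns a DataFrame with columns ``marker``, ``chrom``, ``pos_bp``
    (1-based), ``cM``. Physical positions are strictly increasing and genetic
    positions non-decreasing within each chromosome.
    """
    if n_markers_per_chrom < 1:
        raise ValueError("n_markers_per_chrom must be >= 1")
    bp = chrom_lengths_bp or CHROM_LENGTHS_BP
    cm = chrom_lengths_cm or CHROM_LENGTHS_CM
    rows = []
    for chrom in chroms:
        length_bp = bp[chrom]
        length_cm = cm[chrom]
        pos = np.linspace(1, length_bp, n_markers_per_chrom).round().astype(int)
        pos = np.maximum.accumulate(pos)  # guard rounding collisions
        pos = pos + np.arange(n_markers_per_chrom) * (np.diff(pos, prepend=0) == 0)
        gen = np.linspace(0.0, length_cm, n_markers_per_chrom)
        for i, (p, g) in enumerate(zip(pos, gen)):
            rows.append((f"{chrom}_{i + 1:04d}", chrom, int(p), float(g)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos_bp", "cM"])


def validate_marker_map(markers: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a marker map violates its invariants."""
    required = {"marker", "chrom", "pos_bp", "cM"}
    if not required.issubset(markers.columns):
        raise ValueError(f"marker map must have columns {sorted(required)}")
    if len(markers) == 0:
        raise ValueError("marker map is empty")
    if (markers["pos_bp"] < 1).any():
        raise ValueError("physical positions must be >= 1 (1-based)")
    if (markers["cM"] < 0).any():
        raise ValueError("genetic positions must be non-negative")
    for chrom, sub in markers.groupby("chrom", sort=False):
        if not sub["pos_bp"].is_monotonic_increasing or sub["pos_bp"].duplicated().any():
            raise ValueError(f"positions not strictly increasing on {chrom}")
        if not sub["cM"].is_monotonic_increasing:
            raise ValueError(f"genetic positions not non-decreasing on {chrom}")


@dataclass
class GenotypeMatrix:
    """Strains x biallelic markers, inbred coding.

    ``calls`` is a float array with values 0 (reference / Bristol-like allele),
    1 (alternate allele) or NaN (missing). Heterozygous calls never appear:
    both RIAIL and wild-isotype panels are homozygous.
    """

    strains: list[str]
    markers: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        validate_marker_map(self.markers)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.strains), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        finite = self.calls[~np.isnan(self.calls)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("genotype calls must be 0, 1 or NaN")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.calls, axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, ignoring missing calls."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, min_maf: float) -> "GenotypeMatrix":
        """Drop markers with minor allele frequency below ``min_maf``."""
        keep = self.maf() >= min_maf
        return GenotypeMatrix(
            strains=list(self.strains),
            markers=self.markers.loc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
        )

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id!r} not in genotype matrix")
        return int(idx[0])

    def inject_missing(self, rate: float, seed: int) -> "GenotypeMatrix":
        """Return a copy with calls set missing independently at ``rate``."""
        if not 0 <= rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        rng = np.random.default_rng(seed)
        calls = self.calls.copy()
        calls[rng.random(calls.shape) < rate] = np.nan
        return dataclasses.replace(self, calls=calls)


@dataclass
class QTLSpec:
    """A causal marker and the fraction of trait variance it explains."""

    marker_id: str
    variance_explained: float

    def __post_init__(self) -> None:
        if not 0 < self.variance_explained <= 1:
            raise ValueError("variance_explained must be in (0, 1]")


# ---------------------------------------------------------------------------
# RIAIL genotypes
# ---------------------------------------------------------------------------

def simulate_riail_genotypes(
    n_lines: int,
    markers: pd.DataFrame,
    n_intercross_generations: int = 10,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate homozygous recombinant inbred advanced intercross lines.

    Each line's chromosome is a mosaic of the two parental haplotypes.
    Crossovers are placed as a homogeneous Poisson process on the genetic map
    (no interference) at a rate of ``1 + n_intercross_generations`` breakpoints
    per Morgan, so the expected breakpoint count per chromosome equals the map
    length in Morgans for a plain selfing panel and grows linearly with rounds
    of intercrossing. The left telomere haplotype is a fair coin flip per
    chromosome, which keeps the panel allele frequency near 0.5 at every
    marker. Lines are returned fully homozygous (inbred to fixation).
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if n_intercross_generations < 0:
        raise ValueError("n_intercross_generations must be >= 0")
    validate_marker_map(markers)
    rng = np.random.default_rng(seed)
    rate = 1.0 + n_intercross_generations  # breakpoints per Morgan

    calls = np.empty((n_lines, len(markers)), dtype=float)
    col = 0
    for chrom, sub in markers.groupby("chrom", sort=False):
        cm = sub["cM"].to_numpy()
        length_m = (cm[-1] - cm[0]) / 100.0  # Morgans
        pos_m = (cm - cm[0]) / 100.0
        n_markers = len(sub)
        for line in range(n_lines):
            start = rng.integers(0, 2)
            n_break = rng.poisson(rate * length_m)
            if n_break == 0:
                geno = np.full(n_markers, start, dtype=float)
            else:
                breaks = np.sort(rng.uniform(0.0, length_m, size=n_break))
                # parent switches at every breakpoint strictly left of a marker
                switches = np.searchsorted(breaks, pos_m, side="left")
                geno = (start + switches) % 2
            calls[line, col : col + n_markers] = geno
        col += n_markers

    strains = [f"RIAIL_{i + 1:04d}" for i in range(n_lines)]
    return GenotypeMatrix(strains=strains, markers=markers.copy(), calls=calls)


# ---------------------------------------------------------------------------
# Structured wild panel
# ---------------------------------------------------------------------------

def simulate_wild_panel(
    n_strains: int,
    markers: pd.DataFrame,
    n_subpopulations: int = 3,
    fst_like_divergence: float = 0.2,
    seed: int = 0,
    ld_scale_cm: float = 15.0,
) -> GenotypeMatrix:
    """Simulate a structured panel of inbred wild isotypes with local LD.

    Per marker an ancestral alternate-allele frequency on (0.1, 0.9) is
    produced from a latent Gaussian field that is autocorrelated along the
    genetic map; each subpopulation's frequency is the Balding–Nichols beta
    quantile (divergence parameter ``fst_like_divergence``, 0 collapses to
    the ancestral frequency) of its own smooth latent field, so nearby
    markers carry similar frequencies. Strains are assigned to
    subpopulations round-robin, and each strain's calls threshold a private
    standard-normal AR(1) process (correlation ``exp(-d_cM / ld_scale_cm)``
    between markers ``d_cM`` apart) at the subpopulation frequency quantile.
    Marginal allele frequencies therefore follow the Balding–Nichols model
    while neighboring markers sit in linkage disequilibrium that decays with
    genetic distance — the haplotype structure that makes fine-mapping
    calibration meaningful. ``ld_scale_cm = 0`` switches the latent
    autocorrelation off (independent markers). Within-subpopulation kinship
    exceeds between-subpopulation kinship whenever the divergence is
    positive.
    """
    from scipy import stats as _stats

    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if n_subpopulations < 1:
        raise ValueError("n_subpopulations must be >= 1")
    if not 0 <= fst_like_divergence < 1:
        raise ValueError("fst_like_divergence must be in [0, 1)")
    if ld_scale_cm < 0:
        raise ValueError("ld_scale_cm must be >= 0")
    validate_marker_map(markers)
    rng = np.random.default_rng(seed)
    m = len(markers)
    chrom_codes = pd.factorize(markers["chrom"])[0]
    cm = markers["cM"].to_numpy(dtype=float)

    def ar1_field(n_rows: int) -> np.ndarray:
        """Stationary N(0,1) AR(1) rows along the genetic map."""
        innov = rng.normal(size=(n_rows, m))
        z = np.empty((n_rows, m))
        for c in np.unique(chrom_codes):
            cols = np.flatnonzero(chrom_codes == c)
            z[:, cols[0]] = innov[:, cols[0]]
            for prev, cur in zip(cols[:-1], cols[1:]):
                rho = (
                    np.exp(-(cm[cur] - cm[prev]) / ld_scale_cm)
                    if ld_scale_cm > 0
                    else 0.0
                )
                z[:, cur] = rho * z[:, prev] + np.sqrt(1.0 - rho**2) * innov[:, cur]
        return z

    from scipy.special import ndtr

    ancestral = 0.1 + 0.8 * ndtr(ar1_field(1)[0])
    if fst_like_divergence == 0:
        sub_freq = np.tile(ancestral, (n_subpopulations, 1))
    else:
        f = fst_like_divergence
        a = ancestral * (1 - f) / f
        b = (1 - ancestral) * (1 - f) / f
        sub_freq = _stats.beta.ppf(ndtr(ar1_field(n_subpopulations)), a, b)
        sub_freq = np.clip(sub_freq, 1e-6, 1 - 1e-6)
    assignment = np.arange(n_strains) % n_subpopulations

    z = ar1_field(n_strains)
    thresholds = ndtri(sub_freq[assignment])
    calls = (z < thresholds).astype(float)
    strains = [f"WILD_{i + 1:04d}" for i in range(n_strains)]
    gm = GenotypeMatrix(strains=strains, markers=markers.copy(), calls=calls)
    gm.subpopulation = assignment  # diagnostic channel, not part of the type
    return gm


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    qtls: list[QTLSpec],
    polygenic_h2: float = 0.0,
    seed: int = 0,
    standardize: bool = True,
) -> pd.Series:
    """Simulate one trait value per strain with the requested architecture.

    The trait is a sum of per-QTL genotype effects scaled to the requested
    variance fractions, a polygenic term built from small effects at every
    marker scaled to ``polygenic_h2``, and i.i.d. Gaussian noise filling the
    remainder. Each component is standardized empirically before scaling so
    the realized variance decomposition matches the request up to the sampling
    covariance between components.
    """
    if not 0 <= polygenic_h2 <= 1:
        raise ValueError("polygenic_h2 must be in [0, 1]")
    total_ve = sum(q.variance_explained for q in qtls) + polygenic_h2
    if total_ve > 1 + 1e-12:
        raise ValueError(f"variance fractions sum to {total_ve:.3f} > 1")
    rng = np.random.default_rng(seed)
    n = genotypes.n_strains
    y = np.zeros(n)
    for q in qtls:
        g = genotypes.calls[:, genotypes.marker_index(q.marker_id)]
        g = np.where(np.isnan(g), np.nanmean(g), g)
        y += np.sqrt(q.variance_explained) * _standardize(g)
    if polygenic_h2 > 0:
        w = rng.normal(size=genotypes.n_markers)
        calls = np.where(np.isnan(genotypes.calls),
                         np.nanmean(genotypes.calls, axis=0), genotypes.calls)
        u = calls @ w
        y += np.sqrt(polygenic_h2) * _standardize(u)
    resid = 1.0 - total_ve
    if resid > 1e-12:
        eps = rng.normal(size=n)
        y += np.sqrt(resid) * _standardize(eps)
    out = pd.Series(y, index=pd.Index(genotypes.strains, name="strain"),
                    name="trait")
    if standardize:
        out = (out - out.mean()) / out.std()
    return out


# ---------------------------------------------------------------------------
# BIOSORT-like well records
# ---------------------------------------------------------------------------

#: Baseline animal length (TOF units) of drug-stunted progeny, and the scale
#: converting one strain-effect SD into TOF units. The 60-unit control offset
#: mirrors the observation that unexposed animals grow longer.
_TOF_BASE_DRUG = 250.0
_TOF_BASE_CONTROL = 310.0
_TOF_PER_EFFECT_SD = 30.0
_TOF_WITHIN_WELL_SD = 25.0


def simulate_well_data(
    strain_effects: pd.Series,
    n_assays: int = 3,
    assay_shift_sd: float = 0.25,
    control_coupling: float = 0.6,
    animals_per_well: int = 50,
    well_noise_sd: float = 0.5,
    drug_name: str = "etoposide",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate paired drug/control well records for each strain x assay.

    Each strain carries two latent quantities: its drug-response effect
    (``strain_effects``, the signal the pipeline should recover) and an
    independent baseline growth propensity (the nuisance the control
    condition exists to measure). Control wells measure the baseline; drug
    wells measure the drug effect plus ``control_coupling`` times the
    baseline, so the control regression can remove the shared component.
    Both conditions get their own per-assay block shift (``assay_shift_sd``,
    in strain-effect SD units) and every well an independent biological
    deviation (``well_noise_sd``, same units), so strain repeatability across
    assays is high but not perfect. Per-animal lengths are Gaussian around
    the well mean in TOF units; brood counts are Poisson and normalized later by
    the three sorted animals; fluorescence is zero for non-reporter strains.

    Returns a long DataFrame with one row per well: columns ``assay``,
    ``plate``, ``well``, ``strain``, ``condition``, ``drug_name``,
    ``sorted_n``, ``animal_lengths`` (list of floats), ``brood_count``,
    ``fluorescence``, ``exclude``.
    """
    if n_assays < 1:
        raise ValueError("n_assays must be >= 1")
    if animals_per_well < 1:
        raise ValueError("animals_per_well must be >= 1")
    rng = np.random.default_rng(seed)
    baseline = pd.Series(
        rng.normal(size=len(strain_effects)), index=strain_effects.index
    )
    rows = []
    for a in range(n_assays):
        shift_drug = rng.normal(0.0, assay_shift_sd) if assay_shift_sd > 0 else 0.0
        shift_ctrl = rng.normal(0.0, assay_shift_sd) if assay_shift_sd > 0 else 0.0
        for w, (strain, effect) in enumerate(strain_effects.items()):
            well_label = f"{chr(ord('A') + w % 8)}{w // 8 + 1:02d}"
            for condition, base, mean_effect, shift in (
                ("drug", _TOF_BASE_DRUG,
                 effect + control_coupling * baseline[strain], shift_drug),
                ("control", _TOF_BASE_CONTROL, baseline[strain], shift_ctrl),
            ):
                well_dev = rng.normal(0.0, well_noise_sd) if well_noise_sd > 0 else 0.0
                mu = base + _TOF_PER_EFFECT_SD * (mean_effect + shift + well_dev)
                lengths = rng.normal(mu, _TOF_WITHIN_WELL_SD, size=animals_per_well)
                lengths = np.clip(lengths, 1.0, None)
                brood_mu = 45.0 if condition == "drug" else 90.0
                rows.append(
                    {
                        "assay": f"assay{a + 1}",
                        "plate": f"p{a + 1}",
                        "well": well_label,
                        "strain": strain,
                        "condition": condition,
                        "drug_name": drug_name if condition == "drug" else "DMSO",
                        "sorted_n": 3,
                        "animal_lengths": lengths.round(2).tolist(),
                        "brood_count": int(rng.poisson(brood_mu)),
                        "fluorescence": 0.0,
                        "exclude": False,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pooled amplicon read counts under selection
# ---------------------------------------------------------------------------

def synthetic_dose_response_strain_values(
    h2: float,
    n_strains: int = 4,
    n_reps: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for a dose-response table with known heritability.

    Builds a balanced strain x replicate design (by default four genetically
    diverged strains in technical quadruplicates) whose realized variance
    components are fixed exactly by construction: within-strain replicate
    residuals are centered and scaled to unit sample variance in every
    strain, and strain means are scaled so the between-strain mean square
    matches a strain variance of ``h2 / (1 - h2)``. The balanced ANOVA moment
    estimator — and therefore an interior REML fit — recovers ``H2 = h2``
    from the returned values. This is a synthetic reference object, not
    measured data; it exists so the heritability estimator can be validated
    against a known truth.

    Returns a DataFrame with columns ``strain``, ``replicate``, ``value``.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must be in (0, 1)")
    if n_strains < 2 or n_reps < 2:
        raise ValueError("need >= 2 strains and >= 2 replicates")
    rng = np.random.default_rng(seed)
    var_strain = h2 / (1.0 - h2)  # residual variance fixed at 1
    a = rng.normal(size=n_strains)
    # between-strain mean square = k * var(strain means); set it exactly
    target_mean_var = var_strain + 1.0 / n_reps
    a = (a - a.mean()) / a.std(ddof=1) * np.sqrt(target_mean_var)
    rows = []
    for i in range(n_strains):
        e = rng.normal(size=n_reps)
        e = (e - e.mean()) / e.std(ddof=1)  # exact MSW contribution of 1
        for j in range(n_reps):
            rows.append((f"strain_{i + 1}", j + 1, a[i] + e[j]))
    return pd.DataFrame(rows, columns=["strain", "replicate", "value"])


def synthetic_editing_readcounts(
    fold_changes: dict[str, float] | None = None,
    control_fraction: float = 0.001,
    depth: int = 1_000_000,
    locus: str = "TOP2A",
) -> pd.DataFrame:
    """Synthetic stand-in for a pooled-editing read-count table.

    The real experiment sequences an edited locus in drug-treated and
    no-drug cell populations; only the edited-fraction fold changes and the
    significance pattern of the outcome are public. This builder inverts
    those headline numbers into a deterministic count table: the no-drug arm
    carries ``control_fraction`` edited reads (sub-1% editing, as observed)
    at the given depth, and each drug arm carries ``fold * control_fraction``.
    Counts are exact expectations (no sampling), so the enrichment statistics
    recomputed from the table equal the requested fold changes. This is a
    synthetic reference object for validating the enrichment pipeline, not
    measured data.
    """
    if fold_changes is None:
        fold_changes = {
            "etoposide": 168.2,
            "teniposide": 8.2,
            "XK469": 2.8,
            "amsacrine": 1.6,
            "dactinomycin": 0.93,
        }
    if not 0 < control_fraction < 1:
        raise ValueError("control_fraction must be in (0, 1)")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rows = []

    def add(condition: str, fraction: float, timepoint: str) -> None:
        edited = int(round(depth * fraction))
        rows.append(
            {
                "locus": locus,
                "condition": condition,
                "timepoint": timepoint,
                "wildtype_reads": depth - edited,
                "edited_reads": edited,
            }
        )

    add("no_drug", control_fraction, "pre")
    add("no_drug", control_fraction, "post")
    for condition, fold in fold_changes.items():
        frac = fold * control_fraction
        if not 0 < frac < 1:
            raise ValueError(
                f"fold {fold} at control fraction {control_fraction} leaves (0,1)"
            )
        add(condition, control_fraction, "pre")
        add(condition, frac, "post")
    return pd.DataFrame(rows)


def selection_expected_fraction(
    fraction_pre: float, relative_fitness: float, n_generations: float
) -> float:
    """Deterministic edited-allele fraction after haploid selection.

    ``f_t = f0 w^t / (f0 w^t + (1 - f0))`` for relative fitness ``w`` over
    ``t`` (possibly fractional) generations.
    """
    if not 0 < fraction_pre < 1:
        raise ValueError("fraction_pre must be in (0, 1)")
    if relative_fitness <= 0:
        raise ValueError("relative_fitness must be > 0")
    wt = relative_fitness ** n_generations
    return fraction_pre * wt / (fraction_pre * wt + (1.0 - fraction_pre))


def simulate_pooled_readcounts(
    edit_fraction_pre: float,
    relative_fitness_edited: float,
    n_generations: float,
    depth: int,
    seed: int = 0,
    locus: str = "TOP2A",
    condition: str = "etoposide",
) -> pd.DataFrame:
    """Simulate wild-type/edited read counts before and after selection.

    The post-selection edited fraction follows the deterministic selection
    recursion in :func:`selection_expected_fraction`; read counts at each
    timepoint are binomial at the given sequencing depth. A matched
    ``no_drug`` arm (relative fitness 1) is always emitted so enrichment
    contrasts against the control are possible.

    Returns a DataFrame with columns ``locus``, ``condition``, ``timepoint``
    (pre/post), ``wildtype_reads``, ``edited_reads``.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 < edit_fraction_pre < 1:
        raise ValueError("edit_fraction_pre must be in (0, 1)")
    rng = np.random.default_rng(seed)
    f_post = selection_expected_fraction(
        edit_fraction_pre, relative_fitness_edited, n_generations
    )
    rows = []
    for cond, fractions in (
        (condition, {"pre": edit_fraction_pre, "post": f_post}),
        ("no_drug", {"pre": edit_fraction_pre, "post": edit_fraction_pre}),
    ):
        for timepoint, f in fractions.items():
            edited = int(rng.binomial(depth, f))
            rows.append(
                {
                    "locus": locus,
                    "condition": cond,
                    "timepoint": timepoint,
                    "wildtype_reads": depth - edited,
                    "edited_reads": edited,
                }
            )
    return pd.DataFrame(rows)
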