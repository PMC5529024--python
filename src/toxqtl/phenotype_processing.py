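"""High-throughput phenotype processing for plate-based fitness assays.

The processing chain mirrors the standard plate-sorter workflow and runs in a
fixed, documented order:

1. :func:`summarize_wells` — per-well quantiles of animal length (TOF) and
   brood counts normalized by the number of sorted animals;
2. :func:`regress_assay` — residuals of a linear model on the assay factor,
   removing assay-to-assay block effects;
3. :func:`prune_outliers` — the single-pass IQR rule (drop values beyond
   Q75 + 2*IQR or Q25 - 2*IQR unless at least 5% of strains fall outside);
4. :func:`regress_control` — residuals of the drug trait on the paired
   control-condition trait, removing carrier/baseline effects.

Also here: broad-sense heritability from replicated strain measurements
(one-way random-effects REML, cross-checked against the balanced ANOVA
moment estimator), fluorescence gating of heterozygotes for dominance tests,
and Tukey-HSD pairwise strain comparisons.

Quantiles use linear interpolation between order statistics (type 7), the
dominant default in scientific software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .gwa_mapping import emma_reml


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability and its variance components."""

    H2: float
    var_strain: float
    var_resid: float
    degenerate: bool = False  # all values identical

    def __post_init__(self) -> None:
        if self.var_strain < 0 or self.var_resid < 0:
            raise ValueError("variance components must be non-negative")


def summarize_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-well summary statistics of the raw sorter records.

    Expects the long well-record layout (columns ``assay``, ``strain``,
    ``condition``, ``sorted_n``, ``animal_lengths``, ``brood_count``, and
    optionally ``exclude``). Returns one row per well with the 10th/25th/50th/
    75th/90th length quantiles (``q10`` ... ``q90``) and ``norm_n``, the brood
    count divided by the number of animals originally sorted. Wells flagged
    ``exclude`` are dropped; a well with ``sorted_n <= 0`` or no scored
    animals is an error.
    """
    if len(wells) == 0:
        return pd.DataFrame(
            columns=["assay", "strain", "condition",
                     "q10", "q25", "q50", "q75", "q90", "norm_n"]
        )
    if "exclude" in wells.columns:
        wells = wells[~wells["exclude"].astype(bool)]
    rows = []
    for _, rec in wells.iterrows():
        lengths = np.asarray(rec["animal_lengths"], dtype=float)
        if lengths.size == 0:
            raise ValueError(f"well {rec.get('well', '?')} has no scored animals")
        if rec["sorted_n"] <= 0:
            raise ValueError(f"well {rec.get('well', '?')} has sorted_n <= 0")
        q = np.quantile(lengths, [0.10, 0.25, 0.50, 0.75, 0.90])
        rows.append(
            {
                "assay": rec["assay"],
                "strain": rec["strain"],
                "condition": rec["condition"],
                "q10": q[0], "q25": q[1], "q50": q[2], "q75": q[3], "q90": q[4],
                "norm_n": rec["brood_count"] / rec["sorted_n"],
            }
        )
    return pd.DataFrame(rows)


def regress_assay(values: pd.Series, assay: pd.Series) -> pd.Series:
    """Residuals of a least-squares fit of the trait on the assay factor.

    With a categorical-only design the OLS residuals are simply deviations
    from assay-level means, so residuals sum to zero within each assay. A
    single assay level degenerates to centering.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 wells to regress out assay effects")
    if len(values) != len(assay):
        raise ValueError("values and assay labels must align")
    level_means = values.groupby(assay.to_numpy()).transform("mean")
    return values - level_means


def prune_outliers(values: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Single-pass IQR outlier pruning across strains.

    A value is flagged iff it exceeds ``Q75 + 2*IQR`` or falls below
    ``Q25 - 2*IQR`` (strict inequalities, quartiles computed once on the
    input). If the flagged set exceeds 5% of the strains nothing is removed —
    the escape clause for genuinely long-tailed traits (a single outlier in a
    20-strain panel is still pruned; two are not). Fewer than 4 values: no
    pruning, with a warning.

    Returns ``(pruned_values, removed_flags)`` where flags index the input.
    """
    if len(values) < 4:
        warnings.warn("fewer than 4 values; outlier pruning skipped")
        return values.copy(), pd.Series(False, index=values.index)
    q25, q75 = np.quantile(values.to_numpy(dtype=float), [0.25, 0.75])
    iqr = q75 - q25
    flags = (values > q75 + 2.0 * iqr) | (values < q25 - 2.0 * iqr)
    if flags.sum() > 0.05 * len(values):
        flags = pd.Series(False, index=values.index)
    return values[~flags].copy(), flags


def regress_control(
    drug_traits: pd.Series, control_traits: pd.Series
) -> pd.Series:
    """Residuals of the drug-condition trait on the control-condition trait.

    Strains are matched by index; unmatched strains are dropped with a
    warning. A constant control regressor degenerates to centering the drug
    values. Residuals are uncorrelated with the control values (least-squares
    orthogonality).
    """
    shared = drug_traits.index.intersection(control_traits.index)
    dropped = len(drug_traits) - len(shared)
    if dropped:
        warnings.warn(f"{dropped} strains lack a matched control; dropped")
    if len(shared) < 3:
        raise ValueError(f"need >= 3 matched strains, got {len(shared)}")
    y = drug_traits.loc[shared].to_numpy(dtype=float)
    x = control_traits.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0:
        resid = y - y.mean()
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
    return pd.Series(resid, index=shared, name=drug_traits.name)


def estimate_heritability(
    values: pd.Series, strain: pd.Series
) -> HeritabilityEstimate:
    """Broad-sense heritability from replicated strain measurements.

    Fits the one-way random-effects model ``y = mu + a_strain + e`` by exact
    REML (the strain incidence matrix turns it into the kinship mixed model
    with ``K = Z Z'``) and reports ``H2 = var_strain / (var_strain +
    var_resid)``. A negative genetic-variance solution is clamped to zero;
    for balanced designs the estimate agrees with the ANOVA moment estimator
    ``(MSB - MSW) / k``. An all-identical input returns ``H2 = 0`` flagged
    degenerate.
    """
    if len(values) != len(strain):
        raise ValueError("values and strain labels must align")
    strains = pd.unique(strain)
    if len(strains) < 2:
        raise ValueError("need >= 2 strains")
    counts = strain.value_counts()
    if (counts >= 2).sum() < 1:
        raise ValueError("need >= 2 replicates for at least one strain")
    y = values.to_numpy(dtype=float)
    if np.std(y) == 0:
        return HeritabilityEstimate(0.0, 0.0, 0.0, degenerate=True)
    Z = (strain.to_numpy()[:, None] == np.asarray(strains)[None, :]).astype(float)
    K = Z @ Z.T
    vc = emma_reml(y, np.ones((len(y), 1)), K)
    var_strain, var_resid = vc.sigma2_g, vc.sigma2_e
    # delta at the search boundary means the genetic component is not
    # distinguishable from zero
    if var_strain <= var_resid * 10 ** (-4.5):
        var_strain = 0.0
    total = var_strain + var_resid
    h2 = var_strain / total if total > 0 else 0.0
    return HeritabilityEstimate(h2, var_strain, var_resid)


def classify_heterozygotes(
    fluorescence: np.ndarray | pd.Series,
    bright_parent: np.ndarray | pd.Series,
    dark_parent: np.ndarray | pd.Series,
    dark_gate_percentile: float = 95.0,
    bright_gate_percentile: float = 5.0,
) -> np.ndarray:
    """Gate animals into het / parental classes by fluorescence.

    The dark gate is the 95th percentile of the non-fluorescent parent and
    the bright gate the 5th percentile of the fluorescent parent; an animal
    strictly between the gates is a heterozygote, otherwise it is assigned to
    the parental class on its side. Overlapping gates (dark >= bright) are an
    error demanding manually chosen gates.
    """
    bright = np.asarray(bright_parent, dtype=float)
    dark = np.asarray(dark_parent, dtype=float)
    if bright.size == 0 or dark.size == 0:
        raise ValueError("both parental reference distributions must be non-empty")
    dark_gate = np.percentile(dark, dark_gate_percentile)
    bright_gate = np.percentile(bright, bright_gate_percentile)
    if dark_gate >= bright_gate:
        raise ValueError(
            f"gates overlap (dark 95th = {dark_gate:.3g} >= bright 5th = "
            f"{bright_gate:.3g}); supply manual gates"
        )
    f = np.asarray(fluorescence, dtype=float)
    labels = np.where(
        f <= dark_gate,
        "parental_dark",
        np.where(f >= bright_gate, "parental_bright", "het"),
    )
    return labels


def compare_strains(values: pd.Series, strain: pd.Series) -> pd.DataFrame:
    """Pairwise strain comparisons: one-way ANOVA + Tukey's HSD.

    Family-wise adjusted p-values come from the studentized-range
    distribution; unbalanced groups are handled by the Tukey-Kramer
    harmonic-mean correction (as implemented in statsmodels).
    Returns a DataFrame with columns ``strain_a``, ``strain_b``,
    ``mean_diff``, ``p_adj``.
    """
    if len(values) != len(strain):
        raise ValueError("values and strain labels must align")
    counts = strain.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 strains with >= 2 replicates each")
    res = pairwise_tukeyhsd(values.to_numpy(dtype=float), strain.to_numpy())
    table = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    return pd.DataFrame(
        {
            "strain_a": table["group1"],
            "strain_b": table["group2"],
            "mean_diff": table["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
        }
    )


def process_trait(
    wells: pd.DataFrame,
    trait: str = "q50",
    prune: bool = True,
) -> pd.Series:
    """Run the full chain on raw well records for one trait.

    summarize -> assay regression -> per-strain aggregation (mean) ->
    outlier pruning -> control regression. Returns the final residual trait
    keyed by strain for the drug condition.
    """
    summaries = summarize_wells(wells)
    if trait not in summaries.columns:
        raise ValueError(f"unknown trait {trait!r}")
    summaries = summaries.copy()
    summaries["resid"] = regress_assay(summaries[trait], summaries["assay"])
    per_strain = (
        summaries.groupby(["condition", "strain"])["resid"].mean().unstack(level=0)
    )
    if "drug" not in per_strain.columns or "control" not in per_strain.columns:
        raise ValueError("well records must contain both drug and control wells")
    drug = per_strain["drug"].dropna()
    control = per_strain["control"].dropna()
    if prune:
        drug, _ = prune_outliers(drug)
    return regress_control(drug, control).rename(trait)
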