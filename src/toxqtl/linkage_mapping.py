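"""Linkage mapping on recombinant inbred panels with a correlation LOD score.

The scan statistic at a marker is ``LOD = -n * ln(1 - r^2) / (2 * ln 10)``
where ``r`` is the Pearson correlation between marker genotype and trait over
the ``n`` strains with complete data at that marker. Genome-wide significance
comes from permutations of strain labels (moved jointly across traits so the
trait-trait correlation structure is preserved); confidence intervals are
1.5-LOD-drop regions around each chromosome's retained peak; the variance a
QTL explains is ``1 - 10^(-2*LOD/n)`` and is reported both raw and as a
fraction of the trait's broad-sense heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix

_LN10 = np.log(10.0)


@dataclass
class QTLInterval:
    """A QTL confidence/interest region on one chromosome (1-based, inclusive)."""

    chromosome: str
    left_bp: int
    right_bp: int
    peak_marker: str
    peak_lod: float
    variance_explained: float | None = None
    fraction_of_h2: float | None = None

    def __post_init__(self) -> None:
        if self.left_bp > self.right_bp:
            raise ValueError("interval left_bp must be <= right_bp")


@dataclass
class ScanResult:
    """Per-marker association strengths with thresholds, peaks and intervals."""

    markers: pd.DataFrame = field(repr=False)  # marker, chrom, pos_bp, lod
    threshold: float | None = None
    peaks: pd.DataFrame | None = None
    intervals: list[QTLInterval] = field(default_factory=list)
    n_strains: int = 0


def lod_score(genotype: np.ndarray, phenotype: np.ndarray) -> float:
    """Correlation LOD score between one marker and one trait.

    Pairs with a missing genotype or trait value are dropped; ``n`` in the
    formula is the number of complete pairs. A zero-variance genotype or trait
    yields LOD 0 with a warning (the correlation is undefined).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = ~(np.isnan(g) | np.isnan(y))
    g, y = g[ok], y[ok]
    n = g.size
    if n < 3:
        raise ValueError(f"need >= 3 complete genotype/trait pairs, got {n}")
    if g.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance genotype or trait; LOD set to 0")
        return 0.0
    r = np.corrcoef(g, y)[0, 1]
    one_minus_r2 = max(1.0 - r * r, np.finfo(float).tiny)
    return -n * np.log(one_minus_r2) / (2.0 * _LN10)


def _scan_lods(calls: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized per-marker LOD over a strains x markers call matrix."""
    missing = np.isnan(calls) | np.isnan(y)[:, None]
    g = np.where(missing, 0.0, calls)
    yv = np.where(np.isnan(y), 0.0, y)[:, None] * ~missing
    n = (~missing).sum(axis=0).astype(float)
    sg = g.sum(axis=0)
    sy = yv.sum(axis=0)
    sgg = (g * g).sum(axis=0)
    syy = (yv * yv).sum(axis=0)
    sgy = (g * yv).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sgy - sg * sy / n
        vg = sgg - sg * sg / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vg * vy)
    r2 = np.where((vg <= 0) | (vy <= 0) | (n < 3), 0.0, r2)
    one_minus = np.clip(1.0 - r2, np.finfo(float).tiny, None)
    return -n * np.log(one_minus) / (2.0 * _LN10)


def genome_scan(
    genotypes: GenotypeMatrix,
    trait: pd.Series,
    threshold: float | None = None,
    standardize: bool = True,
) -> ScanResult:
    """LOD scan at every marker; one peak retained per chromosome.

    The trait is standardized to mean zero and unit variance before scanning
    (the statistic is affine-invariant; standardization is kept for parity
    with downstream variance accounting). Peaks are each chromosome's maximum
    LOD; when a ``threshold`` is supplied, only chromosomes whose maximum
    exceeds it contribute peaks.
    """
    shared = [s for s in genotypes.strains if s in trait.index]
    if not shared:
        raise ValueError("no strains shared between genotypes and trait")
    if len(shared) < 10:
        warnings.warn(f"only {len(shared)} shared strains; scan may be unstable")
    idx = [genotypes.strains.index(s) for s in shared]
    calls = genotypes.calls[idx]
    y = trait.loc[shared].to_numpy(dtype=float)
    if standardize and y.std() > 0:
        y = (y - y.mean()) / y.std()

    lods = _scan_lods(calls, y)
    df = genotypes.markers[["marker", "chrom", "pos_bp"]].copy()
    df["lod"] = lods

    peak_rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        i = sub["lod"].idxmax()
        if threshold is None or df.loc[i, "lod"] > threshold:
            peak_rows.append(df.loc[i])
    peaks = pd.DataFrame(peak_rows).reset_index(drop=True)
    return ScanResult(markers=df, threshold=threshold, peaks=peaks,
                      n_strains=len(shared))


def permutation_threshold(
    genotypes: GenotypeMatrix,
    trait_matrix: pd.DataFrame | pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    mode: str = "max_lod",
) -> float:
    """Empirical genome-wide LOD threshold from joint strain permutations.

    Strain rows of the trait matrix are permuted as units so correlations
    among traits are preserved. In the default ``max_lod`` mode the threshold
    is the ``1 - alpha`` quantile of the per-permutation genome-wide maximum
    LOD (maximum over markers and traits). The alternative ``peak_ratio``
    mode returns the smallest candidate LOD at which the expected number of
    chromosome-wise peaks under permutation, relative to the number observed
    at that threshold in the permutations themselves, first drops to
    ``alpha`` — a reading of the expected/observed peak-count criterion, one
    chromosome maximum counting as one peak.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if isinstance(trait_matrix, pd.Series):
        trait_matrix = trait_matrix.to_frame()
    shared = [s for s in genotypes.strains if s in trait_matrix.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared strains")
    idx = [genotypes.strains.index(s) for s in shared]
    calls = genotypes.calls[idx]
    traits = trait_matrix.loc[shared].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    max_lods = np.empty(n_perm)
    chrom_codes = pd.factorize(genotypes.markers["chrom"])[0]
    n_chrom = chrom_codes.max() + 1
    perm_chrom_max = np.empty((n_perm, n_chrom)) if mode == "peak_ratio" else None
    for p in range(n_perm):
        order = rng.permutation(len(shared))
        permuted = traits[order]
        lods = np.column_stack(
            [_scan_lods(calls, permuted[:, t]) for t in range(permuted.shape[1])]
        )
        max_lods[p] = lods.max()
        if perm_chrom_max is not None:
            per_marker = lods.max(axis=1)
            perm_chrom_max[p] = [
                per_marker[chrom_codes == c].max() for c in range(n_chrom)
            ]
    if mode == "max_lod":
        return float(np.quantile(max_lods, 1.0 - alpha))
    if mode == "peak_ratio":
        # candidate thresholds: observed permutation chromosome maxima
        candidates = np.sort(np.unique(perm_chrom_max.ravel()))
        expected = [(perm_chrom_max > t).sum(axis=1).mean() for t in candidates]
        expected = np.asarray(expected)
        ok = expected <= alpha
        if not ok.any():
            return float(candidates[-1])
        return float(candidates[np.argmax(ok)])
    raise ValueError(f"unknown threshold mode: {mode!r}")


def lod_drop_interval(
    scan: ScanResult, chromosome: str, drop: float = 1.5
) -> QTLInterval:
    """Maximal contiguous marker run around the peak within ``drop`` LOD.

    Requires the chromosome's peak to exceed the scan threshold (if one is
    set). Interval endpoints are marker positions (1-based, inclusive).
    """
    sub = scan.markers[scan.markers["chrom"] == chromosome].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no markers on chromosome {chromosome!r}")
    peak_i = int(sub["lod"].idxmax())
    peak_lod = float(sub.loc[peak_i, "lod"])
    if scan.threshold is not None and peak_lod <= scan.threshold:
        raise ValueError(
            f"peak LOD {peak_lod:.2f} on {chromosome} does not exceed "
            f"threshold {scan.threshold:.2f}; no interval"
        )
    floor = peak_lod - drop
    left = peak_i
    while left > 0 and sub.loc[left - 1, "lod"] >= floor:
        left -= 1
    right = peak_i
    while right < len(sub) - 1 and sub.loc[right + 1, "lod"] >= floor:
        right += 1
    return QTLInterval(
        chromosome=chromosome,
        left_bp=int(sub.loc[left, "pos_bp"]),
        right_bp=int(sub.loc[right, "pos_bp"]),
        peak_marker=str(sub.loc[peak_i, "marker"]),
        peak_lod=peak_lod,
    )


def variance_explained(
    peak_lod: float, n: int, h2: float
) -> tuple[float, float]:
    """Phenotypic variance explained by a peak, and its share of heritability.

    ``ve = 1 - 10^(-2 * LOD / n)`` inverts the LOD formula back to the squared
    correlation; dividing by the broad-sense heritability says how much of the
    heritable variance the QTL accounts for.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]")
    if peak_lod < 0:
        raise ValueError("peak_lod must be >= 0")
    ve = 1.0 - 10.0 ** (-2.0 * peak_lod / n)
    return ve, ve / h2
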