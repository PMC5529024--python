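"""Sliding-window Tajima's D over an inbred genotype panel.

Tajima's D contrasts mean pairwise diversity (pi) with the segregating-site
estimate of the population mutation rate (S / a1); an excess of rare variants
drives D negative, an excess of intermediate-frequency variants (as under
balancing selection or a soft sweep's shoulder) drives it positive. Windows
advance in SNV-rank units (default 300-SNV windows sliding by 100 SNVs) and
never span chromosome boundaries. Inbred strain calls are treated as haploid
sequences. The reference strain can be excluded from the sample before
computing the statistic (the default, mirroring its use as an outgroup
label); exclusion is a sample-composition choice, not a polarization — the
statistic is folded and needs no ancestral state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import GenotypeMatrix


@dataclass
class TajimaConstants:
    """The standard normalizing constants for sample size n."""

    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Closed-form constants of Tajima's variance normalization."""
    if n < 2:
        raise ValueError("need sample size >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def pairwise_diversity(haplotypes: np.ndarray) -> float:
    """Mean pairwise differences (pi) over biallelic sites.

    Site-wise computation: a site with ``n_s`` non-missing calls and ``c_s``
    copies of the derived/alternate allele contributes
    ``c_s (n_s - c_s) / C(n_s, 2)`` mismatching pairs on average.
    """
    h = np.asarray(haplotypes, dtype=float)
    ok = ~np.isnan(h)
    n_s = ok.sum(axis=0).astype(float)
    c_s = np.nansum(h, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = c_s * (n_s - c_s) / (n_s * (n_s - 1) / 2.0)
    return float(np.nansum(np.where(n_s >= 2, contrib, 0.0)))


def tajimas_d(haplotypes: np.ndarray) -> tuple[float, int, float]:
    """Tajima's D for ``n`` haploid sequences x ``S`` biallelic sites.

    Returns ``(D, S, pi)`` where ``S`` counts segregating sites after
    removing monomorphic columns. ``D = (pi - S/a1) / sqrt(e1*S +
    e2*S*(S-1))``. With no segregating sites D is undefined and returned as
    NaN. Constants use the full sample size even when individual sites carry
    missing calls (site-wise pairwise-complete pi).
    """
    h = np.asarray(haplotypes, dtype=float)
    if h.ndim != 2:
        raise ValueError("haplotypes must be a 2-D array (sequences x sites)")
    n = h.shape[0]
    if n < 4:
        raise ValueError("need >= 4 sequences for Tajima's D")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        freq = np.nanmean(h, axis=0)
    segregating = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    S = int(segregating.sum())
    if S == 0:
        return float("nan"), 0, 0.0
    h = h[:, segregating]
    pi = pairwise_diversity(h)
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    D = (pi - S / c.a1) / np.sqrt(var)
    return float(D), S, pi


def sliding_tajimas_d(
    genotypes: GenotypeMatrix,
    window_snvs: int = 300,
    step_snvs: int = 100,
    outgroup: str | None = None,
    include_outgroup: bool = False,
) -> pd.DataFrame:
    """Windowed Tajima's D in SNV-rank units, per chromosome.

    Windows of ``window_snvs`` SNVs advance by ``step_snvs`` and never cross
    a chromosome boundary; a chromosome with fewer SNVs than one window is
    skipped with a warning. The ``outgroup`` strain (typically the reference
    isolate) is dropped from the sample before computing S and pi unless
    ``include_outgroup`` is set.

    Returns a DataFrame with columns ``chrom``, ``start_rank``, ``end_rank``
    (1-based inclusive SNV ranks within the chromosome), ``start_bp``,
    ``end_bp``, ``mid_bp``, ``S``, ``pi``, ``D``.
    """
    if window_snvs < 2 or step_snvs < 1:
        raise ValueError("window_snvs must be >= 2 and step_snvs >= 1")
    calls = genotypes.calls
    strains = list(genotypes.strains)
    if outgroup is not None and not include_outgroup:
        if outgroup in strains:
            keep = [i for i, s in enumerate(strains) if s != outgroup]
            calls = calls[keep]
        else:
            warnings.warn(f"outgroup {outgroup!r} not in panel; nothing excluded")
    rows = []
    for chrom, sub in genotypes.markers.groupby("chrom", sort=False):
        m = len(sub)
        if m < window_snvs:
            warnings.warn(
                f"chromosome {chrom} has {m} SNVs < window {window_snvs}; skipped"
            )
            continue
        pos = sub["pos_bp"].to_numpy()
        cols = sub.index.to_numpy()
        for start in range(0, m - window_snvs + 1, step_snvs):
            end = start + window_snvs
            D, S, pi = tajimas_d(calls[:, cols[start:end]])
            rows.append(
                {
                    "chrom": chrom,
                    "start_rank": start + 1,
                    "end_rank": end,
                    "start_bp": int(pos[start]),
                    "end_bp": int(pos[end - 1]),
                    "mid_bp": int((pos[start] + pos[end - 1]) // 2),
                    "S": S,
                    "pi": pi,
                    "D": D,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_rank", "end_rank", "start_bp", "end_bp",
                 "mid_bp", "S", "pi", "D"],
    )
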