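"""Allele-enrichment statistics for pooled CRISPR editing experiments.

A population of cells is edited at low efficiency, split into drug and
no-drug arms, passaged, and deep-sequenced at the edited locus. Reads are
counted only on exact full-span match to the wild-type or the edited
reference (anything else — indels, sequencing errors — is unmatched). The
headline statistic per locus x drug is the fold change of the edited-allele
fraction in the treated arm over the no-drug control, with a two-sided
Fisher's exact test on the 2x2 count table (edited/wild-type x
treated/control). Both the treated-vs-control and post-vs-pre contrasts are
exposed. A power helper quantifies the detection limit when the starting
edited fraction is very small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    """Fold enrichment of the edited allele and its Fisher's exact test.

    ``fold_change`` is the edited-allele fraction in the treatment divided by
    the edited-allele fraction in the control (NaN when the control fraction
    is zero; the p-value is still defined). The two-sided p uses the
    minimum-likelihood rule: the sum of probabilities of all tables, with the
    observed margins, no more likely than the observed one.
    """

    fold_change: float
    odds_ratio: float
    p_value: float
    treated_wildtype: int
    treated_edited: int
    control_wildtype: int
    control_edited: int
    locus: str = ""
    condition: str = ""


def count_alleles(
    reads: list[str], wildtype_ref: str, edited_ref: str
) -> tuple[int, int, int]:
    """Exact-match allele counting.

    A read increments the wild-type or edited counter only when it equals the
    corresponding reference over its full span; every other read (one
    mismatch is enough) is unmatched. Identical references are an error.
    """
    if wildtype_ref == edited_ref:
        raise ValueError("wild-type and edited references are identical")
    wt = ed = unmatched = 0
    for read in reads:
        if read == wildtype_ref:
            wt += 1
        elif read == edited_ref:
            ed += 1
        else:
            unmatched += 1
    return wt, ed, unmatched


def enrichment_test(
    treated: tuple[int, int],
    control: tuple[int, int],
    locus: str = "",
    condition: str = "",
) -> EnrichmentResult:
    """Edited-fraction fold change and Fisher's exact test.

    ``treated`` and ``control`` are ``(wildtype_reads, edited_reads)`` pairs;
    both arms must have positive totals.
    """
    wt_t, ed_t = (int(x) for x in treated)
    wt_c, ed_c = (int(x) for x in control)
    if min(wt_t, ed_t, wt_c, ed_c) < 0:
        raise ValueError("read counts must be non-negative")
    if wt_t + ed_t == 0 or wt_c + ed_c == 0:
        raise ValueError("both conditions need positive read totals")
    frac_t = ed_t / (ed_t + wt_t)
    frac_c = ed_c / (ed_c + wt_c)
    fold = frac_t / frac_c if frac_c > 0 else float("nan")
    table = np.array([[ed_t, wt_t], [ed_c, wt_c]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        fold_change=float(fold),
        odds_ratio=float(odds),
        p_value=float(p),
        treated_wildtype=wt_t,
        treated_edited=ed_t,
        control_wildtype=wt_c,
        control_edited=ed_c,
        locus=locus,
        condition=condition,
    )


def enrichment_from_table(
    readcounts: pd.DataFrame,
    control_condition: str = "no_drug",
    timepoint: str = "post",
    contrast: str = "vs_control",
) -> pd.DataFrame:
    """Per locus x drug enrichment from a tidy read-count table.

    ``readcounts`` needs columns ``locus``, ``condition``, ``timepoint``,
    ``wildtype_reads``, ``edited_reads``. The default contrast compares each
    drug condition's post-treatment counts against the no-drug control at the
    same timepoint; ``contrast="post_vs_pre"`` instead compares each
    condition's post counts against its own pre-treatment counts.
    """
    required = {"locus", "condition", "timepoint", "wildtype_reads", "edited_reads"}
    if not required.issubset(readcounts.columns):
        raise ValueError(f"read-count table needs columns {sorted(required)}")
    rows = []
    for locus, sub in readcounts.groupby("locus", sort=False):
        if contrast == "vs_control":
            ctrl = sub[
                (sub["condition"] == control_condition)
                & (sub["timepoint"] == timepoint)
            ]
            if len(ctrl) != 1:
                raise ValueError(
                    f"locus {locus}: expected one {control_condition}/{timepoint} row"
                )
            ctrl_counts = (
                int(ctrl["wildtype_reads"].iloc[0]),
                int(ctrl["edited_reads"].iloc[0]),
            )
            tests = sub[
                (sub["condition"] != control_condition)
                & (sub["timepoint"] == timepoint)
            ]
            for _, rec in tests.iterrows():
                res = enrichment_test(
                    (int(rec["wildtype_reads"]), int(rec["edited_reads"])),
                    ctrl_counts,
                    locus=str(locus),
                    condition=str(rec["condition"]),
                )
                rows.append(res)
        elif contrast == "post_vs_pre":
            for condition, arm in sub.groupby("condition", sort=False):
                pre = arm[arm["timepoint"] == "pre"]
                post = arm[arm["timepoint"] == "post"]
                if len(pre) != 1 or len(post) != 1:
                    continue
                res = enrichment_test(
                    (int(post["wildtype_reads"].iloc[0]),
                     int(post["edited_reads"].iloc[0])),
                    (int(pre["wildtype_reads"].iloc[0]),
                     int(pre["edited_reads"].iloc[0])),
                    locus=str(locus),
                    condition=str(condition),
                )
                rows.append(res)
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
    return pd.DataFrame([vars(r) for r in rows])


def detect_depletion_power(
    pre_fraction: float,
    depth: int,
    effect: float,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo power to detect an ``effect``-fold allele depletion.

    The control arm keeps the edited fraction at ``pre_fraction``; the
    treated arm depletes it ``effect``-fold. Both arms draw binomial counts
    at ``depth`` and the fraction of replicates with a Fisher p below
    ``alpha`` is the power. With ``effect = 1`` this calibrates to ~alpha.
    Quantifies why depletion of an allele edited into <1% of cells is hard to
    detect at practical sequencing depths.
    """
    if not 0 < pre_fraction < 1:
        raise ValueError("pre_fraction must be in (0, 1)")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if effect <= 0:
        raise ValueError("effect must be > 0")
    rng = np.random.default_rng(seed)
    treated_frac = pre_fraction / effect
    hits = 0
    for _ in range(n_reps):
        ed_c = int(rng.binomial(depth, pre_fraction))
        ed_t = int(rng.binomial(depth, treated_frac))
        res = enrichment_test((depth - ed_t, ed_t), (depth - ed_c, ed_c))
        if res.p_value < alpha:
            hits += 1
    return hits / n_reps
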