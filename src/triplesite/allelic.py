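"""Allele-specific binding analysis for F1-hybrid ChIP-seq count tables.

Reads at heterozygous sites in an F1 cross (reference = C57BL/6J,
alternate = A/J) are assigned upstream to a parental genome; this module
consumes the resulting per-site, per-factor count tables.  Sites are
classified by an exact two-sided binomial test against an unbiased 0.5
ratio, and co-binding between factors is quantified as the correlation of
their allele frequencies at shared sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REF_LABEL = "C57"
ALT_LABEL = "A/J"

BIAS_REF = f"{REF_LABEL} > {ALT_LABEL}"  # reference-preferring
BIAS_ALT = f"{ALT_LABEL} > {REF_LABEL}"  # alternate-preferring
BIAS_NONE = f"{REF_LABEL} ~ {ALT_LABEL}"  # no significant bias
BIAS_CLASSES = (BIAS_REF, BIAS_ALT, BIAS_NONE)


@dataclass(frozen=True)
class AllelicCount:
    site_id: int
    factor: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


def allele_frequency(count: AllelicCount) -> float:
    """Fraction of allele-informative reads on the reference allele."""
    if count.total < 1:
        raise ValueError("site has zero allelic reads")
    return count.ref_count / count.total


@lru_cache(maxsize=100_000)
def _binom_pvalue(k: int, n: int) -> float:
    return float(stats.binomtest(k, n, 0.5).pvalue)


def classify_bias(count: AllelicCount, alpha: float = 0.05) -> tuple[str, float]:
    """Exact two-sided binomial test of the allelic ratio against 0.5.

    P-values follow the minimum-likelihood convention (sum of both tails
    at least as extreme).  Significant sites are labelled by the preferred
    allele; others are unbiased.
    """
    if count.total < 1:
        raise ValueError("site has zero allelic reads")
    p = _binom_pvalue(count.ref_count, count.total)
    if p < alpha:
        label = BIAS_REF if count.ref_count > count.alt_count else BIAS_ALT
    else:
        label = BIAS_NONE
    return label, float(p)


def classify_table(
    counts: Sequence[AllelicCount], alpha: float = 0.05, min_coverage: int = 5
) -> pd.DataFrame:
    """Per-site bias table; sites below ``min_coverage`` total reads are
    dropped (too few informative reads to call bias either way)."""
    rows = []
    for c in counts:
        if c.total < min_coverage:
            continue
        label, p = classify_bias(c, alpha)
        rows.append(
            {
                "site_id": c.site_id,
                "factor": c.factor,
                "ref_count": c.ref_count,
                "alt_count": c.alt_count,
                "frequency": allele_frequency(c),
                "bias_class": label,
                "pvalue": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "factor",
            "ref_count",
            "alt_count",
            "frequency",
            "bias_class",
            "pvalue",
        ],
    )


def cobinding_correlation(
    factor_a: Sequence[AllelicCount],
    factor_b: Sequence[AllelicCount],
    method: str = "pearson",
    min_coverage: int = 5,
) -> dict:
    """Correlation of allele frequencies of two factors at shared sites.

    Only sites present for both factors with at least ``min_coverage``
    reads in each enter the correlation.  Pearson by default; Spearman
    available.  Symmetric in its two arguments.
    """
    fa = {c.site_id: c for c in factor_a if c.total >= min_coverage}
    fb = {c.site_id: c for c in factor_b if c.total >= min_coverage}
    shared = sorted(set(fa) & set(fb))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared sites with sufficient coverage")
    xa = np.array([allele_frequency(fa[s]) for s in shared])
    xb = np.array([allele_frequency(fb[s]) for s in shared])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("allele frequencies are constant; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(xa, xb)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, xb)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "pvalue": float(p), "n": len(shared)}


def group_shift_test(
    anchor: Sequence[AllelicCount],
    target: Sequence[AllelicCount],
    alpha: float = 0.05,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Does the target factor share the anchor factor's allelic preference?

    Shared sites are grouped by the anchor's bias class; the target's
    allele frequencies in each biased group are compared against the
    unbiased group with a one-sided Wilcoxon rank-sum test — greater-sided
    for reference-preferring anchors, less-sided for alternate-preferring.
    Groups with fewer than 2 sites are skipped and flagged.
    """
    anchor_by_site = {c.site_id: c for c in anchor if c.total >= min_coverage}
    target_by_site = {c.site_id: c for c in target if c.total >= min_coverage}
    shared = set(anchor_by_site) & set(target_by_site)
    groups: dict[str, list[float]] = {b: [] for b in BIAS_CLASSES}
    for s in shared:
        label, _ = classify_bias(anchor_by_site[s], alpha)
        groups[label].append(allele_frequency(target_by_site[s]))
    neutral = np.asarray(groups[BIAS_NONE])
    rows = []
    for biased_class, alternative in ((BIAS_REF, "greater"), (BIAS_ALT, "less")):
        vals = np.asarray(groups[biased_class])
        if vals.size < 2 or neutral.size < 2:
            rows.append(
                {
                    "anchor_class": biased_class,
                    "n_biased": vals.size,
                    "n_neutral": neutral.size,
                    "alternative": alternative,
                    "pvalue": np.nan,
                    "skipped": True,
                }
            )
            continue
        p = stats.mannwhitneyu(vals, neutral, alternative=alternative).pvalue
        rows.append(
            {
                "anchor_class": biased_class,
                "n_biased": vals.size,
                "n_neutral": neutral.size,
                "alternative": alternative,
                "pvalue": float(p),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows)


def read_counts_table(path) -> list[AllelicCount]:
    """Read a TSV with columns site_id, factor, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t")
    return [
        AllelicCount(int(r.site_id), str(r.factor), int(r.ref_count), int(r.alt_count))
        for r in df.itertuples()
    ]


def write_counts_table(counts: Sequence[AllelicCount], path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": c.site_id,
                "factor": c.factor,
                "ref_count": c.ref_count,
                "alt_count": c.alt_count,
            }
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)
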