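"""Combinatorial occupancy classification and category-level comparisons.

Peaks from several factors (canonically TOP2B, CTCF and RAD21) are pooled
and merged wherever they overlap by at least 1 bp; each merged region is
labelled with the set of factors contributing a peak.  Regions carrying all
three factors are "triple sites", regions with exactly two are "double
sites".  The category table tallies all 2^k - 1 non-empty factor subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, Peak, Read, merge_overlapping, rpkm


def class_label(members: frozenset) -> str:
    return "+".join(sorted(members))


@dataclass
class OccupancySite:
    region: GenomicInterval
    members: frozenset
    member_peaks: dict = field(default_factory=dict)  # factor -> list[Peak]

    @property
    def label(self) -> str:
        return class_label(self.members)


def classify_occupancy(
    peaks_by_factor: Mapping[str, Sequence[Peak]],
) -> tuple[list[OccupancySite], dict[str, int]]:
    """Merge pooled peaks and classify each merged region by its occupants.

    Returns the merged sites and a category table mapping class label
    (e.g. ``"CTCF+RAD21+TOP2B"``) to the number of merged regions in that
    class.  The table is invariant under the order factors are supplied in.
    """
    if len(peaks_by_factor) < 2:
        raise ValueError("need at least 2 factors to classify co-occupancy")
    for factor, peaks in peaks_by_factor.items():
        if not peaks:
            warnings.warn(f"factor {factor!r} has no peaks; retained with zero sites")
    pooled: list[GenomicInterval] = []
    labels: list[str] = []
    peak_of: list[Peak] = []
    for factor, peaks in peaks_by_factor.items():
        for p in peaks:
            pooled.append(p.interval)
            labels.append(factor)
            peak_of.append(p)
    merged = merge_overlapping(pooled, labels)
    sites = [
        OccupancySite(m.interval, m.labels, {f: [] for f in m.labels}) for m in merged
    ]
    # assign each source peak to the merged region containing it
    starts_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, site in enumerate(sites):
        starts_by_chrom.setdefault(site.region.chrom, []).append(
            (site.region.start, idx)
        )
    lookup = {
        chrom: (np.array([s for s, _ in sorted(v)]), [i for _, i in sorted(v)])
        for chrom, v in starts_by_chrom.items()
    }
    for factor, peak in zip(labels, peak_of):
        starts, order = lookup[peak.chrom]
        j = int(np.searchsorted(starts, peak.interval.start, side="right")) - 1
        site = sites[order[j]]
        site.member_peaks[factor].append(peak)
    table: dict[str, int] = {}
    for site in sites:
        table[site.label] = table.get(site.label, 0) + 1
    return sites, table


def _overlap_counts(reads: Sequence[Read]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome sorted start/end arrays for O(log n) overlap counting."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append((r.interval.start, r.interval.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        starts = np.sort(np.array([s for s, _ in pairs]))
        ends = np.sort(np.array([e for _, e in pairs]))
        out[chrom] = (starts, ends)
    return out


def count_overlapping_reads(
    index: dict[str, tuple[np.ndarray, np.ndarray]], region: GenomicInterval
) -> int:
    """Number of reads overlapping the region by >= 1 bp."""
    if region.chrom not in index:
        return 0
    starts, ends = index[region.chrom]
    return int(
        np.searchsorted(starts, region.end, side="left")
        - np.searchsorted(ends, region.start, side="right")
    )


def intensity_by_category(
    sites: Sequence[OccupancySite],
    reads_by_factor: Mapping[str, Sequence[Read]],
    library_sizes: Mapping[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak RPKM grouped by occupancy class, with pairwise class tests.

    For every factor, each original peak's RPKM is computed from the reads
    overlapping its peak region; classes are then compared pairwise with a
    one-sided Wilcoxon rank-sum test in the direction of the larger median,
    Benjamini-Hochberg adjusted within each factor's family of tests.
    Fold changes are ratios of class medians.
    """
    indices = {f: _overlap_counts(reads) for f, reads in reads_by_factor.items()}
    rows = []
    for site in sites:
        for factor, peaks in site.member_peaks.items():
            if factor not in indices:
                continue
            for peak in peaks:
                n = count_overlapping_reads(indices[factor], peak.interval)
                rows.append(
                    {
                        "factor": factor,
                        "occupancy_class": site.label,
                        "rpkm": rpkm(n, len(peak.interval), library_sizes[factor]),
                    }
                )
    values = pd.DataFrame(rows)
    tests = []
    for factor, sub in values.groupby("factor"):
        groups = {c: g["rpkm"].to_numpy() for c, g in sub.groupby("occupancy_class")}
        pvals, recs = [], []
        for a, b in combinations(sorted(groups), 2):
            xa, xb = groups[a], groups[b]
            med_a, med_b = np.median(xa), np.median(xb)
            fold = med_a / med_b if med_b > 0 else np.inf
            if len(xa) < 2 or len(xb) < 2:
                recs.append((a, b, fold, np.nan, True))
                pvals.append(np.nan)
                continue
            hi, lo = (xa, xb) if med_a >= med_b else (xb, xa)
            p = stats.mannwhitneyu(hi, lo, alternative="greater").pvalue
            recs.append((a, b, fold, p, False))
            pvals.append(p)
        finite = [p for p in pvals if np.isfinite(p)]
        adj_iter = iter(multipletests(finite, method="fdr_bh")[1] if finite else [])
        for (a, b, fold, p, skipped), raw in zip(recs, pvals):
            tests.append(
                {
                    "factor": factor,
                    "class_a": a,
                    "class_b": b,
                    "median_fold_change": fold,
                    "pvalue": p,
                    "pvalue_bh": next(adj_iter) if np.isfinite(raw) else np.nan,
                    "skipped": skipped,
                }
            )
    return values, pd.DataFrame(tests)


def overlap_enrichment_test(
    query: Sequence[Peak | GenomicInterval],
    reference: Sequence[Peak | GenomicInterval],
    workspace: Sequence[GenomicInterval],
    n_sim: int = 1000,
    seed: int = 0,
) -> dict:
    """Randomisation test for overlap between two region sets.

    The observed statistic is the fraction of query regions overlapping at
    least one reference region.  The null re-places each query region
    (length preserved) uniformly within the workspace ``n_sim`` times; the
    empirical p-value is ``(1 + #{null >= observed}) / (n_sim + 1)``.
    The null is uniform placement — no mappability or isochore matching.
    """
    q_iv = [x.interval if isinstance(x, Peak) else x for x in query]
    r_iv = [x.interval if isinstance(x, Peak) else x for x in reference]
    ws = sorted(workspace, key=lambda iv: (iv.chrom, iv.start))
    ws_lengths = np.array([len(iv) for iv in ws])
    ws_starts = np.array([iv.start for iv in ws])
    ws_chroms = [iv.chrom for iv in ws]
    if ws_lengths.sum() < sum(len(iv) for iv in q_iv):
        raise ValueError("workspace smaller than total query length")

    ref_index = (
        _overlap_counts(
            [Read(GenomicInterval(iv.chrom, iv.start, iv.end, "+")) for iv in r_iv]
        )
        if r_iv
        else {}
    )

    def frac_overlapping(intervals: Sequence[GenomicInterval]) -> float:
        if not intervals:
            return 0.0
        n = sum(
            1 for iv in intervals if ref_index and count_overlapping_reads(ref_index, iv) > 0
        )
        return n / len(intervals)

    observed = frac_overlapping(q_iv)
    rng = np.random.default_rng(seed)
    q_lengths = np.array([len(iv) for iv in q_iv])
    # vectorised null: per query length, draw a workspace segment (weighted
    # by the room it leaves) and a start for every simulation at once
    chrom_set = sorted(set(ws_chroms))
    chrom_idx = np.array([chrom_set.index(c) for c in ws_chroms])
    hit_counts = np.zeros(n_sim, dtype=int)
    for L in q_lengths:
        room = np.maximum(ws_lengths - L + 1, 0)
        total = room.sum()
        if total == 0:
            raise ValueError(f"no workspace segment can hold a query of length {L}")
        seg = rng.choice(len(ws), size=n_sim, p=room / total)
        starts = ws_starts[seg] + rng.integers(0, room[seg])
        ends = starts + int(L)
        overlaps = np.zeros(n_sim, dtype=bool)
        for ci, chrom in enumerate(chrom_set):
            mask = chrom_idx[seg] == ci
            if not mask.any() or chrom not in ref_index:
                continue
            r_starts, r_ends = ref_index[chrom]
            overlaps[mask] = (
                np.searchsorted(r_starts, ends[mask], side="left")
                - np.searchsorted(r_ends, starts[mask], side="right")
            ) > 0
        hit_counts += overlaps
    null = hit_counts / max(len(q_lengths), 1)
    pvalue = (1 + int((null >= observed).sum())) / (n_sim + 1)
    return {
        "observed_fraction": observed,
        "null_mean": float(null.mean()),
        "null_fractions": null,
        "pvalue": float(pvalue),
    }


def constitutive_classification(
    peaks: Sequence[Peak],
    tissue_peak_sets: Mapping[str, Sequence[GenomicInterval]],
    threshold: int = 7,
) -> pd.DataFrame:
    """Count, per peak, the tissues whose peak set it overlaps.

    A peak is "constitutive" when it is shared in strictly more than
    ``threshold`` tissues (the > 7 rule: exactly 7 is not constitutive).
    """
    if not tissue_peak_sets:
        raise ValueError("need at least one tissue peak set")
    indices = {
        t: _overlap_counts([Read(GenomicInterval(iv.chrom, iv.start, iv.end, "+")) for iv in ivs])
        for t, ivs in tissue_peak_sets.items()
    }
    rows = []
    for peak in peaks:
        n = sum(
            1
            for t in indices
            if count_overlapping_reads(indices[t], peak.interval) > 0
        )
        rows.append({"sharing_count": n, "constitutive": n > threshold})
    return pd.DataFrame(rows)


def fisher_2x2(a_pos: int, a_neg: int, b_pos: int, b_neg: int, alternative="two-sided"):
    """Fisher exact test on [[a_pos, a_neg], [b_pos, b_neg]]."""
    odds, p = stats.fisher_exact([[a_pos, a_neg], [b_pos, b_neg]], alternative=alternative)
    return float(odds), float(p)


PHYLO_CATEGORIES = ("Mouse only", "Rodents only", "Beyond rodents")


def phylo_category(rat: bool, human: bool, dog: bool) -> str:
    """Phylogenetic sharing category of a mouse peak.

    "Beyond rodents" when shared with at least one non-rodent (human or
    dog), "Rodents only" when shared with rat alone, else "Mouse only".
    """
    if human or dog:
        return "Beyond rodents"
    if rat:
        return "Rodents only"
    return "Mouse only"


def phylo_category_counts(
    flags: pd.DataFrame, class_column: str = "occupancy_class"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate phylogenetic categories per occupancy class.

    ``flags`` needs boolean columns ``rat``, ``human``, ``dog`` plus a class
    label column.  Pairwise Fisher exact tests compare the Beyond-rodents
    fraction between classes.
    """
    cats = [
        phylo_category(r, h, d)
        for r, h, d in zip(flags["rat"], flags["human"], flags["dog"])
    ]
    df = flags.assign(category=pd.Categorical(cats, categories=PHYLO_CATEGORIES))
    counts = (
        df.groupby([class_column, "category"], observed=False)
        .size()
        .unstack(fill_value=0)
    )
    tests = []
    for a, b in combinations(counts.index, 2):
        a_pos = int(counts.loc[a, "Beyond rodents"])
        a_neg = int(counts.loc[a].sum() - a_pos)
        b_pos = int(counts.loc[b, "Beyond rodents"])
        b_neg = int(counts.loc[b].sum() - b_pos)
        odds, p = fisher_2x2(a_pos, a_neg, b_pos, b_neg)
        tests.append(
            {"class_a": a, "class_b": b, "odds_ratio": odds, "pvalue": p}
        )
    return counts, pd.DataFrame(tests)


def summit_repeat_filter(
    peaks: Sequence[Peak], repeats: Sequence[GenomicInterval]
) -> list[Peak]:
    """Retain exactly the peaks whose summit base lies inside a repeat."""
    # collapse repeats to disjoint coverage so a single binary search suffices
    merged = merge_overlapping(list(repeats))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in merged:
        by_chrom.setdefault(m.interval.chrom, []).append(
            (m.interval.start, m.interval.end)
        )
    index = {
        chrom: (
            np.array([s for s, _ in v]),
            np.array([e for _, e in v]),
        )
        for chrom, v in by_chrom.items()
    }
    kept = []
    for p in peaks:
        if p.chrom not in index:
            continue
        starts, ends = index[p.chrom]
        j = int(np.searchsorted(starts, p.summit, side="right")) - 1
        if j >= 0 and p.summit < ends[j]:
            kept.append(p)
    return kept
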