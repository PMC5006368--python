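"""Core genomic coordinate types and interval algebra.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` base pairs.  Strand is one of
``"+"``, ``"-"`` or ``"."`` (unstranded).  Everything downstream — peak
merging, motif-oriented offsets, 5'-end pileups — builds on the types here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called binding region with a single-bp summit and a signal value.

    ``summit`` is an absolute coordinate and must lie inside the interval;
    ``factor`` labels the immunoprecipitated protein (e.g. TOP2B, CTCF,
    RAD21).
    """

    interval: GenomicInterval
    summit: int
    signal: float = 0.0
    factor: str = ""
    name: str = "."

    def __post_init__(self) -> None:
        if not self.interval.start <= self.summit < self.interval.end:
            raise ValueError(
                f"summit {self.summit} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.signal < 0:
            raise ValueError("signal must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class Read:
    """A mapped sequencing tag; always stranded."""

    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("reads must be stranded (+ or -)")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def five_prime(self) -> int:
        """Position of the read's 5' nucleotide (strand-aware)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass(frozen=True)
class MergedRegion:
    """A merged interval annotated with the labels of its source intervals."""

    interval: GenomicInterval
    labels: frozenset = field(default_factory=frozenset)
    n_sources: int = 0


def merge_overlapping(
    intervals: Sequence[GenomicInterval],
    labels: Sequence[str] | None = None,
) -> list[MergedRegion]:
    """Merge intervals connected by chains of >= 1 bp pairwise overlaps.

    Book-ended (abutting) intervals are *not* merged: ``[100,200)`` and
    ``[200,300)`` stay separate, since they share no base.  Output is sorted
    and pairwise disjoint; each merged region carries the set of labels of
    the intervals it absorbed.
    """
    if labels is not None and len(labels) != len(intervals):
        raise ValueError("labels must match intervals in length")
    if not intervals:
        return []
    items = sorted(
        range(len(intervals)),
        key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end),
    )
    out: list[MergedRegion] = []
    cur_chrom = intervals[items[0]].chrom
    cur_start = intervals[items[0]].start
    cur_end = intervals[items[0]].end
    cur_labels = {labels[items[0]]} if labels is not None else set()
    cur_n = 1
    for i in items[1:]:
        iv = intervals[i]
        # strict overlap required: iv.start == cur_end means book-ended
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
            if labels is not None:
                cur_labels.add(labels[i])
            cur_n += 1
        else:
            out.append(
                MergedRegion(
                    GenomicInterval(cur_chrom, cur_start, cur_end),
                    frozenset(cur_labels),
                    cur_n,
                )
            )
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            cur_labels = {labels[i]} if labels is not None else set()
            cur_n = 1
    out.append(
        MergedRegion(
            GenomicInterval(cur_chrom, cur_start, cur_end),
            frozenset(cur_labels),
            cur_n,
        )
    )
    return out


def rpkm(read_count: float, region_length: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return read_count / ((region_length / 1e3) * (library_size / 1e6))


@dataclass
class GenomeBins:
    """Fixed-width genome binning of read counts, keyed by (chrom, bin)."""

    bin_size: int = 10_000
    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @classmethod
    def from_reads(cls, reads: Iterable[Read], bin_size: int = 10_000) -> "GenomeBins":
        bins = cls(bin_size=bin_size)
        for r in reads:
            key = (r.chrom, r.five_prime() // bin_size)
            bins.counts[key] = bins.counts.get(key, 0) + 1
        return bins


def binned_track_correlation(a: GenomeBins, b: GenomeBins) -> float:
    """Spearman rank correlation of two binned read tracks.

    The comparison runs over the union of occupied bins; a bin absent from
    one track counts 0 there.  Requires identical bin grids.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("bin grids differ")
    keys = sorted(set(a.counts) | set(b.counts))
    if len(keys) < 3:
        raise ValueError("need at least 3 shared bins")
    va = np.array([a.counts.get(k, 0) for k in keys], dtype=float)
    vb = np.array([b.counts.get(k, 0) for k in keys], dtype=float)
    rho, _ = stats.spearmanr(va, vb)
    return float(rho)


def filter_blacklist(
    items: Sequence[Peak | Read | GenomicInterval],
    blacklist: Sequence[GenomicInterval],
) -> list:
    """Drop items whose interval overlaps any excluded region by >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    kept = []
    for item in items:
        iv = item if isinstance(item, GenomicInterval) else item.interval
        hit = False
        for s, e in by_chrom.get(iv.chrom, ()):
            if s >= iv.end:
                break
            if iv.start < e and s < iv.end:
                hit = True
                break
        if not hit:
            kept.append(item)
    return kept


def reflect_interval(iv: GenomicInterval, genome_length: int) -> GenomicInterval:
    """Mirror an interval through the midpoint of a chromosome of given length."""
    flip = {"+": "-", "-": "+", ".": "."}
    return replace(
        iv,
        start=genome_length - iv.end,
        end=genome_length - iv.start,
        strand=flip[iv.strand],
    )
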