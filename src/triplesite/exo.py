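"""Base-pair-resolution 5'-end pileups around oriented motifs (ChIP-exo).

Lambda-exonuclease digestion stops at protein-DNA crosslinks, so the 5'
ends of ChIP-exo reads pile up at protection boundaries.  Profiles here
count read 5' ends at each offset in a +/-50 bp window around oriented
CTCF motif centers, separately per strand, averaged over regions.

Strand semantics under a minus-oriented motif: offsets are mirrored AND
the strand labels are swapped, so "forward" always means the top strand in
the motif's own G-rich reading direction.  A statement like "reverse-strand
protection at -27..-13" is then independent of which genomic strand the
motif sits on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, Read
from .motifs import (
    MarkovBackground,
    MotifMatrix,
    OrientedSite,
    best_hit_in_region,
    best_hit_per_region,
    permute_matrix,
    scan,
    score_distribution,
)


def five_prime_position(read: Read) -> int:
    """Absolute position of the read's 5' nucleotide (strand-aware)."""
    return read.five_prime()


@dataclass
class ExoProfile:
    """Average 5'-end counts per oriented offset, one array per strand."""

    forward: np.ndarray
    reverse: np.ndarray
    n_regions: int
    flank: int = 50

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def total_ends(self) -> float:
        """Total number of 5' ends across retained windows (both strands)."""
        return float((self.forward + self.reverse).sum() * self.n_regions)


def _five_prime_index(
    reads: Sequence[Read],
) -> dict[tuple[str, str], np.ndarray]:
    """Sorted 5'-end positions keyed by (chrom, strand)."""
    buckets: dict[tuple[str, str], list[int]] = {}
    for r in reads:
        buckets.setdefault((r.chrom, r.strand), []).append(r.five_prime())
    return {k: np.sort(np.array(v)) for k, v in buckets.items()}


def exo_profile(
    reads: Sequence[Read],
    sites: Sequence[OrientedSite],
    flank: int = 50,
    min_reads: int = 10,
) -> ExoProfile:
    """Strand-resolved average 5'-end pileup around oriented motif centers.

    Sites with fewer than ``min_reads`` 5' ends inside the +/-flank window
    (both strands combined) are discarded before averaging, following the
    rule that regions with too few exo reads carry no footprint signal.
    Averages are total counts divided by the number of retained regions.
    """
    index = _five_prime_index(reads)
    width = 2 * flank + 1
    fwd = np.zeros(width)
    rev = np.zeros(width)
    n_regions = 0
    for site in sites:
        window: dict[str, np.ndarray] = {}
        total = 0
        for strand in ("+", "-"):
            pos = index.get((site.chrom, strand))
            if pos is None:
                window[strand] = np.empty(0, dtype=int)
                continue
            lo = np.searchsorted(pos, site.center - flank, side="left")
            hi = np.searchsorted(pos, site.center + flank, side="right")
            window[strand] = pos[lo:hi]
            total += hi - lo
        if total < min_reads:
            continue
        n_regions += 1
        for strand in ("+", "-"):
            offs = window[strand] - site.center
            if site.orientation == "-":
                offs = -offs
                target = rev if strand == "+" else fwd
            else:
                target = fwd if strand == "+" else rev
            np.add.at(target, offs + flank, 1)
    if n_regions == 0:
        raise ValueError(
            f"no site retained >= {min_reads} reads within +/-{flank} bp "
            "(min_reads filter)"
        )
    return ExoProfile(fwd / n_regions, rev / n_regions, n_regions, flank)


@dataclass
class BackgroundEnvelope:
    """Per-offset, per-strand summary of profiles under permuted motifs."""

    mean_forward: np.ndarray
    mean_reverse: np.ndarray
    sd_forward: np.ndarray
    sd_reverse: np.ndarray
    min_forward: np.ndarray
    min_reverse: np.ndarray
    max_forward: np.ndarray
    max_reverse: np.ndarray
    n_permutations: int
    flank: int = 50


def permuted_background(
    reads: Sequence[Read],
    peak_regions: Sequence[GenomicInterval],
    matrix: MotifMatrix,
    sequences: Mapping[str, str],
    n_perm: int = 10,
    seed: int = 0,
    flank: int = 50,
    min_reads: int = 10,
    pvalue_threshold: float = 1e-4,
    exclude_original_overlap: bool = True,
) -> BackgroundEnvelope:
    """Profile envelope from motifs whose matrix columns were shuffled.

    Each permutation reorders the motif columns (sequence composition
    preserved), re-scans the peak regions, re-orients on the best permuted
    hit per region, and re-profiles the same reads.  Permutations yielding
    no oriented site (or none surviving the read filter) are dropped with
    a warning.

    With ``exclude_original_overlap`` (the default), permuted hits whose
    interval overlaps the region's best *original* motif hit are ignored.
    A motif whose consensus repeats letters can be re-found at a small
    shift by a column permutation; such hits re-centre windows on the real
    footprint and contaminate the background with shifted signal.  The
    background is meant to measure sequence-composition effects away from
    the motif, so those self-matches are excluded.  Disable to reproduce
    the plain permuted-matrix control.
    """
    region_seqs = {}
    for region in peak_regions:
        seq = sequences[region.chrom][region.start : region.end]
        region_seqs[region] = seq
    background = MarkovBackground.estimate(list(region_seqs.values()), order=1)
    original_hit: dict = {}
    if exclude_original_overlap:
        dist0 = score_distribution(matrix, background)
        for region, seq in region_seqs.items():
            hits = scan(
                seq,
                matrix,
                background=background,
                pvalue_threshold=pvalue_threshold,
                chrom=region.chrom,
                offset=region.start,
                _dist=dist0,
            )
            original_hit[region] = best_hit_in_region(region, hits)
    profiles = []
    rng = np.random.default_rng(seed)
    for i in range(n_perm):
        pm = permute_matrix(matrix, int(rng.integers(2**31)))
        dist = score_distribution(pm, background)
        sites = []
        for region, seq in region_seqs.items():
            hits = scan(
                seq,
                pm,
                background=background,
                pvalue_threshold=pvalue_threshold,
                chrom=region.chrom,
                offset=region.start,
                _dist=dist,
            )
            orig = original_hit.get(region)
            if orig is not None:
                hits = [h for h in hits if not h.interval.overlaps(orig.interval)]
            site = best_hit_per_region(region, hits)
            if site is not None:
                sites.append(site)
        if not sites:
            warnings.warn(f"permutation {i}: no motif hits; dropped")
            continue
        try:
            profiles.append(exo_profile(reads, sites, flank=flank, min_reads=min_reads))
        except ValueError:
            warnings.warn(f"permutation {i}: no region survived read filter; dropped")
    if not profiles:
        raise ValueError("all permutations dropped; cannot build background")
    fwd = np.stack([p.forward for p in profiles])
    rev = np.stack([p.reverse for p in profiles])
    return BackgroundEnvelope(
        mean_forward=fwd.mean(axis=0),
        mean_reverse=rev.mean(axis=0),
        sd_forward=fwd.std(axis=0, ddof=0),
        sd_reverse=rev.std(axis=0, ddof=0),
        min_forward=fwd.min(axis=0),
        min_reverse=rev.min(axis=0),
        max_forward=fwd.max(axis=0),
        max_reverse=rev.max(axis=0),
        n_permutations=len(profiles),
        flank=flank,
    )


@dataclass(frozen=True)
class FootprintCall:
    """A contiguous run of offsets with protection above background."""

    strand: str  # "forward" or "reverse" (motif-oriented)
    start_offset: int  # inclusive
    end_offset: int  # inclusive


def call_footprints(
    observed: ExoProfile,
    background: BackgroundEnvelope,
    k: float = 3.0,
    min_run: int = 3,
) -> list[FootprintCall]:
    """Maximal runs of offsets where observed exceeds mean + k*sd background.

    Runs shorter than ``min_run`` offsets are discarded — an isolated
    single-bp spike is not a protection footprint.
    """
    if observed.flank != background.flank:
        raise ValueError("observed and background flanks differ")
    calls = []
    for strand, obs, mean, sd in (
        ("forward", observed.forward, background.mean_forward, background.sd_forward),
        ("reverse", observed.reverse, background.mean_reverse, background.sd_reverse),
    ):
        above = obs > mean + k * sd
        offsets = observed.offsets
        start = None
        for i, flag in enumerate(np.append(above, False)):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start >= min_run:
                    calls.append(
                        FootprintCall(strand, int(offsets[start]), int(offsets[i - 1]))
                    )
                start = None
    return calls
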