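"""Motif-oriented distance statistics, factor ordering and TAD positions.

All offsets are signed base-pair distances from the CTCF core motif center
after orienting every motif to its G-rich direction: negative offsets lie
5' of the motif, positive offsets 3'.  On this axis the canonical spatial
arrangement of a triple site is TOP2B (5', around -15 bp), the CTCF summit
near the motif, and RAD21 (3', around +12 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, Peak
from .motifs import OrientedSite

CANONICAL_ORDER = "TOP2B-CTCF-RAD21"
DEFAULT_FLANK = 100  # bp window around the motif center for ordering


def oriented_distance(summit: int, site: OrientedSite) -> int:
    """Signed offset of a summit from the motif center, in motif orientation.

    For a + oriented motif this is ``summit - center``; for a - oriented
    motif the axis flips, giving ``center - summit``.
    """
    if site.orientation == "+":
        return summit - site.center
    return site.center - summit


@dataclass(frozen=True)
class OrientedOffsets:
    """Per-site signed summit offsets for each factor, plus raw offsets."""

    site_id: int
    offsets: Mapping[str, int]  # oriented
    raw_offsets: Mapping[str, int]  # summit - center on the genome + strand


def site_offsets(
    site_id: int,
    site: OrientedSite,
    summits: Mapping[str, int],
    flank: int | None = DEFAULT_FLANK,
) -> OrientedOffsets | None:
    """Oriented and raw offsets of each factor's summit at one motif site.

    Returns None when any factor's summit falls outside ``flank`` bp of
    the motif center (such sites are excluded from ordering analyses and
    counted by the caller); pass ``flank=None`` to disable the window.
    """
    oriented = {f: oriented_distance(s, site) for f, s in summits.items()}
    raw = {f: s - site.center for f, s in summits.items()}
    if flank is not None and any(abs(o) > flank for o in oriented.values()):
        return None
    return OrientedOffsets(site_id, oriented, raw)


def distance_summaries(offset_sets: Sequence[OrientedOffsets]) -> pd.DataFrame:
    """Median/quartile summaries of summit offsets per factor.

    Reported both after orientation (signed offsets on the G-rich axis) and
    before (raw ``summit - center`` on the genome's + strand for every
    site, regardless of motif strand).
    """
    if not offset_sets:
        raise ValueError("need at least one site")
    rows = []
    factors = sorted({f for o in offset_sets for f in o.offsets})
    for factor in factors:
        for label, getter in (
            ("oriented", lambda o: o.offsets),
            ("unoriented", lambda o: o.raw_offsets),
        ):
            vals = np.array(
                [getter(o)[factor] for o in offset_sets if factor in getter(o)],
                dtype=float,
            )
            rows.append(
                {
                    "factor": factor,
                    "mode": label,
                    "n": vals.size,
                    "median": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                }
            )
    return pd.DataFrame(rows)


def offsets_long_table(offset_sets: Sequence[OrientedOffsets]) -> pd.DataFrame:
    """Long-format (site, factor, mode, offset) table for violin plots."""
    rows = []
    for o in offset_sets:
        for factor, v in o.offsets.items():
            rows.append(
                {"site_id": o.site_id, "factor": factor, "mode": "oriented", "offset": v}
            )
        for factor, v in o.raw_offsets.items():
            rows.append(
                {
                    "site_id": o.site_id,
                    "factor": factor,
                    "mode": "unoriented",
                    "offset": v,
                }
            )
    return pd.DataFrame(rows)


def classify_order(
    offsets: Mapping[str, float], factors: Sequence[str] = ("TOP2B", "CTCF", "RAD21")
) -> tuple[str, bool]:
    """Ordering label of the factors along the oriented axis.

    Factors are sorted by ascending signed offset; exact ties break
    alphabetically and set the tie flag.  Returns ``("A-B-C", tied)``.
    """
    missing = [f for f in factors if f not in offsets]
    if missing:
        raise ValueError(f"missing offsets for {missing}")
    ordered = sorted(factors, key=lambda f: (offsets[f], f))
    values = [offsets[f] for f in factors]
    tied = len(set(values)) < len(values)
    return "-".join(ordered), tied


def order_counts(
    offset_sets: Sequence[OrientedOffsets],
    factors: Sequence[str] = ("TOP2B", "CTCF", "RAD21"),
    mode: str = "oriented",
) -> dict[str, int]:
    """Counts of each of the 6 orderings over sites, oriented or raw."""
    counts: dict[str, int] = {}
    for o in offset_sets:
        source = o.offsets if mode == "oriented" else o.raw_offsets
        label, _ = classify_order(source, factors)
        counts[label] = counts.get(label, 0) + 1
    return counts


def order_enrichment(
    orderings_before: Mapping[str, int],
    orderings_after: Mapping[str, int],
    canonical: str = CANONICAL_ORDER,
) -> dict:
    """Compare the canonical-order fraction before vs after orientation.

    Fisher exact test on the 2x2 table (canonical vs non-canonical) x
    (before vs after).  "Before" means raw genomic offsets ignoring motif
    strand; "after" means offsets on the G-rich axis.
    """
    n_before = sum(orderings_before.values())
    n_after = sum(orderings_after.values())
    if n_before == 0 or n_after == 0:
        raise ValueError("ordering counts must be non-empty")
    canon_b = orderings_before.get(canonical, 0)
    canon_a = orderings_after.get(canonical, 0)
    odds, p = stats.fisher_exact(
        [[canon_a, n_after - canon_a], [canon_b, n_before - canon_b]]
    )
    return {
        "canonical": canonical,
        "fraction_before": canon_b / n_before,
        "fraction_after": canon_a / n_after,
        "odds_ratio": float(odds),
        "pvalue": float(p),
    }


@dataclass(frozen=True)
class Domain:
    """A topological domain (TAD) interval from Hi-C."""

    interval: GenomicInterval


def relative_domain_position(
    site: OrientedSite | Peak,
    domains: Sequence[Domain],
) -> float | None:
    """Normalized position of a site within its containing domain.

    0 is the 5' border, 1 the 3' border, 0.5 the center: the distance of
    the anchor from the domain center plus half the domain size, divided
    by the size.  The anchor is the motif center for oriented sites and
    the summit for peaks.  Returns None when no domain contains the
    anchor; domains must be disjoint.
    """
    if isinstance(site, Peak):
        chrom, anchor = site.chrom, site.summit
    else:
        chrom, anchor = site.chrom, site.center
    for d in domains:
        if d.interval.contains(chrom, anchor):
            size = len(d.interval)
            center = d.interval.start + size / 2
            return (anchor - center + size / 2) / size
    return None


def border_enrichment(
    positions: Sequence[float], edge: float = 0.1, center_halfwidth: float = 0.05
) -> dict:
    """Edge-vs-center density ratio of relative domain positions.

    Compares per-unit density within ``edge`` of either border against the
    window of the same total width around the domain center.
    """
    pos = np.asarray([p for p in positions if p is not None], dtype=float)
    if pos.size == 0:
        raise ValueError("no positions")
    in_edge = ((pos <= edge) | (pos >= 1 - edge)).mean() / (2 * edge)
    in_center = (
        np.abs(pos - 0.5) <= center_halfwidth
    ).mean() / (2 * center_halfwidth)
    return {
        "edge_density": float(in_edge),
        "center_density": float(in_center),
        "ratio": float(np.inf if in_center == 0 else in_edge / in_center),
        "n": int(pos.size),
    }
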