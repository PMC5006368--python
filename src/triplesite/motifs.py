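"""Position-weight-matrix scanning with Markov backgrounds and exact p-values.

The scanner scores windows as a log2 likelihood ratio between the motif
model and a background Markov model of order 0 or 1 estimated from the
scanned sequences themselves.  Minus-strand hits are scored on the reverse
complement, so scanning a sequence and its reverse complement returns the
same hit set with strands swapped.

P-values are computed under the order-0 marginal of the background by
convolving the per-column score distributions column by column; the
resulting survival function is exact whenever the number of distinct
attainable scores stays below a state cap, and falls back to a rounded
score lattice beyond it.  Order-1 scan scores are looked up in the order-0
distribution — a deliberate approximation, since the exact order-1 null
depends on window context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval

BASES = "ACGT"
_BASE_TO_INT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_TO_INT[ord(_b)] = _i
    _BASE_TO_INT[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integers A=0,C=1,G=2,T=3; anything else -> -1."""
    return _BASE_TO_INT[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def reverse_complement(sequence: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return sequence.translate(table)[::-1]


@dataclass(frozen=True)
class MotifMatrix:
    """A count matrix over A/C/G/T with a pseudocount applied on use."""

    counts: np.ndarray  # shape (width, 4)
    pseudocount: float = 1.0
    name: str = "motif"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (width, 4)")
        if counts.shape[0] < 1:
            raise ValueError("matrix width must be >= 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if ((counts + self.pseudocount).sum(axis=1) <= 0).any():
            raise ValueError("every column must have positive total")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def probabilities(self) -> np.ndarray:
        p = self.counts + self.pseudocount
        return p / p.sum(axis=1, keepdims=True)

    def information_content(self) -> float:
        """Total information content in bits against a uniform background."""
        p = self.probabilities()
        return float((p * np.log2(p / 0.25)).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities().argmax(axis=1))

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(self.counts[::-1, ::-1].copy(), self.pseudocount, self.name)


def permute_matrix(matrix: MotifMatrix, seed: int) -> MotifMatrix:
    """Reorder the matrix columns uniformly at random (seeded).

    Per-column composition — hence total information content — is
    preserved; only the column order changes.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(matrix.width)
    return MotifMatrix(
        matrix.counts[order].copy(), matrix.pseudocount, f"{matrix.name}_perm"
    )


@dataclass(frozen=True)
class MarkovBackground:
    """Order-0 or order-1 background, strand-symmetrised on estimation."""

    marginal: np.ndarray  # (4,)
    transitions: np.ndarray | None = None  # (4,4), rows = previous base

    @property
    def order(self) -> int:
        return 0 if self.transitions is None else 1

    @classmethod
    def uniform(cls) -> "MarkovBackground":
        return cls(np.full(4, 0.25))

    @classmethod
    def estimate(
        cls, sequences: Sequence[str], order: int = 1, pseudocount: float = 1.0
    ) -> "MarkovBackground":
        """Estimate base/transition frequencies from both strands of input."""
        if order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        base_counts = np.full(4, pseudocount)
        trans_counts = np.full((4, 4), pseudocount)
        for seq in sequences:
            enc = encode(seq)
            for arr in (enc, _COMPLEMENT[enc[enc >= 0]][::-1]):
                valid = arr[arr >= 0]
                base_counts += np.bincount(valid, minlength=4)
                if order == 1 and valid.size >= 2:
                    prev, nxt = arr[:-1], arr[1:]
                    ok = (prev >= 0) & (nxt >= 0)
                    np.add.at(trans_counts, (prev[ok], nxt[ok]), 1)
        marginal = base_counts / base_counts.sum()
        if order == 0:
            return cls(marginal)
        transitions = trans_counts / trans_counts.sum(axis=1, keepdims=True)
        return cls(marginal, transitions)


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval  # strand in {+, -}; length == matrix width
    score: float  # log2 likelihood ratio, bits
    pvalue: float


@dataclass(frozen=True)
class OrientedSite:
    """A motif instance reduced to its center and G-rich orientation.

    The orientation defines the positive axis for all signed offsets:
    positive offsets are 3' of the motif in its own reading direction.
    """

    chrom: str
    center: int
    orientation: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be + or -")


class ScoreDistribution:
    """Null distribution of PWM scores under an order-0 background.

    Built by column-wise convolution over distinct attainable scores.  Keys
    are rounded to ``ndigits`` decimals to merge float duplicates (12
    digits keeps cumulative rounding well under the p-value tolerance); if the
    state count exceeds ``max_states`` the keys are coarsened to ``grid``
    (the survival function then carries discretisation error of at most
    width * grid / 2 in score).
    """

    def __init__(
        self,
        column_scores: np.ndarray,
        column_probs: np.ndarray,
        max_states: int = 1 << 17,
        grid: float = 1e-4,
        ndigits: int = 12,
    ) -> None:
        dist = {0.0: 1.0}
        for j in range(column_scores.shape[0]):
            new: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = round(s + column_scores[j, b], ndigits)
                    new[key] = new.get(key, 0.0) + p * column_probs[j, b]
            if len(new) > max_states:
                coarse: dict[float, float] = {}
                for s, p in new.items():
                    key = round(round(s / grid) * grid, ndigits)
                    coarse[key] = coarse.get(key, 0.0) + p
                new = coarse
            dist = new
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        self.scores = scores
        # survival[i] = P(S >= scores[i])
        self.survival = probs[::-1].cumsum()[::-1]

    def pvalue(self, score: float, tol: float = 1e-9) -> float:
        """P(S >= score) with a small tolerance absorbing float noise."""
        idx = np.searchsorted(self.scores, score - tol, side="left")
        if idx >= self.scores.size:
            return 0.0
        return float(min(1.0, self.survival[idx]))

    def score_at_pvalue(self, alpha: float) -> float:
        """Smallest attainable score whose p-value is <= alpha."""
        idx = np.searchsorted(-self.survival, -alpha, side="left")
        if idx >= self.scores.size:
            return math.inf
        return float(self.scores[idx])


def _column_scores(matrix: MotifMatrix, background: MarkovBackground) -> np.ndarray:
    return np.log2(matrix.probabilities() / background.marginal[None, :])


def score_distribution(
    matrix: MotifMatrix, background: MarkovBackground | None = None, **kwargs
) -> ScoreDistribution:
    bg = background or MarkovBackground.uniform()
    probs = np.broadcast_to(bg.marginal, (matrix.width, 4))
    return ScoreDistribution(_column_scores(matrix, bg), np.asarray(probs), **kwargs)


def _window_scores(
    enc: np.ndarray, matrix: MotifMatrix, background: MarkovBackground
) -> np.ndarray:
    """Scores of all windows on the encoded strand; NaN where a window has N."""
    w = matrix.width
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0)
    logp = np.log2(matrix.probabilities())
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows < 0, 0, windows)
    match = logp[np.arange(w), safe].sum(axis=1)
    # background log-likelihood of each window
    logq_marg = np.log2(background.marginal)
    if background.order == 0:
        bg_ll = logq_marg[safe].sum(axis=1)
    else:
        logt = np.log2(background.transitions)
        bg_ll = logq_marg[safe[:, 0]]
        if w > 1:
            bg_ll = bg_ll + logt[safe[:, :-1], safe[:, 1:]].sum(axis=1)
    scores = match - bg_ll
    scores[~valid] = np.nan
    return scores


def scan(
    sequence: str,
    matrix: MotifMatrix,
    background: MarkovBackground | None = None,
    pvalue_threshold: float = 1e-4,
    both_strands: bool = True,
    chrom: str = "seq",
    offset: int = 0,
    markov_order: int = 1,
    _dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan a sequence for motif hits with p-value <= threshold.

    Windows containing non-ACGT characters are skipped.  Minus-strand hits
    are scored on the reverse complement; ``offset`` shifts reported
    coordinates (for scanning sub-regions of a chromosome).
    """
    w = matrix.width
    if len(sequence) < w:
        return []
    bg = background or MarkovBackground.estimate([sequence], order=markov_order)
    dist = _dist or score_distribution(matrix, bg)
    # small slack so float noise at the score cutoff cannot drop true hits;
    # the p-value filter below remains the authoritative test
    min_score = dist.score_at_pvalue(pvalue_threshold) - 1e-9
    hits: list[MotifHit] = []

    enc = encode(sequence)
    fwd = _window_scores(enc, matrix, bg)
    for i in np.flatnonzero(~np.isnan(fwd) & (fwd >= min_score)):
        p = dist.pvalue(fwd[i])
        if p <= pvalue_threshold:
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, offset + int(i), offset + int(i) + w, "+"),
                    float(fwd[i]),
                    p,
                )
            )
    if both_strands:
        L = enc.size
        rc = encode(reverse_complement(sequence))
        rev = _window_scores(rc, matrix, bg)
        for i in np.flatnonzero(~np.isnan(rev) & (rev >= min_score)):
            p = dist.pvalue(rev[i])
            if p <= pvalue_threshold:
                start = L - int(i) - w
                hits.append(
                    MotifHit(
                        GenomicInterval(chrom, offset + start, offset + start + w, "-"),
                        float(rev[i]),
                        p,
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def motif_center(hit_interval: GenomicInterval, width: int) -> int:
    """Center bp of a motif hit: the base just 3' of the midpoint, in motif
    orientation, for even widths; the middle base for odd widths."""
    if hit_interval.strand == "-":
        return hit_interval.start + math.ceil(width / 2) - 1
    return hit_interval.start + width // 2


def best_hit_in_region(
    region: GenomicInterval, hits: Sequence[MotifHit]
) -> MotifHit | None:
    """The highest-scoring hit fully inside a region, or None.

    Ties break to the leftmost genomic start, then + before -.
    """
    inside = [
        h
        for h in hits
        if h.interval.chrom == region.chrom
        and h.interval.start >= region.start
        and h.interval.end <= region.end
    ]
    if not inside:
        return None
    return min(
        inside,
        key=lambda h: (-h.score, h.interval.start, 0 if h.interval.strand == "+" else 1),
    )


def best_hit_per_region(
    region: GenomicInterval, hits: Sequence[MotifHit]
) -> OrientedSite | None:
    """Pick the highest-scoring hit inside a region as its oriented anchor.

    Returns None when no hit falls inside the region (the region is then
    excluded from motif-anchored analyses).
    """
    best = best_hit_in_region(region, hits)
    if best is None:
        return None
    width = len(best.interval)
    return OrientedSite(
        best.interval.chrom, motif_center(best.interval, width), best.interval.strand
    )


def write_hits_bed(hits: Sequence[MotifHit], path) -> None:
    """Write hits as BED6 with score = bits * 100, integer-truncated."""
    with open(path, "w") as fh:
        for h in hits:
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tmotif\t{int(round(h.score * 100))}\t{iv.strand}\n"
            )
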