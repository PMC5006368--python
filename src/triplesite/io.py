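"""Readers and writers for the plain-text genomics formats the pipeline uses.

Supported: BED3/BED6, ENCODE narrowPeak (10 columns, column 10 = summit
offset from start), tagAlign (6 columns), bedGraph, FASTA (via Biopython),
TRANSFAC-style count matrices and simple 4-row count matrices.  All readers
tolerate ``track`` and ``#`` header lines.  Coordinates are kept 0-based
half-open throughout.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, Peak, Read

_HEADER_PREFIXES = ("track", "browser", "#")


def _rows(path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or any(line.startswith(p) for p in _HEADER_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_int(field: str, lineno: int, what: str) -> int:
    try:
        return int(field)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed {what}: {field!r}") from exc


def read_intervals(path, format: str):
    """Read a peak/tag file; returns Peaks (narrowPeak) or Reads/intervals.

    ``format`` is one of ``"bed3"``, ``"bed6"``, ``"narrowPeak"``,
    ``"tagAlign"``.  narrowPeak summit offset ``-1`` maps the summit to the
    interval midpoint (rounded down), since downstream analyses require a
    summit for every peak.
    """
    fmt = format.lower()
    if fmt == "bed3":
        return [
            GenomicInterval(f[0], _parse_int(f[1], ln, "start"), _parse_int(f[2], ln, "end"))
            for ln, f in _rows(path)
        ]
    if fmt == "bed6":
        out = []
        for ln, f in _rows(path):
            if len(f) < 6:
                raise ValueError(f"line {ln}: expected 6 columns, got {len(f)}")
            out.append(
                GenomicInterval(
                    f[0], _parse_int(f[1], ln, "start"), _parse_int(f[2], ln, "end"), f[5]
                )
            )
        return out
    if fmt == "tagalign":
        out = []
        for ln, f in _rows(path):
            if len(f) < 6:
                raise ValueError(f"line {ln}: expected 6 columns, got {len(f)}")
            if f[5] not in ("+", "-"):
                raise ValueError(f"line {ln}: tagAlign strand must be + or -")
            out.append(
                Read(
                    GenomicInterval(
                        f[0], _parse_int(f[1], ln, "start"), _parse_int(f[2], ln, "end"), f[5]
                    )
                )
            )
        return out
    if fmt == "narrowpeak":
        out = []
        for ln, f in _rows(path):
            if len(f) < 10:
                raise ValueError(f"line {ln}: expected 10 columns, got {len(f)}")
            start = _parse_int(f[1], ln, "start")
            end = _parse_int(f[2], ln, "end")
            offset = _parse_int(f[9], ln, "summit offset")
            if offset == -1:
                summit = start + (end - start) // 2
            else:
                summit = start + offset
                if not start <= summit < end:
                    raise ValueError(f"line {ln}: summit {summit} outside [{start}, {end})")
            strand = f[5] if f[5] in ("+", "-") else "."
            out.append(
                Peak(
                    GenomicInterval(f[0], start, end, strand),
                    summit=summit,
                    signal=float(f[6]),
                    name=f[3],
                )
            )
        return out
    raise ValueError(f"unknown format {format!r}")


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.name or p.factor or ".",
                        "0",
                        iv.strand if iv.strand != "." else ".",
                        f"{p.signal:g}",
                        "-1",
                        "-1",
                        str(p.summit - iv.start),
                    ]
                )
                + "\n"
            )


def write_tagalign(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tN\t1000\t{iv.strand}\n"
            )


def write_bed(intervals: Iterable[GenomicInterval], path, names=None) -> None:
    intervals = list(intervals)
    if names is None:
        names = ["."] * len(intervals)
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_bedgraph(track: Mapping[str, np.ndarray], path) -> None:
    """Write per-bp value arrays as a run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            values = np.asarray(track[chrom])
            if values.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [values.size]])
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_transfac_matrix(path_or_text) -> np.ndarray:
    """Parse a TRANSFAC count matrix into a (width, 4) A/C/G/T array.

    Accepts a path or the matrix text itself.  Rows between the ``P0``
    header and ``//`` (or ``XX``) hold one motif column each: an index
    followed by four counts.
    """
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    rows = []
    in_matrix = False
    for line in _io.StringIO(text):
        fields = line.split()
        if not fields:
            continue
        if fields[0].upper() == "P0":
            in_matrix = True
            continue
        if fields[0] in ("//", "XX"):
            in_matrix = False
            continue
        if in_matrix and fields[0].lstrip("0").isdigit() or (in_matrix and fields[0] == "0"):
            rows.append([float(x) for x in fields[1:5]])
    if not rows:
        raise ValueError("no matrix rows found (missing P0 header?)")
    return np.array(rows, dtype=float)


def read_counts_matrix(path) -> np.ndarray:
    """Read a simple 4-row (A/C/G/T) count matrix, rows optionally labelled."""
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith(("#", ">")):
                continue
            if fields[0].upper().rstrip(":|") in "ACGT" and len(fields[0]) <= 2:
                fields = fields[1:]
            rows.append([float(x) for x in fields])
    if len(rows) != 4:
        raise ValueError(f"expected 4 rows (A,C,G,T), got {len(rows)}")
    return np.array(rows, dtype=float).T
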