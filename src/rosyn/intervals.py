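"""Genomic interval data model, BED/bedGraph I/O and coverage quantification.

All coordinates are 0-based, half-open — the native convention of BED and
bedGraph, the only genomic text formats this package consumes.  Any 1-based
coordinate appearing in a human-readable report is labeled as such where it
is written.

Strand is deliberately ignored for peaks and coverage (H3K27ac ChIP signal
is unstranded); it only matters for gene annotations, where it fixes which
end of the gene is the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "GenomicInterval",
    "Peak",
    "CoverageTrack",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "sort_and_merge",
    "interval_signal",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValidationError(f"chromosome name must be a non-empty token, got {self.chrom!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint (floor division), used as the reference point."""
        return (self.start + self.end) // 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus an identifier and an informational score."""

    interval: GenomicInterval
    name: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"peak score must be non-negative, got {self.score}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with its transcription start site."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"TSS must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


class CoverageTrack:
    """Step-function signal over chromosomes with bedGraph semantics.

    Per chromosome the track holds sorted, non-overlapping steps
    ``(start, end, value)`` with ``value >= 0`` interpreted as signal
    density per base.  Gaps between steps carry zero signal.
    """

    def __init__(self, steps: Iterable[tuple[str, int, int, float]] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in steps:
            GenomicInterval(chrom, start, end)  # validates coordinates
            if value < 0:
                raise ValidationError(
                    f"coverage value must be non-negative, got {value} at {chrom}:{start}-{end}"
                )
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))

        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, triples in by_chrom.items():
            triples.sort(key=lambda t: t[0])
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
                raise ValidationError(
                    f"overlapping steps on {chrom}: "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._starts))

    def steps(self) -> Iterator[tuple[str, int, int, float]]:
        """Yield (chrom, start, end, value) in sorted order."""
        for chrom in self.chroms:
            for s, e, v in zip(self._starts[chrom], self._ends[chrom], self._values[chrom]):
                yield chrom, int(s), int(e), float(v)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) arrays for one chromosome; empty if absent."""
        if chrom not in self._starts:
            z = np.empty(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._starts[chrom], self._ends[chrom], self._values[chrom]

    def total_signal(self) -> float:
        """Total area under the step function across all chromosomes."""
        return float(
            sum(
                np.dot(self._values[c], (self._ends[c] - self._starts[c]).astype(float))
                for c in self._starts
            )
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        """A new track with every step value multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValidationError(f"scale factor must be >= 0, got {factor}")
        return CoverageTrack(
            (c, int(s), int(e), float(v) * factor) for c, s, e, v in self.steps()
        )

    def __len__(self) -> int:
        return int(sum(a.size for a in self._starts.values()))


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_BED_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def read_bed(path: str | Path, dialect: str = "bed6") -> list[Peak]:
    """Read a BED3/BED6/narrowPeak file into peaks, preserving file order.

    Coordinates are taken verbatim (BED is already 0-based half-open).
    The narrowPeak score column (5th) maps to :attr:`Peak.score`.  Missing
    or placeholder (``.``) names are auto-generated as ``peak_<n>`` with
    n counting from 1 in file order.
    """
    if dialect not in _BED_COLUMNS:
        raise ValidationError(f"unknown BED dialect {dialect!r}; expected one of {sorted(_BED_COLUMNS)}")
    min_cols = _BED_COLUMNS[dialect]
    peaks: list[Peak] = []
    names_seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns for {dialect}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                interval = GenomicInterval(fields[0], start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if min_cols >= 6 and fields[3] not in ("", ".") else f"peak_{len(peaks) + 1}"
            score = 0.0
            if min_cols >= 6 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}") from exc
            if name in names_seen:
                raise ValidationError(f"{path}:{lineno}: duplicate peak name {name!r}")
            names_seen.add(name)
            peaks.append(Peak(interval, name, score))
    return peaks


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as BED6 (strand written as '.'; round-trips with read_bed)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{_format_score(p.score)}\t.\n")


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack`.

    Overlapping steps and negative values are rejected; zero-value steps
    are retained (they are informative for round-tripping).
    """
    steps: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph fields") from exc
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative coverage value {value}")
            steps.append((fields[0], start, end, value))
    return CoverageTrack(steps)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as 4-column bedGraph ('%.6g' value formatting)."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.steps():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_gene_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a TSV gene table with header columns gene, chrom, tss, strand."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene", "chrom", "tss", "strand"]
        if header[: len(required)] != required:
            raise ParseError(f"{path}:1: expected header {required}, got {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            try:
                tss = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer TSS") from exc
            genes.append(GeneAnnotation(fields[0], fields[1], tss, fields[3]))
    return genes


def write_gene_table(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def sort_and_merge(
    peaks: Sequence[Peak], max_gap: int
) -> list[tuple[GenomicInterval, list[str]]]:
    """Sort peaks and merge neighbours whose gap is at most ``max_gap`` bp.

    Two consecutive same-chromosome intervals merge when
    ``next.start - current.end <= max_gap`` — touching and overlapping peaks
    always merge, and the boundary gap equal to ``max_gap`` merges too (the
    inclusive reading of "within a distance").  Output intervals are
    disjoint with pairwise gaps strictly greater than ``max_gap``; each
    carries the names of its constituent peaks in genomic order.
    """
    if max_gap < 0:
        raise ValidationError(f"max_gap must be >= 0, got {max_gap}")
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    merged: list[tuple[GenomicInterval, list[str]]] = []
    for peak in ordered:
        iv = peak.interval
        if merged:
            cur, names = merged[-1]
            if cur.chrom == iv.chrom and iv.start - cur.end <= max_gap:
                merged[-1] = (
                    GenomicInterval(cur.chrom, cur.start, max(cur.end, iv.end)),
                    names + [peak.name],
                )
                continue
        merged.append((iv, [peak.name]))
    return merged


def interval_signal(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Area under the track's step function over ``interval``.

    Sum over overlapping steps of value x overlap-length; zero where the
    track has no coverage (including chromosomes absent from the track).
    """
    starts, ends, values = track.chrom_arrays(interval.chrom)
    if starts.size == 0:
        return 0.0
    # candidate steps: end > interval.start and start < interval.end
    i0 = int(np.searchsorted(ends, interval.start, side="right"))
    i1 = int(np.searchsorted(starts, interval.end, side="left"))
    if i0 >= i1:
        return 0.0
    ov = np.minimum(ends[i0:i1], interval.end) - np.maximum(starts[i0:i1], interval.start)
    return float(np.dot(values[i0:i1], np.maximum(ov, 0).astype(float)))


def check_chromosome_overlap(peaks: Sequence[Peak], track: CoverageTrack) -> bool:
    """Preflight: warn when peak and track chromosome sets are disjoint.

    Chromosome matching is exact string comparison (no "chr" aliasing):
    silent aliasing hides mixed-assembly inputs.  Returns True when at
    least one chromosome is shared.
    """
    peak_chroms = {p.interval.chrom for p in peaks}
    shared = peak_chroms & set(track.chroms)
    if peaks and len(track) and not shared:
        warnings.warn(
            f"peak chromosomes {sorted(peak_chroms)} and coverage chromosomes "
            f"{sorted(track.chroms)} are disjoint; check naming/assembly",
            stacklevel=2,
        )
    return bool(shared)
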