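"""Genomic coordinate model and exact interval-set arithmetic.

All coordinates are BED-convention 0-based half-open ``[start, end)``,
everywhere, including printed output.  A :class:`GenomicIntervalSet` is
always kept sorted by ``(chrom, start, end, name)`` so downstream sweeps
can rely on order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Genome",
    "GenomicInterval",
    "GenomicIntervalSet",
    "read_bed",
    "write_bed",
    "merge",
    "intersect",
    "jaccard",
    "reciprocal_overlap",
]


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be parsed."""


@dataclass(frozen=True)
class Genome:
    """An ordered set of named chromosomes with lengths in bp."""

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be > 0")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length(self, name: str) -> int:
        return self.lengths[name]


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open interval, optionally named/scored/stranded with a summit.

    ``summit`` is an offset from ``start`` (MACS2 narrowPeak column 10
    semantics).  When absent, :meth:`effective_summit` falls back to the
    interval midpoint (floor division).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    summit: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (0 <= self.summit < len(self)):
            raise ValueError(f"summit {self.summit} outside interval")
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def effective_summit(self) -> int:
        """Absolute genomic position of the summit (midpoint fallback)."""
        off = self.summit if self.summit is not None else len(self) // 2
        return self.start + off

    @property
    def center(self) -> int:
        return self.start + len(self) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")


class GenomicIntervalSet:
    """Sorted collection of intervals bound to a :class:`Genome`."""

    def __init__(self, genome: Genome, intervals: Iterable[GenomicInterval] = ()):
        self.genome = genome
        ivs = list(intervals)
        lengths = genome.lengths
        for iv in ivs:
            if iv.chrom not in lengths:
                raise ValueError(f"chromosome {iv.chrom!r} not in genome")
            if iv.end > lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {lengths[iv.chrom]}"
                )
        order = {n: i for i, n in enumerate(genome.names)}
        ivs.sort(key=lambda iv: (order[iv.chrom],) + iv.sort_key()[1:])
        self.intervals: list[GenomicInterval] = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomicIntervalSet)
            and self.genome == other.genome
            and self.intervals == other.intervals
        )

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def covered_bp(self) -> int:
        """Number of distinct bases covered (after implicit merge)."""
        return sum(iv.end - iv.start for iv in merge(self))

    def coverage_arrays(self) -> dict[str, np.ndarray]:
        """Per-chromosome sorted, disjoint ``(start, end)`` arrays (merged)."""
        out = {}
        for chrom, ivs in merge(self).by_chrom().items():
            out[chrom] = np.array([(iv.start, iv.end) for iv in ivs], dtype=np.int64)
        return out


# ---------------------------------------------------------------------------
# BED I/O


def _parse_bed_line(line: str, lineno: int, genome: Genome) -> GenomicInterval | None:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    if chrom not in genome:
        raise BedParseError(f"line {lineno}: unknown chromosome {chrom!r}")
    if start >= end:
        raise BedParseError(f"line {lineno}: start {start} >= end {end}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-", ".") else None
    summit = None
    if len(fields) >= 10:  # MACS2 narrowPeak dialect: col 10 = summit offset
        try:
            s = int(fields[9])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: bad summit column") from exc
        if s >= 0:
            summit = s
    try:
        return GenomicInterval(chrom, start, end, name, score, strand, summit)
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(path, genome: Genome) -> GenomicIntervalSet:
    """Read BED3/BED6 or 10-column narrowPeak into a sorted set.

    Intervals on chromosomes absent from *genome* raise
    :class:`BedParseError` with the offending line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv = _parse_bed_line(line, lineno, genome)
            if iv is not None:
                intervals.append(iv)
    return GenomicIntervalSet(genome, intervals)


def write_bed(s: GenomicIntervalSet, path, *, narrowpeak: bool = False) -> None:
    """Write BED (3-6 columns as populated); narrowPeak keeps summits."""
    with open(path, "w") as fh:
        for iv in s:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if narrowpeak:
                fields += [
                    iv.name or ".",
                    format(iv.score if iv.score is not None else 0, "g"),
                    iv.strand or ".",
                    "0",
                    "-1",
                    "-1",
                    str(iv.summit if iv.summit is not None else -1),
                ]
            else:
                if iv.name is not None or iv.score is not None or iv.strand is not None:
                    fields.append(iv.name or ".")
                if iv.score is not None or iv.strand is not None:
                    fields.append(format(iv.score, "g") if iv.score is not None else ".")
                if iv.strand is not None:
                    fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Set arithmetic


def merge(s: GenomicIntervalSet) -> GenomicIntervalSet:
    """Collapse overlapping and bookended intervals (bedtools-merge default).

    Output intervals are pairwise disjoint; the covered base set is preserved.
    Names/scores/summits are dropped.
    """
    out = []
    for chrom, ivs in s.by_chrom().items():
        cur_start, cur_end = None, None
        for iv in ivs:
            if cur_start is None:
                cur_start, cur_end = iv.start, iv.end
            elif iv.start <= cur_end:  # bookended (==) merges too
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        if cur_start is not None:
            out.append(GenomicInterval(chrom, cur_start, cur_end))
    return GenomicIntervalSet(s.genome, out)


def _check_same_genome(a: GenomicIntervalSet, b: GenomicIntervalSet) -> None:
    if a.genome != b.genome:
        raise ValueError("interval sets are on different genomes")


def intersect(
    a: GenomicIntervalSet, b: GenomicIntervalSet
) -> list[tuple[GenomicInterval, GenomicInterval, int]]:
    """All pairs ``(iv_a, iv_b, overlap_bp)`` with at least 1 shared base.

    Plane-sweep per chromosome; output ordered by the position of ``iv_a``.
    """
    _check_same_genome(a, b)
    pairs = []
    b_by_chrom = b.by_chrom()
    for chrom, ivs_a in a.by_chrom().items():
        ivs_b = b_by_chrom.get(chrom, [])
        if not ivs_b:
            continue
        starts_b = np.array([iv.start for iv in ivs_b])
        # prefix-max of ends is non-decreasing: candidates before its
        # crossing point of iv.start cannot reach iv.
        maxend_b = np.maximum.accumulate(np.array([iv.end for iv in ivs_b]))
        for iv in ivs_a:
            j0 = int(np.searchsorted(starts_b, iv.end, side="left"))
            lo = int(np.searchsorted(maxend_b, iv.start, side="right"))
            for jv in ivs_b[lo:j0]:
                ov = iv.overlap_bp(jv)
                if ov > 0:
                    pairs.append((iv, jv, ov))
    return pairs


def _intersection_bp(a: GenomicIntervalSet, b: GenomicIntervalSet) -> int:
    """Covered bp of the base-set intersection of two (merged) sets."""
    total = 0
    cov_b = b.coverage_arrays()
    for chrom, ivs in merge(a).by_chrom().items():
        arr_b = cov_b.get(chrom)
        if arr_b is None or arr_b.size == 0:
            continue
        starts_b, ends_b = arr_b[:, 0], arr_b[:, 1]
        for iv in ivs:
            lo = int(np.searchsorted(ends_b, iv.start, side="right"))
            hi = int(np.searchsorted(starts_b, iv.end, side="left"))
            for j in range(lo, hi):
                total += max(
                    0, min(iv.end, ends_b[j]) - max(iv.start, starts_b[j])
                )
    return int(total)


def jaccard(a: GenomicIntervalSet, b: GenomicIntervalSet) -> float:
    """Base-pair Jaccard similarity of two interval sets.

    ``|bases(a) ∩ bases(b)| / |bases(a) ∪ bases(b)|`` on merged sets; by
    convention 0.0 when both sets are empty.
    """
    _check_same_genome(a, b)
    inter = _intersection_bp(a, b)
    union = a.covered_bp() + b.covered_bp() - inter
    if union == 0:
        return 0.0
    return inter / union


def reciprocal_overlap(
    x: GenomicInterval, y: GenomicInterval, min_frac: float
) -> bool:
    """True iff x and y overlap by >= min_frac of *both* their lengths."""
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    ov = x.overlap_bp(y)
    if ov <= 0:
        return False
    return ov / len(x) >= min_frac and ov / len(y) >= min_frac
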