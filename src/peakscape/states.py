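"""Chromatin-state annotation of peaks from a labeled genome segmentation.

Each peak receives the single state contributing the most overlapping bases
(ties broken by palette order); the per-peak labels are then summarized as a
state distribution with configurable grouping (promoters, enhancers,
heterochromatin/repressed, other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import Genome, GenomicInterval, GenomicIntervalSet, read_bed

__all__ = [
    "DEFAULT_PALETTE",
    "DEFAULT_GROUPS",
    "SegmentationTrack",
    "StateDistribution",
    "read_segmentation",
    "assign_states",
    "state_distribution",
]

# ChromHMM-style 11-state palette (order is the tie-break order).
DEFAULT_PALETTE: tuple[str, ...] = (
    "Active Promoter",
    "Weak Promoter",
    "Poised Promoter",
    "Strong Enhancer",
    "Weak/Poised Enhancer",
    "Insulator",
    "Txn Transition/Elongation",
    "Weak Txn",
    "Repressed",
    "Heterochrom/lo",
    "Repetitive/CNV",
)

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "promoters": ("Active Promoter", "Weak Promoter", "Poised Promoter"),
    "enhancers": ("Strong Enhancer", "Weak/Poised Enhancer"),
    "heterochromatin/repressed": ("Heterochrom/lo", "Repressed"),
}

UNSEGMENTED = "Unsegmented"


class SegmentationTrack:
    """Non-overlapping labeled intervals; labels drawn from a palette."""

    def __init__(
        self,
        genome: Genome,
        segments: GenomicIntervalSet,
        state_palette: Sequence[str] = DEFAULT_PALETTE,
    ):
        self.genome = genome
        self.state_palette = tuple(state_palette)
        known = set(self.state_palette)
        prev_end: dict[str, int] = {}
        for seg in segments:
            if seg.name is None or seg.name not in known:
                raise ValueError(f"segment label {seg.name!r} not in palette")
            if seg.start < prev_end.get(seg.chrom, 0):
                raise ValueError(
                    f"overlapping segments on {seg.chrom} at {seg.start}"
                )
            prev_end[seg.chrom] = seg.end
        self.segments = segments
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for chrom, ivs in segments.by_chrom().items():
            self._by_chrom[chrom] = (
                np.array([s.start for s in ivs], dtype=np.int64),
                np.array([s.end for s in ivs], dtype=np.int64),
                [s.name for s in ivs],
            )

    def covers_genome(self) -> bool:
        """True iff every base of every chromosome is segmented."""
        for chrom, L in self.genome.chromosomes:
            if chrom not in self._by_chrom:
                return False
            starts, ends, _ = self._by_chrom[chrom]
            if starts[0] != 0 or ends[-1] != L or np.any(starts[1:] != ends[:-1]):
                return False
        return True

    def overlap_bp_by_state(self, iv: GenomicInterval) -> dict[str, int]:
        """Bases of *iv* falling in each state (plus ``Unsegmented``)."""
        out: dict[str, int] = {}
        covered = 0
        if iv.chrom in self._by_chrom:
            starts, ends, labels = self._by_chrom[iv.chrom]
            lo = int(np.searchsorted(ends, iv.start, side="right"))
            hi = int(np.searchsorted(starts, iv.end, side="left"))
            for j in range(lo, hi):
                ov = min(iv.end, ends[j]) - max(iv.start, starts[j])
                if ov > 0:
                    out[labels[j]] = out.get(labels[j], 0) + int(ov)
                    covered += int(ov)
        if covered < len(iv):
            out[UNSEGMENTED] = len(iv) - covered
        return out


def read_segmentation(
    path, genome: Genome, state_palette: Sequence[str] | None = None
) -> SegmentationTrack:
    """Read a chromHMM-style BED export (state label in the name column).

    When *state_palette* is omitted it is taken from the default 11-state
    palette extended with any extra labels present (in order of appearance).
    """
    segs = read_bed(path, genome)
    if state_palette is None:
        palette = list(DEFAULT_PALETTE)
        for seg in segs:
            if seg.name is not None and seg.name not in palette:
                palette.append(seg.name)
        state_palette = palette
    return SegmentationTrack(genome, segs, state_palette)


def assign_states(
    peaks: GenomicIntervalSet, seg: SegmentationTrack
) -> dict[str, str]:
    """Label each peak with its majority-base state.

    Ties are broken by palette order; peaks lying (partly) over unsegmented
    bases with no better-covered state are labeled ``Unsegmented`` with a
    warning.
    """
    rank = {s: i for i, s in enumerate(seg.state_palette)}
    rank[UNSEGMENTED] = len(rank)
    out: dict[str, str] = {}
    n_unseg = 0
    for iv in peaks:
        pid = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        bp = seg.overlap_bp_by_state(iv)
        best = max(bp.items(), key=lambda kv: (kv[1], -rank[kv[0]]))[0]
        if best == UNSEGMENTED:
            n_unseg += 1
        out[pid] = best
    if n_unseg:
        warnings.warn(
            f"{n_unseg} peak(s) over unsegmented bases labeled {UNSEGMENTED!r}",
            stacklevel=2,
        )
    return out


@dataclass
class StateDistribution:
    per_state_fraction: dict[str, float]
    per_state_count: dict[str, int]
    grouped_fraction: dict[str, float]
    n: int

    def report_pct(self, decimals: int = 1) -> dict[str, float]:
        """Percentages rounded half-up to *decimals* (report-time only)."""
        scale = 10**decimals
        return {
            s: float(np.floor(f * 100 * scale + 0.5)) / scale
            for s, f in self.per_state_fraction.items()
        }


def state_distribution(
    assignment: Mapping[str, str],
    groups: Mapping[str, Sequence[str]] = DEFAULT_GROUPS,
) -> StateDistribution:
    """Fractions of peaks per state and per group (grouping is config;
    ungrouped states pool into "other")."""
    if not assignment:
        raise ValueError("empty assignment")
    n = len(assignment)
    counts: dict[str, int] = {}
    for state in assignment.values():
        counts[state] = counts.get(state, 0) + 1
    frac = {s: c / n for s, c in counts.items()}
    state_to_group = {s: g for g, states in groups.items() for s in states}
    grouped: dict[str, float] = {g: 0.0 for g in groups}
    grouped["other"] = 0.0
    for s, f in frac.items():
        grouped[state_to_group.get(s, "other")] += f
    return StateDistribution(frac, counts, grouped, n)
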