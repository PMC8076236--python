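"""Replicate agreement: consensus peaks by reciprocal overlap and binned
signal correlation between replicate tracks.

A replicate-1 peak enters the consensus iff every other replicate contains
at least one peak overlapping it reciprocally by ``min_frac`` of both
lengths (existence semantics — a peak matching two partners still counts
once).  Consensus coordinates are the replicate-1 intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicIntervalSet, reciprocal_overlap
from .signals import SignalTrack

__all__ = ["ConsensusResult", "consensus_peaks", "binned_signal_correlation"]


@dataclass
class ConsensusResult:
    consensus: GenomicIntervalSet
    per_replicate_counts: list[int]
    venn_counts: dict[frozenset, int]

    @property
    def n_consensus(self) -> int:
        return len(self.consensus)


def _has_reciprocal_match(iv, other_ivs, other_starts, other_maxend, min_frac):
    j0 = int(np.searchsorted(other_starts, iv.end, side="left"))
    lo = int(np.searchsorted(other_maxend, iv.start, side="right"))
    return any(
        reciprocal_overlap(iv, jv, min_frac) for jv in other_ivs[lo:j0]
    )


def _chrom_index(s: GenomicIntervalSet):
    idx = {}
    for chrom, ivs in s.by_chrom().items():
        starts = np.array([iv.start for iv in ivs])
        maxend = np.maximum.accumulate(np.array([iv.end for iv in ivs]))
        idx[chrom] = (ivs, starts, maxend)
    return idx


def _support(iv, rep_i, indices, min_frac):
    """Replicate indices (including rep_i) holding a reciprocal match."""
    supp = {rep_i}
    for j, idx in enumerate(indices):
        if j == rep_i:
            continue
        entry = idx.get(iv.chrom)
        if entry and _has_reciprocal_match(iv, *entry, min_frac):
            supp.add(j)
    return frozenset(supp)


def consensus_peaks(
    replicates: Sequence[GenomicIntervalSet],
    min_frac: float = 0.5,
    require_all: bool = True,
) -> ConsensusResult:
    """Consensus peak set across replicates under the reciprocal-overlap rule.

    With ``require_all`` (default) a replicate-1 peak must find a match in
    every other replicate; otherwise a strict majority of replicates
    (counting itself) suffices.  ``venn_counts`` assigns every peak of every
    replicate a support signature and counts, per replicate subset, the
    peaks from the lowest-index member whose signature equals that subset.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    genome = replicates[0].genome
    if any(r.genome != genome for r in replicates[1:]):
        raise ValueError("replicates are on different genomes")
    indices = [_chrom_index(r) for r in replicates]

    venn: dict[frozenset, int] = {}
    consensus_ivs = []
    n_reps = len(replicates)
    needed = n_reps if require_all else n_reps // 2 + 1
    for i, rep in enumerate(replicates):
        for iv in rep:
            supp = _support(iv, i, indices, min_frac)
            if min(supp) == i:  # count each subset once, from its lowest member
                venn[supp] = venn.get(supp, 0) + 1
            if i == 0 and len(supp) >= needed:
                consensus_ivs.append(iv)
    return ConsensusResult(
        GenomicIntervalSet(genome, consensus_ivs),
        [len(r) for r in replicates],
        venn,
    )


def binned_signal_correlation(
    a: SignalTrack,
    b: SignalTrack,
    bin_bp: int = 1000,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Correlation of mean signal per genome-tiling bin between two tracks."""
    if a.genome != b.genome:
        raise ValueError("tracks are on different genomes")
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    x = a.genome_bins(bin_bp)
    y = b.genome_bins(bin_bp)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a track has zero variance")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
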