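"""Colocalization statistics for binary genomic tracks.

Two tracks are compared through their joint per-base occupancy: a 2x2 table
of bases covered by both, either, or neither track feeds a tetrachoric
correlation (cosine approximation), while a base-pair Jaccard matrix over
many tracks feeds complete-linkage hierarchical clustering.  Significance
comes from a Monte-Carlo null that circularly rotates the query track per
chromosome, preserving interval lengths and inter-element distances
exactly while the reference track stays fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .intervals import (
    Genome,
    GenomicInterval,
    GenomicIntervalSet,
    _intersection_bp,
    jaccard,
    merge,
)

__all__ = [
    "BasePair2x2",
    "ColocResult",
    "basepair_table",
    "tetrachoric",
    "mc_coloc_test",
    "pairwise_matrix",
    "hierarchical_cluster",
    "bh_adjust",
    "circular_shift",
]


@dataclass(frozen=True)
class BasePair2x2:
    """Joint base-pair occupancy of a query and a reference track.

    a: bp in both; b: query only; c: reference only; d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell in 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class ColocResult:
    coefficient: float
    table: BasePair2x2
    overlap_bp: int
    p_value: float
    n_mc: int
    seed: int
    statistic: str
    null_stats: np.ndarray | None = None


def basepair_table(
    query: GenomicIntervalSet, reference: GenomicIntervalSet, genome: Genome
) -> BasePair2x2:
    """Exact base counts of the four joint occupancy states."""
    if query.genome != genome or reference.genome != genome:
        raise ValueError("interval sets not on the given genome")
    a = _intersection_bp(query, reference)
    cov_q = query.covered_bp()
    cov_r = reference.covered_bp()
    total = genome.total_bp
    return BasePair2x2(a, cov_q - a, cov_r - a, total - cov_q - cov_r + a)


def tetrachoric(table: BasePair2x2) -> float:
    """Tetrachoric correlation, cosine approximation.

    ``r = cos(pi / (1 + sqrt(ad/bc)))``; the limits are +1 when ``bc == 0``
    with ``ad > 0`` (perfect co-occurrence), -1 when ``ad == 0`` with
    ``bc > 0`` (perfect avoidance).  A table with a zero row or column is
    degenerate and raises.
    """
    if table.total <= 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
        raise ValueError("degenerate 2x2 table: a zero row or column")
    ad, bc = a * d, b * c
    if bc == 0 and ad > 0:
        return 1.0
    if ad == 0 and bc > 0:
        return -1.0
    if ad == 0 and bc == 0:
        raise ValueError("tetrachoric undefined: ad = bc = 0")
    return math.cos(math.pi / (1.0 + math.sqrt(ad / bc)))


def circular_shift(
    s: GenomicIntervalSet, offsets: Mapping[str, int]
) -> GenomicIntervalSet:
    """Rotate all intervals of each chromosome by its offset, with
    wrap-around (an interval crossing the end splits in two).

    Preserves per-chromosome covered bp and inter-element distances.
    """
    out = []
    lengths = s.genome.lengths
    for iv in s:
        L = lengths[iv.chrom]
        off = offsets.get(iv.chrom, 0) % L
        start = (iv.start + off) % L
        end = start + len(iv)
        if end <= L:
            out.append(GenomicInterval(iv.chrom, start, end))
        else:
            out.append(GenomicInterval(iv.chrom, start, L))
            out.append(GenomicInterval(iv.chrom, 0, end - L))
    return GenomicIntervalSet(s.genome, out)


def _statistic(
    name: str, query: GenomicIntervalSet, reference: GenomicIntervalSet,
    genome: Genome,
) -> tuple[float, BasePair2x2]:
    table = basepair_table(query, reference, genome)
    if name == "tetrachoric":
        return tetrachoric(table), table
    if name == "jaccard":
        denom = table.a + table.b + table.c
        return (table.a / denom if denom else 0.0), table
    raise ValueError(f"unknown statistic {name!r}")


def mc_coloc_test(
    query: GenomicIntervalSet,
    reference: GenomicIntervalSet,
    genome: Genome,
    statistic: Literal["tetrachoric", "jaccard"] = "tetrachoric",
    n_mc: int = 999,
    seed: int = 0,
    keep_null: bool = False,
) -> ColocResult:
    """One-sided Monte-Carlo colocalization test.

    Null draws circularly shift the query per chromosome by an offset
    uniform on the chromosome length; the reference is fixed.  The
    empirical p uses the add-one estimator
    ``p = (1 + #{null >= observed}) / (n_mc + 1)`` and is never zero.
    """
    if n_mc < 19:
        raise ValueError("n_mc must be >= 19")
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("empty query or reference")
    query = merge(query)
    reference = merge(reference)
    obs, table = _statistic(statistic, query, reference, genome)
    rng = np.random.default_rng(seed)
    chroms = [c for c, _ in genome.chromosomes]
    lengths = genome.lengths
    null = np.empty(n_mc)
    for t in range(n_mc):
        offsets = {c: int(rng.integers(0, lengths[c])) for c in chroms}
        shifted = circular_shift(query, offsets)
        null[t], _ = _statistic(statistic, shifted, reference, genome)
    p = (1 + int(np.sum(null >= obs))) / (n_mc + 1)
    return ColocResult(
        obs, table, table.a, p, n_mc, seed, statistic,
        null if keep_null else None,
    )


def pairwise_matrix(
    sets: Mapping[str, GenomicIntervalSet],
    statistic: Literal["jaccard", "tetrachoric"] = "jaccard",
) -> pd.DataFrame:
    """Symmetric named similarity matrix over interval sets.

    The Jaccard diagonal is exactly 1; a pair on which the statistic is
    undefined gets NaN (flagged missing).
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    genome = sets[names[0]].genome
    if any(sets[n].genome != genome for n in names):
        raise ValueError("sets are on different genomes")
    M = np.ones((len(names), len(names)))
    for i, ni in enumerate(names):
        if statistic == "tetrachoric":
            try:
                M[i, i] = tetrachoric(basepair_table(sets[ni], sets[ni], genome))
            except ValueError:
                M[i, i] = np.nan
        for j in range(i + 1, len(names)):
            nj = names[j]
            if statistic == "jaccard":
                v = jaccard(sets[ni], sets[nj])
            else:
                try:
                    v = tetrachoric(basepair_table(sets[ni], sets[nj], genome))
                except ValueError:
                    v = np.nan
            M[i, j] = M[j, i] = v
    return pd.DataFrame(M, index=names, columns=names)


@dataclass
class ClusterTree:
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]
    newick: str


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    trees = {i: (labels[i], 0.0) for i in range(n)}
    for k, (i, j, h, _) in enumerate(Z):
        li, hi = trees.pop(int(i))
        lj, hj = trees.pop(int(j))
        node = f"({li}:{h - hi:g},{lj}:{h - hj:g})"
        trees[n + k] = (node, float(h))
    (tree, _), = trees.values()
    return tree + ";"


def hierarchical_cluster(matrix: pd.DataFrame) -> ClusterTree:
    """Complete-linkage agglomeration on Euclidean distances between rows.

    Rows are pre-sorted by name so equal-distance merges are deterministic;
    leaf order is scipy's dendrogram order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("non-finite entries in matrix")
    m = matrix.loc[sorted(matrix.index), sorted(matrix.index)]
    Z = hierarchy.linkage(pdist(m.values, metric="euclidean"), method="complete")
    order = [m.index[i] for i in hierarchy.leaves_list(Z)]
    return ClusterTree(Z, order, _linkage_to_newick(Z, list(m.index)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])
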