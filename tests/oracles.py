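"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities from first principles (per-base
boolean arrays, all-pairs scans, exhaustive enumeration) and never calls
the implementation path it is checking.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def coverage_bool(intervals, genome) -> dict[str, np.ndarray]:
    """Per-chromosome boolean occupancy arrays from raw (chrom,start,end)."""
    cov = {name: np.zeros(L, dtype=bool) for name, L in genome.chromosomes}
    for iv in intervals:
        cov[iv.chrom][iv.start : iv.end] = True
    return cov


def merged_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def jaccard_bool(a_cov, b_cov) -> float:
    inter = sum(int((a_cov[c] & b_cov[c]).sum()) for c in a_cov)
    union = sum(int((a_cov[c] | b_cov[c]).sum()) for c in a_cov)
    return inter / union if union else 0.0


def table_bool(q_cov, r_cov, genome) -> tuple[int, int, int, int]:
    a = b = c = 0
    for chrom in q_cov:
        a += int((q_cov[chrom] & r_cov[chrom]).sum())
        b += int((q_cov[chrom] & ~r_cov[chrom]).sum())
        c += int((~q_cov[chrom] & r_cov[chrom]).sum())
    return a, b, c, genome.total_bp - a - b - c


def allpairs_intersect(a, b) -> list[tuple[int, int, int]]:
    """All (i, j, overlap_bp) pairs by O(n^2) scan over index positions."""
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            ov = min(x.end, y.end) - max(x.start, y.start)
            if ov > 0:
                out.append((i, j, ov))
    return out


def reciprocal_ok(x, y, f) -> bool:
    if x.chrom != y.chrom:
        return False
    ov = min(x.end, y.end) - max(x.start, y.start)
    return ov > 0 and ov / (x.end - x.start) >= f and ov / (y.end - y.start) >= f


def consensus_bruteforce(replicates, min_frac=0.5) -> list:
    """Replicate-1 peaks with a reciprocal match in every other replicate."""
    out = []
    for iv in replicates[0]:
        if all(
            any(reciprocal_ok(iv, jv, min_frac) for jv in rep)
            for rep in replicates[1:]
        ):
            out.append(iv)
    return out


def majority_state(iv, segments, palette) -> str:
    """Per-base state vote over a peak; ties by palette order."""
    counts: dict[str, int] = {}
    covered = 0
    for seg in segments:
        if seg.chrom != iv.chrom:
            continue
        ov = min(iv.end, seg.end) - max(iv.start, seg.start)
        if ov > 0:
            counts[seg.name] = counts.get(seg.name, 0) + ov
            covered += ov
    if covered < iv.end - iv.start:
        counts["Unsegmented"] = (iv.end - iv.start) - covered
    rank = {s: i for i, s in enumerate(palette)}
    rank["Unsegmented"] = len(rank)
    return max(counts.items(), key=lambda kv: (kv[1], -rank[kv[0]]))[0]


def complete_linkage_heights(D: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage agglomeration by direct search."""
    clusters = [frozenset([i]) for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(clusters, 2):
            h = max(D[i, j] for i in a for j in b)
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights


def pwm_window_scores(seq: str, logodds: np.ndarray) -> list[tuple[int, str, float]]:
    """Exhaustive per-window scores on both strands; N windows skipped."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = logodds.shape[0]
    out = []
    for i in range(len(seq) - L + 1):
        w = seq[i : i + L].upper()
        if any(b not in idx for b in w):
            continue
        plus = sum(logodds[j, idx[w[j]]] for j in range(L))
        rc = "".join(comp[b] for b in reversed(w))
        minus = sum(logodds[j, idx[rc[j]]] for j in range(L))
        out.append((i, "+", plus))
        out.append((i, "-", minus))
    return out


def hypergeom_tail_enum(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for a hypergeometric by direct summation of the pmf."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        if n - x > M - N:
            continue
        total += comb(n, x) * comb(M - n, N - x) / comb(M, N)
    return total
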