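"""Piecewise-constant signal tracks, windowed signal matrices, meta-profiles,
k-means clustering of peaks by epigenomic signal, and genomic-position
categories (TSS/promoter, gene body, distal).

A :class:`SignalTrack` has bedGraph semantics: disjoint intervals carry a
constant non-negative value, uncovered bases are 0.  Windowed means are
computed from an exact prefix integral, so bin means are conservative: the
sum of ``bin_mean * bin_bp`` over a window equals the track's integral over
that window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .intervals import (
    BedParseError,
    Genome,
    GenomicInterval,
    GenomicIntervalSet,
)

__all__ = [
    "SignalTrack",
    "SignalMatrix",
    "ClusterAssignment",
    "Gene",
    "read_bedgraph",
    "build_signal_matrix",
    "aggregate_profile",
    "kmeans_cluster",
    "categorize_peaks",
]


class SignalTrack:
    """Non-negative piecewise-constant coverage over a genome."""

    def __init__(
        self,
        genome: Genome,
        chrom_data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ):
        """*chrom_data* maps chrom -> (starts, ends, values), sorted and
        non-overlapping; values finite and >= 0."""
        self.genome = genome
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in chrom_data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} not in genome")
            if starts.size:
                if np.any(starts >= ends) or np.any(starts[1:] < ends[:-1]):
                    raise ValueError(f"{chrom}: intervals unsorted or overlapping")
                if starts[0] < 0 or ends[-1] > genome.length(chrom):
                    raise ValueError(f"{chrom}: intervals out of bounds")
                if not np.all(np.isfinite(values)) or np.any(values < 0):
                    raise ValueError(f"{chrom}: values must be finite and >= 0")
            self._data[chrom] = (starts, ends, values)
            cum = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
            self._cum[chrom] = cum

    @classmethod
    def from_dense(cls, genome: Genome, dense: Mapping[str, np.ndarray],
                   bin_bp: int = 1) -> "SignalTrack":
        """Build from per-chromosome dense arrays at *bin_bp* resolution
        (run-length encoded internally)."""
        data = {}
        for chrom, arr in dense.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                z = np.array([], dtype=np.int64)
                data[chrom] = (z, z, np.array([]))
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts_i = np.concatenate([[0], change])
            ends_i = np.concatenate([change, [arr.size]])
            vals = arr[starts_i]
            keep = vals != 0
            L = genome.length(chrom)
            data[chrom] = (
                np.minimum(starts_i[keep] * bin_bp, L),
                np.minimum(ends_i[keep] * bin_bp, L),
                vals[keep],
            )
        return cls(genome, data)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Exact integral of the signal over [start, end) (clipped to bounds)."""
        if chrom not in self._data:
            return 0.0 if chrom in self.genome else self._missing(chrom)
        starts, ends, values = self._data[chrom]
        if starts.size == 0:
            return 0.0
        start = max(start, 0)
        end = min(end, self.genome.length(chrom))
        if start >= end:
            return 0.0
        cum = self._cum[chrom]
        # full intervals strictly inside plus clipped partial ends
        i = int(np.searchsorted(ends, start, side="right"))
        j = int(np.searchsorted(starts, end, side="left"))
        if i >= j:
            return 0.0
        total = cum[j] - cum[i]
        # trim partial overlap at the two flanks
        total -= values[i] * max(0, min(start, ends[i]) - starts[i])
        total -= values[j - 1] * max(0, ends[j - 1] - max(end, starts[j - 1]))
        return float(total)

    def _missing(self, chrom):
        raise KeyError(f"chromosome {chrom!r} not in genome")

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over [start, end); bases outside the
        chromosome count as 0 (zero-padding semantics)."""
        if end <= start:
            raise ValueError("empty window")
        return self.integral(chrom, start, end) / (end - start)

    def binned_means(self, chrom: str, start: int, end: int, n_bins: int) -> np.ndarray:
        width = (end - start) / n_bins
        edges = start + np.round(np.arange(n_bins + 1) * width).astype(np.int64)
        return np.array(
            [self.mean(chrom, int(edges[k]), int(edges[k + 1])) for k in range(n_bins)]
        )

    def genome_bins(self, bin_bp: int) -> np.ndarray:
        """Mean signal per genome-tiling bin (all chromosomes concatenated;
        the trailing partial bin of each chromosome is kept)."""
        if bin_bp < 1:
            raise ValueError("bin_bp must be >= 1")
        out = []
        for chrom, L in self.genome.chromosomes:
            edges = list(range(0, L, bin_bp)) + [L]
            for a, b in zip(edges[:-1], edges[1:]):
                out.append(self.mean(chrom, a, b))
        return np.array(out)


def read_bedgraph(path, genome: Genome) -> SignalTrack:
    """Read a bedGraph file (chrom, start, end, value); negative values are
    rejected on load."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected 4 fields")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: bad coordinates/value") from exc
            if value < 0:
                raise BedParseError(f"line {lineno}: negative signal value")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=np.float64)
        data[chrom] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return SignalTrack(genome, data)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            if chrom not in track._data:
                continue
            starts, ends, values = track._data[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Signal matrices


@dataclass
class SignalMatrix:
    """Per-anchor binned signal for several tracks.

    ``values`` has one row per anchor and ``n_bins * n_tracks`` columns,
    blocked by track then bin (track 0 bins, then track 1 bins, ...).
    """

    anchor_ids: list[str]
    anchors: list[tuple[str, int, str]]  # (chrom, anchor bp, strand)
    bins: int
    bin_bp: int
    tracks: list[str]
    values: np.ndarray

    def track_block(self, track: str) -> np.ndarray:
        i = self.tracks.index(track)
        return self.values[:, i * self.bins : (i + 1) * self.bins]


def _anchor_pos(iv: GenomicInterval, kind: str) -> int:
    if kind == "summit":
        return iv.effective_summit()
    if kind == "center":
        return iv.center
    if kind == "tss":
        return iv.start if (iv.strand or "+") == "+" else iv.end - 1
    raise ValueError(f"unknown anchor kind {kind!r}")


def build_signal_matrix(
    peaks: GenomicIntervalSet,
    tracks: Mapping[str, SignalTrack],
    flank_bp: int = 2000,
    bin_bp: int = 50,
    anchor: Literal["summit", "center", "tss"] = "summit",
) -> SignalMatrix:
    """Mean per-base signal in ``2*flank_bp/bin_bp`` bins around each anchor.

    Windows truncated at chromosome edges are zero-padded; minus-strand
    anchors have their bin order reversed when ``anchor == "tss"`` so that
    bins run 5' to 3' along the gene.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    track_names = list(tracks)
    n = len(peaks)
    values = np.zeros((n, n_bins * len(track_names)))
    anchor_ids, anchors = [], []
    for r, iv in enumerate(peaks):
        pos = _anchor_pos(iv, anchor)
        strand = iv.strand or "."
        anchor_ids.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
        anchors.append((iv.chrom, pos, strand))
        lo = pos - flank_bp
        for t, tname in enumerate(track_names):
            tr = tracks[tname]
            row = np.array(
                [
                    tr.mean(iv.chrom, lo + k * bin_bp, lo + (k + 1) * bin_bp)
                    if lo + (k + 1) * bin_bp > 0
                    and lo + k * bin_bp < tr.genome.length(iv.chrom)
                    else 0.0
                    for k in range(n_bins)
                ]
            )
            if anchor == "tss" and strand == "-":
                row = row[::-1]
            values[r, t * n_bins : (t + 1) * n_bins] = row
    return SignalMatrix(anchor_ids, anchors, n_bins, bin_bp, track_names, values)


def aggregate_profile(m: SignalMatrix) -> dict[str, np.ndarray]:
    """Per-track vector of column (bin) means — the meta-profile."""
    if m.values.shape[0] == 0:
        raise ValueError("empty signal matrix")
    return {t: m.track_block(t).mean(axis=0) for t in m.tracks}


# ---------------------------------------------------------------------------
# K-means clustering of peaks


@dataclass
class ClusterAssignment:
    labels: dict[str, str]  # anchor id -> "C1".."Ck"
    centroids: np.ndarray  # k x (bins*tracks), in clustering space
    k: int
    seed: int
    inertia: float
    order_track: str

    def label_list(self, anchor_ids: Sequence[str]) -> list[str]:
        return [self.labels[a] for a in anchor_ids]


def _transform_rows(m: SignalMatrix) -> np.ndarray:
    """arcsinh variance stabilization per value, then per-column z-score.

    Keeps one bright track from dominating the Euclidean objective; columns
    with zero variance are left centred at 0.
    """
    X = np.arcsinh(m.values)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def kmeans_cluster(
    m: SignalMatrix,
    k: int = 5,
    seed: int = 0,
    n_init: int = 10,
    transform: bool = True,
    order_track: str | None = None,
) -> ClusterAssignment:
    """Standard k-means (Euclidean, k-means++ init, best of *n_init*).

    Clusters are renamed C1..Ck by descending centroid mean over the
    designated ordering track (default: a promoter mark, ``H3K4me3`` when
    present, else the first track) so labels are stable across runs.
    """
    n = m.values.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} rows")
    X = _transform_rows(m) if transform else m.values
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
    raw = km.fit_predict(X)
    if order_track is None:
        order_track = "H3K4me3" if "H3K4me3" in m.tracks else m.tracks[0]
    ti = m.tracks.index(order_track)
    block = slice(ti * m.bins, (ti + 1) * m.bins)
    means = [km.cluster_centers_[c, block].mean() for c in range(k)]
    rank = np.argsort(np.argsort(-np.asarray(means)))  # 0 = highest mean
    labels = {
        aid: f"C{rank[c] + 1}" for aid, c in zip(m.anchor_ids, raw)
    }
    centroids = km.cluster_centers_[np.argsort(rank)]
    return ClusterAssignment(labels, centroids, k, seed, float(km.inertia_), order_track)


# ---------------------------------------------------------------------------
# Genomic position categories


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"gene {self.gene_id}: TSS outside span")


def promoter_window(g: Gene, upstream: int = 5000, downstream: int = 500) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, clipped at 0."""
    if g.strand == "+":
        return max(0, g.tss - upstream), g.tss + downstream
    return max(0, g.tss - downstream + 1), g.tss + upstream + 1


def categorize_peaks(
    peaks: GenomicIntervalSet,
    genes: Sequence[Gene],
    upstream: int = 5000,
    downstream: int = 500,
) -> dict[str, str]:
    """Assign each peak TSS/promoter, gene body or distal.

    TSS/promoter wins when the peak overlaps any gene's promoter window
    (default 5 kb upstream to 500 bp downstream of the TSS, strand aware);
    else gene body when it overlaps any gene span; else distal.
    """
    out = {}
    for i, iv in enumerate(peaks):
        pid = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        category = "distal"
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            lo, hi = promoter_window(g, upstream, downstream)
            if min(iv.end, hi) > max(iv.start, lo):
                category = "TSS/promoter"
                break
            if min(iv.end, g.end) > max(iv.start, g.start):
                category = "gene body"
        out[pid] = category
    return out


def category_fractions(
    categories: Mapping[str, str], labels: Mapping[str, str] | None = None
) -> dict:
    """Fractions per category, optionally split per cluster label."""
    cats = ("TSS/promoter", "gene body", "distal")
    if labels is None:
        n = len(categories)
        return {c: sum(v == c for v in categories.values()) / n for c in cats}
    out: dict[str, dict[str, float]] = {}
    for cluster in sorted(set(labels.values())):
        ids = [p for p, l in labels.items() if l == cluster and p in categories]
        if ids:
            out[cluster] = {
                c: sum(categories[p] == c for p in ids) / len(ids) for c in cats
            }
    return out
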