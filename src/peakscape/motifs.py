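"""PWM scanning and known-motif enrichment of peak sequences vs background.

Scanning scores both strands with a log-odds matrix
``log2((p + pseudo) / bg)``; a window is a hit when its score reaches
``threshold_frac`` of the motif's maximum achievable score.  Enrichment
counts sequences with at least one hit ("% of targets" semantics) and
tests the target count against the pooled target+background population
with a one-sided hypergeometric tail, BH-adjusted across motifs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from scipy.stats import hypergeom

from .intervals import GenomicIntervalSet
from .coloc import bh_adjust

__all__ = [
    "PWM",
    "EnrichmentRow",
    "scan_sequence",
    "enrich",
    "make_background",
    "extract_peak_sequences",
    "read_jaspar",
    "BUILTIN_PWMS",
]

_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    """Position probability matrix with background and pseudocount."""

    name: str
    matrix: np.ndarray  # L x 4, rows sum to 1, columns A C G T
    pseudo: float = 0.001
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L x 4 (A,C,G,T)")
        if len(self) < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("matrix rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """L x 4 log2 odds with pseudocount added to probabilities."""
        return np.log2((self.matrix + self.pseudo) / self.background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(name, counts / counts.sum(axis=1, keepdims=True), **kw)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, p_match: float = 0.97,
                       **kw) -> "PWM":
        """Near-deterministic PWM around a consensus string."""
        L = len(consensus)
        m = np.full((L, 4), (1 - p_match) / 3)
        for i, b in enumerate(consensus.upper()):
            m[i, _BASES.index(b)] = p_match
        return cls(name, m, **kw)


def read_jaspar(path_or_handle) -> list[PWM]:
    """Read JASPAR-format position frequency matrices via Bio.motifs."""
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        handle = open(path_or_handle)
        close = True
    else:
        handle, close = path_or_handle, False
    try:
        records = bio_motifs.parse(handle, "jaspar")
        out = []
        for rec in records:
            counts = np.array([rec.counts[b] for b in _BASES], dtype=float).T
            out.append(PWM.from_counts(rec.name or rec.matrix_id, counts))
        return out
    finally:
        if close:
            handle.close()


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4 (treated as N)."""
    lut = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_sequence(
    seq: str, pwm: PWM, threshold_frac: float = 0.8
) -> list[tuple[int, str, float]]:
    """All hits ``(position, strand, score)`` of *pwm* on both strands.

    The minus-strand score at position i is the score of the reverse
    complement of the window starting at i.  Windows containing N are
    skipped.  Returns an empty list when the sequence is shorter than the
    motif.
    """
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must be in (0, 1]")
    L = len(pwm)
    enc = _encode(seq)
    n_win = len(enc) - L + 1
    if n_win <= 0:
        return []
    lo = pwm.log_odds()
    lo_rc = lo[::-1, ::-1]  # minus-strand scores read on the plus sequence
    cutoff = threshold_frac * pwm.max_score()
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = ~np.any(windows == 4, axis=1)
    pos_idx = np.arange(L)
    hits = []
    for strand, mat in (("+", lo), ("-", lo_rc)):
        scores = np.where(
            valid, mat[pos_idx, np.clip(windows, 0, 3)].sum(axis=1), -np.inf
        )
        for i in np.flatnonzero(scores >= cutoff):
            hits.append((int(i), strand, float(scores[i])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


@dataclass
class EnrichmentRow:
    motif: str
    target_hits: int
    target_total: int
    bg_hits: int
    bg_total: int
    p: float
    p_adj: float

    @property
    def target_pct(self) -> float:
        return 100.0 * self.target_hits / self.target_total

    @property
    def bg_pct(self) -> float:
        return 100.0 * self.bg_hits / self.bg_total


def _n_with_hit(seqs: Sequence[str], pwm: PWM, threshold_frac: float) -> int:
    return sum(1 for s in seqs if scan_sequence(s, pwm, threshold_frac))


def enrich(
    target_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    pwms: Sequence[PWM],
    threshold_frac: float = 0.8,
) -> list[EnrichmentRow]:
    """Known-motif enrichment, sorted by ascending p (ties: target % desc).

    p is the one-sided hypergeometric tail P(X >= target_hits) when
    ``target_total`` sequences are drawn from the pooled target+background
    population containing ``target_hits + bg_hits`` motif-bearing sequences.
    """
    if not target_seqs or not bg_seqs:
        raise ValueError("target and background sequence sets must be non-empty")
    if not pwms:
        raise ValueError("empty PWM list")
    rows = []
    for pwm in pwms:
        th = _n_with_hit(target_seqs, pwm, threshold_frac)
        bh = _n_with_hit(bg_seqs, pwm, threshold_frac)
        M = len(target_seqs) + len(bg_seqs)
        n = th + bh
        N = len(target_seqs)
        p = float(hypergeom.sf(th - 1, M, n, N)) if n else 1.0
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            EnrichmentRow(pwm.name, th, len(target_seqs), bh, len(bg_seqs), p, 1.0)
        )
    adj = bh_adjust([r.p for r in rows])
    for r, q in zip(rows, adj):
        r.p_adj = float(q)
    rows.sort(key=lambda r: (r.p, -r.target_pct, r.motif))
    return rows


def extract_peak_sequences(
    peaks: GenomicIntervalSet,
    genome_seq: Mapping[str, str],
    flank: int = 100,
) -> list[str]:
    """Fixed windows (summit +/- flank, clipped at chromosome edges) as
    uppercase strings; *genome_seq* maps chrom to sequence (a pyfaidx
    ``Fasta`` works)."""
    out = []
    for iv in peaks:
        s = iv.effective_summit()
        chrom_seq = genome_seq[iv.chrom]
        lo, hi = max(0, s - flank), min(len(chrom_seq), s + flank)
        out.append(str(chrom_seq[lo:hi]).upper())
    return out


def make_background(
    target_seqs: Sequence[str],
    n: int,
    seed: int,
    mode: Literal["shuffle", "sample"] = "shuffle",
    peaks: GenomicIntervalSet | None = None,
    genome_seq: Mapping[str, str] | None = None,
    max_tries: int = 1000,
) -> list[str]:
    """Background sequences for enrichment.

    ``shuffle``: mononucleotide-shuffled copies of the target sequences
    (per-sequence length and base composition preserved).  ``sample``:
    random genomic windows of matched lengths avoiding *peaks* (requires
    *peaks* and *genome_seq*); raises if a window cannot be placed.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "shuffle":
        out = []
        for i in range(n):
            src = target_seqs[i % len(target_seqs)]
            chars = np.array(list(src))
            out.append("".join(chars[rng.permutation(len(chars))]))
        return out
    if mode == "sample":
        if peaks is None or genome_seq is None:
            raise ValueError("sample mode needs peaks and genome_seq")
        forbidden = peaks.coverage_arrays()
        chroms = peaks.genome.names
        lengths = peaks.genome.lengths
        out = []
        for i in range(n):
            want = len(target_seqs[i % len(target_seqs)])
            for _ in range(max_tries):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                if lengths[chrom] <= want:
                    continue
                start = int(rng.integers(0, lengths[chrom] - want))
                end = start + want
                arr = forbidden.get(chrom)
                if arr is not None and arr.size:
                    j = np.searchsorted(arr[:, 1], start, side="right")
                    if j < len(arr) and arr[j, 0] < end:
                        continue
                out.append(str(genome_seq[chrom][start:end]).upper())
                break
            else:
                raise RuntimeError(
                    f"could not place background window {i} after {max_tries} tries"
                )
        return out
    raise ValueError(f"unknown mode {mode!r}")


# A small built-in library of consensus-derived PWMs used by the synthetic
# pipeline: the embedded TF motif plus common decoy families.  These are
# synthetic stand-ins constructed from consensus strings, not database
# matrices.
BUILTIN_PWMS: dict[str, PWM] = {
    pwm.name: pwm
    for pwm in (
        PWM.from_consensus("MYB-like", "TAACGGTC"),
        PWM.from_consensus("GATA-like", "AGATAAGA"),
        PWM.from_consensus("ETS-like", "ACTTCCGG"),
        PWM.from_consensus("AP1-like", "TGACTCAT"),
        PWM.from_consensus("CTCF-like", "CCACCAGGGGGC"),
    )
}
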