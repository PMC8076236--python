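"""Synthetic pipeline inputs with planted ground truth.

The generator emulates the statistical shape of a TF ChIP-seq study in a
well-characterized cell line: three jittered replicate peak sets plus
noise, a chromHMM-style genome segmentation, six epigenomic signal tracks
(five histone marks and ATAC) following five peak archetypes
(promoter-like, enhancer-like, intragenic, repressed, unmarked), a genome
sequence with a consensus motif embedded at peak summits, a
regulatory-element (REM) map linking elements to genes, a knockdown/rescue
expression table with planted pioneer/non-pioneer genes, and auxiliary
partner/super-enhancer/footprint tracks.

Each output artifact draws from its own random stream seeded as
``seed + fixed offset``, so adding an artifact never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import Genome, GenomicInterval, GenomicIntervalSet, write_bed
from .motifs import BUILTIN_PWMS, PWM, reverse_complement
from .signals import Gene, SignalTrack, write_bedgraph
from .states import DEFAULT_PALETTE, SegmentationTrack

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticBundle", "simulate", "write_bundle"]

# archetype -> (narrow-bump tracks, broad-bump tracks)
ARCHETYPES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "C1": (("H3K4me3", "ATAC"), ()),
    "C2": (("H3K4me1", "H3K27ac"), ()),
    "C3": ((), ("H3K36me3",)),
    "C4": ((), ("H3K27me3",)),
    "C5": ((), ()),
}

TRACK_NAMES = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K36me3", "H3K27me3", "ATAC")

CLUSTER_STATE = {
    "C1": "Active Promoter",
    "C2": "Strong Enhancer",
    "C3": "Txn Transition/Elongation",
    "C4": "Repressed",
    "C5": "Heterochrom/lo",
}

# stream offsets (one independent generator per artifact)
_STREAMS = {
    "peaks": 11,
    "replicates": 23,
    "segmentation": 37,
    "signals": 41,
    "sequence": 53,
    "motif": 67,
    "rems": 79,
    "expression": 83,
    "partner": 97,
    "se": 101,
    "footprints": 103,
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    n_true_peaks: int = 500
    peak_len_range: tuple[int, int] = (200, 600)
    replicate_jitter_sd: float = 20.0
    replicate_dropout_p: float = 0.05
    noise_peaks_per_replicate: int = 25
    n_clusters: int = 5
    motif_embed_p: float = 0.6
    motif_pwm_sampled: bool = False
    gc_content: float = 0.41
    coloc_p: float = 0.5
    n_genes: int = 300
    n_pioneer: int = 30
    n_nonpioneer: int = 60
    noisy_expression: bool = False

    def __post_init__(self):
        for p in (
            self.replicate_dropout_p,
            self.motif_embed_p,
            self.gc_content,
            self.coloc_p,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.peak_len_range[1] >= self.chrom_len:
            raise ValueError("peak lengths must be smaller than chrom_len")
        if self.n_true_peaks < 1:
            raise ValueError("need at least one true peak")
        if self.n_pioneer + self.n_nonpioneer > self.n_genes:
            raise ValueError("planted gene classes exceed n_genes")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.seed + _STREAMS[stream])


@dataclass
class GroundTruth:
    true_peaks: GenomicIntervalSet
    peak_cluster_labels: dict[str, str]
    motif_positions: dict[str, int | None]  # offset from peak start, or None
    gene_class: dict[str, str]  # pioneer | non-pioneer | unaffected
    peak_gene_links: dict[str, set[str]]


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: Genome
    replicates: list[GenomicIntervalSet]
    segmentation: SegmentationTrack
    signal_tracks: dict[str, SignalTrack]
    sequence: dict[str, str]
    rem_elements: GenomicIntervalSet
    genes: list[Gene]
    expression: pd.DataFrame
    partner: GenomicIntervalSet
    super_enhancers: GenomicIntervalSet
    footprints: GenomicIntervalSet
    truth: GroundTruth


# ---------------------------------------------------------------------------


def _place_true_peaks(cfg: SyntheticConfig, genome: Genome):
    """One peak per equal slot with a random offset: disjoint by design,
    with a >=100 bp margin for replicate jitter."""
    rng = cfg.rng("peaks")
    lmin, lmax = cfg.peak_len_range
    margin = 100
    n_per = _split_counts(cfg.n_true_peaks, [l for _, l in genome.chromosomes])
    peaks, labels = [], {}
    cluster_cycle = np.tile(
        [f"C{i + 1}" for i in range(cfg.n_clusters)],
        cfg.n_true_peaks // cfg.n_clusters + 1,
    )[: cfg.n_true_peaks]
    rng.shuffle(cluster_cycle)
    idx = 0
    for (chrom, L), n_c in zip(genome.chromosomes, n_per):
        if n_c == 0:
            continue
        slot = L // n_c
        if slot <= lmax + 2 * margin:
            raise ValueError(
                "infeasible packing: peaks (plus jitter margin) exceed genome"
            )
        for s in range(n_c):
            length = int(rng.integers(lmin, lmax + 1))
            start = s * slot + int(rng.integers(margin, slot - length - margin))
            third = max(1, length // 3)
            summit = length // 2 + int(rng.integers(-third // 2, third // 2 + 1))
            name = f"peak{idx:04d}"
            peaks.append(
                GenomicInterval(chrom, start, start + length, name, None, ".", summit)
            )
            labels[name] = str(cluster_cycle[idx])
            idx += 1
    return GenomicIntervalSet(genome, peaks), labels


def _split_counts(n: int, weights: list[int]) -> list[int]:
    total = sum(weights)
    counts = [n * w // total for w in weights]
    for i in range(n - sum(counts)):
        counts[i % len(counts)] += 1
    return counts


def _make_replicates(cfg: SyntheticConfig, genome: Genome,
                     true_peaks: GenomicIntervalSet):
    rng = cfg.rng("replicates")
    lengths = genome.lengths
    reps = []
    for r in range(3):
        ivs = []
        for iv in true_peaks:
            if rng.uniform() < cfg.replicate_dropout_p:
                continue
            L = lengths[iv.chrom]
            s = iv.start + int(round(rng.normal(0, cfg.replicate_jitter_sd)))
            e = iv.end + int(round(rng.normal(0, cfg.replicate_jitter_sd)))
            s = max(0, min(s, L - 2))
            e = max(s + 1, min(e, L))
            summit = min(max(iv.effective_summit() - s, 0), e - s - 1)
            ivs.append(
                GenomicInterval(iv.chrom, s, e, f"rep{r + 1}_{iv.name}", None, ".", summit)
            )
        lmin, lmax = cfg.peak_len_range
        for j in range(cfg.noise_peaks_per_replicate):
            chrom, L = genome.chromosomes[int(rng.integers(0, cfg.n_chrom))]
            length = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(0, L - length))
            ivs.append(
                GenomicInterval(
                    chrom, start, start + length, f"rep{r + 1}_noise{j:03d}",
                    None, ".", length // 2,
                )
            )
        reps.append(GenomicIntervalSet(genome, ivs))
    return reps


def _make_segmentation(cfg: SyntheticConfig, genome: Genome,
                       true_peaks: GenomicIntervalSet, labels):
    """Exact partition: one labeled block per peak (cluster-matched state,
    padded 50 bp) and background blocks elsewhere."""
    rng = cfg.rng("segmentation")
    bg_states = list(DEFAULT_PALETTE)
    # genome-wide background skews to quiet states
    bg_p = np.array([2, 2, 1, 2, 3, 2, 4, 6, 6, 14, 3], dtype=float)
    bg_p /= bg_p.sum()
    pad = 50
    segs = []

    def fill(chrom, lo, hi):
        pos = lo
        while pos < hi:
            blen = min(int(rng.integers(1000, 10000)), hi - pos)
            state = bg_states[int(rng.choice(len(bg_states), p=bg_p))]
            segs.append(GenomicInterval(chrom, pos, pos + blen, state))
            pos += blen

    by_chrom = true_peaks.by_chrom()
    for chrom, L in genome.chromosomes:
        pos = 0
        for iv in by_chrom.get(chrom, []):
            lo, hi = max(0, iv.start - pad), min(L, iv.end + pad)
            if lo > pos:
                fill(chrom, pos, lo)
            segs.append(GenomicInterval(chrom, lo, hi, CLUSTER_STATE[labels[iv.name]]))
            pos = hi
        if pos < L:
            fill(chrom, pos, L)
    return SegmentationTrack(genome, GenomicIntervalSet(genome, segs))


def _make_signals(cfg: SyntheticConfig, genome: Genome,
                  true_peaks: GenomicIntervalSet, labels):
    """Gaussian-bump-plus-noise tracks at 25 bp resolution, one archetype
    pattern per planted cluster."""
    rng = cfg.rng("signals")
    res = 25
    dense = {
        t: {c: rng.gamma(1.0, 0.2, size=-(-L // res)) for c, L in genome.chromosomes}
        for t in TRACK_NAMES
    }
    for iv in true_peaks:
        narrow, broad = ARCHETYPES[labels[iv.name]]
        for tname in narrow:
            _add_bump(dense[tname][iv.chrom], rng, iv.effective_summit() / res,
                      sd=150 / res, amp=rng.normal(8.0, 1.0))
        for tname in broad:
            _add_bump(dense[tname][iv.chrom], rng, iv.center / res,
                      sd=800 / res, amp=rng.normal(5.0, 0.6))
    return {
        t: SignalTrack.from_dense(genome, per_chrom, bin_bp=res)
        for t, per_chrom in dense.items()
    }


def _add_bump(arr: np.ndarray, rng, center: float, sd: float, amp: float):
    amp = max(0.5, amp)
    lo = max(0, int(center - 4 * sd))
    hi = min(arr.size, int(center + 4 * sd) + 1)
    x = np.arange(lo, hi)
    arr[lo:hi] += amp * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _make_sequence(cfg: SyntheticConfig, genome: Genome,
                   true_peaks: GenomicIntervalSet):
    rng = cfg.rng("sequence")
    gc = cfg.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {}
    for chrom, L in genome.chromosomes:
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L, p=p)
        seqs[chrom] = arr
    # motif embedding uses its own stream
    mrng = cfg.rng("motif")
    pwm = BUILTIN_PWMS["MYB-like"]
    positions: dict[str, int | None] = {}
    for iv in true_peaks:
        if mrng.uniform() >= cfg.motif_embed_p:
            positions[iv.name] = None
            continue
        if cfg.motif_pwm_sampled:
            motif = "".join(
                "ACGT"[int(mrng.choice(4, p=row))] for row in pwm.matrix
            )
        else:
            motif = pwm.consensus
        if mrng.uniform() < 0.5:
            motif = reverse_complement(motif)
        offset = int(mrng.integers(-10, 11))
        pos = iv.effective_summit() + offset - len(motif) // 2
        pos = max(iv.start, min(pos, iv.end - len(motif)))
        seqs[iv.chrom][pos : pos + len(motif)] = np.frombuffer(
            motif.encode(), dtype=np.uint8
        )
        positions[iv.name] = pos - iv.start
    return {c: a.tobytes().decode("ascii") for c, a in seqs.items()}, positions


def _make_genes_and_rems(cfg: SyntheticConfig, genome: Genome,
                         true_peaks: GenomicIntervalSet):
    """Plant gene classes and their REM linkage.

    All pioneer genes and half the non-pioneer genes are linked to a
    distinct true peak through a REM element that overlaps it; the other
    half of the non-pioneer genes is deliberately unlinked (indirect
    targets), with REMs rejected against a padded union of true peaks.
    Unaffected genes fill the remaining peaks and some unlinked slots.
    """
    rng = cfg.rng("rems")
    n_peaks = len(true_peaks)
    peak_order = rng.permutation(n_peaks)
    gene_class: dict[str, str] = {}
    genes: list[Gene] = []
    elements: list[GenomicInterval] = []
    links: dict[str, set[str]] = {}
    lengths = genome.lengths

    pad = 250  # keep unlinked REMs clear of jittered replicate peaks
    forbidden = {
        chrom: np.array([(iv.start - pad, iv.end + pad) for iv in ivs])
        for chrom, ivs in true_peaks.by_chrom().items()
    }

    def overlaps_peak(chrom, start, end):
        arr = forbidden.get(chrom)
        if arr is None or arr.size == 0:
            return False
        j = np.searchsorted(arr[:, 1], start, side="right")
        return j < len(arr) and arr[j, 0] < end

    def random_clear_interval(length):
        for _ in range(200):
            chrom, L = genome.chromosomes[int(rng.integers(0, cfg.n_chrom))]
            start = int(rng.integers(0, L - length))
            if not overlaps_peak(chrom, start, start + length):
                return chrom, start, start + length
        raise RuntimeError("could not place a peak-free REM element")

    n_linked_nonpioneer = cfg.n_nonpioneer // 2
    n_unaffected = cfg.n_genes - cfg.n_pioneer - cfg.n_nonpioneer
    n_linked_unaffected = min(
        n_unaffected // 2, n_peaks - cfg.n_pioneer - n_linked_nonpioneer
    )
    n_linked_unaffected = max(0, n_linked_unaffected)

    roster = (
        [("pioneer", True)] * cfg.n_pioneer
        + [("non-pioneer", True)] * n_linked_nonpioneer
        + [("non-pioneer", False)] * (cfg.n_nonpioneer - n_linked_nonpioneer)
        + [("unaffected", True)] * n_linked_unaffected
        + [("unaffected", False)] * (n_unaffected - n_linked_unaffected)
    )
    peak_cursor = 0
    for g_idx, (klass, linked) in enumerate(roster):
        gid = f"gene{g_idx:04d}"
        gene_class[gid] = klass
        strand = "+" if rng.uniform() < 0.5 else "-"
        if linked and peak_cursor < n_peaks:
            iv = true_peaks[int(peak_order[peak_cursor])]
            peak_cursor += 1
            grow = int(rng.integers(0, 100))
            start = max(0, iv.start - grow)
            end = min(lengths[iv.chrom], iv.end + grow)
            elements.append(GenomicInterval(iv.chrom, start, end, gid))
            links.setdefault(iv.name, set()).add(gid)
            tss = iv.effective_summit() + int(rng.integers(-500, 501))
            chrom = iv.chrom
        else:
            length = int(rng.integers(300, 1500))
            chrom, start, end = random_clear_interval(length)
            elements.append(GenomicInterval(chrom, start, end, gid))
            tss = (start + end) // 2
        # additional distal (peak-free) elements for the same gene
        for _ in range(int(rng.integers(0, 2))):
            length = int(rng.integers(300, 1500))
            c2, s2, e2 = random_clear_interval(length)
            elements.append(GenomicInterval(c2, s2, e2, gid))
        span = int(rng.integers(5000, 20000))
        L = lengths[chrom]
        tss = max(0, min(tss, L - 2))
        if strand == "+":
            g_start, g_end = tss, min(L, tss + span)
        else:
            g_start, g_end = max(0, tss - span), tss + 1
        genes.append(Gene(gid, chrom, strand, tss, g_start, g_end))
    return (
        genes,
        GenomicIntervalSet(genome, elements),
        gene_class,
        links,
    )


def _make_expression(cfg: SyntheticConfig, gene_class: Mapping[str, str]):
    """Three contrasts per gene with planted significance patterns.

    Affected genes: |log2FC| ~ U(1,3), padj 1e-6; rescues oppose the KD
    sign; the mutant rescue is flat for pioneer genes.  Unaffected genes:
    log2FC ~ N(0, 0.1), padj 0.9.
    """
    rng = cfg.rng("expression")
    sig_p, null_p = 1e-6, 0.9
    if cfg.noisy_expression:
        sig_p, null_p = 1e-3, 0.3
    rows = []

    def flat():
        return float(rng.normal(0, 0.1)), null_p

    for gid, klass in gene_class.items():
        if klass == "unaffected":
            for contrast in ("KD_vs_ctrl", "WT_rescue_vs_KD", "D152V_rescue_vs_KD"):
                fc, p = flat()
                rows.append((gid, contrast, fc, p))
            continue
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        kd = sign * rng.uniform(1, 3)
        wt = -sign * rng.uniform(1, 3)
        rows.append((gid, "KD_vs_ctrl", float(kd), sig_p))
        rows.append((gid, "WT_rescue_vs_KD", float(wt), sig_p))
        if klass == "pioneer":
            fc, p = flat()
            rows.append((gid, "D152V_rescue_vs_KD", fc, p))
        else:  # non-pioneer: mutant rescues too
            rows.append(
                (gid, "D152V_rescue_vs_KD", float(-sign * rng.uniform(1, 3)), sig_p)
            )
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc", "padj"])


def _make_partner(cfg: SyntheticConfig, genome: Genome,
                  true_peaks: GenomicIntervalSet):
    rng = cfg.rng("partner")
    lengths = genome.lengths
    ivs = []
    for i, iv in enumerate(true_peaks):
        length = int(rng.integers(150, 400))
        if rng.uniform() < cfg.coloc_p:
            # centred near the summit: overlap with the peak is guaranteed
            center = iv.effective_summit() + int(rng.integers(-50, 51))
            center = max(iv.start, min(center, iv.end - 1))
            start = max(0, center - length // 2)
        else:
            chrom, L = genome.chromosomes[int(rng.integers(0, cfg.n_chrom))]
            start = int(rng.integers(0, L - length))
            ivs.append(GenomicInterval(chrom, start, start + length, f"partner{i:04d}"))
            continue
        end = min(lengths[iv.chrom], start + length)
        ivs.append(GenomicInterval(iv.chrom, start, end, f"partner{i:04d}"))
    return GenomicIntervalSet(genome, ivs)


def _make_se_and_footprints(cfg: SyntheticConfig, genome: Genome,
                            true_peaks: GenomicIntervalSet, labels):
    se_rng = cfg.rng("se")
    fp_rng = cfg.rng("footprints")
    lengths = genome.lengths
    ses = []
    enhancer_peaks = [iv for iv in true_peaks if labels[iv.name] == "C2"]
    for i, iv in enumerate(enhancer_peaks):
        if se_rng.uniform() < 0.4:
            lo = max(0, iv.start - int(se_rng.integers(1000, 3000)))
            hi = min(lengths[iv.chrom], iv.end + int(se_rng.integers(1000, 3000)))
            ses.append(GenomicInterval(iv.chrom, lo, hi, f"SE{i:03d}"))
    for j in range(20):  # peak-free large domains
        chrom, L = genome.chromosomes[int(se_rng.integers(0, cfg.n_chrom))]
        length = int(se_rng.integers(8000, 25000))
        start = int(se_rng.integers(0, L - length))
        ses.append(GenomicInterval(chrom, start, start + length, f"SEbg{j:03d}"))

    fps = []
    for i, iv in enumerate(true_peaks):
        if fp_rng.uniform() < 0.3:
            s = iv.effective_summit()
            fps.append(
                GenomicInterval(iv.chrom, max(0, s - 10),
                                min(lengths[iv.chrom], s + 10), f"fp{i:04d}")
            )
    n_extra = max(1, len(fps))
    for j in range(n_extra):
        chrom, L = genome.chromosomes[int(fp_rng.integers(0, cfg.n_chrom))]
        start = int(fp_rng.integers(0, L - 20))
        fps.append(GenomicInterval(chrom, start, start + 20, f"fpbg{j:04d}"))
    return GenomicIntervalSet(genome, ses), GenomicIntervalSet(genome, fps)


def simulate(cfg: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate the full synthetic input bundle (deterministic per seed)."""
    cfg = cfg or SyntheticConfig()
    genome = Genome(
        [(f"chr{i + 1}", cfg.chrom_len) for i in range(cfg.n_chrom)]
    )
    true_peaks, labels = _place_true_peaks(cfg, genome)
    replicates = _make_replicates(cfg, genome, true_peaks)
    segmentation = _make_segmentation(cfg, genome, true_peaks, labels)
    signal_tracks = _make_signals(cfg, genome, true_peaks, labels)
    sequence, motif_positions = _make_sequence(cfg, genome, true_peaks)
    genes, rem_elements, gene_class, links = _make_genes_and_rems(
        cfg, genome, true_peaks
    )
    expression = _make_expression(cfg, gene_class)
    partner = _make_partner(cfg, genome, true_peaks)
    ses, fps = _make_se_and_footprints(cfg, genome, true_peaks, labels)
    truth = GroundTruth(true_peaks, labels, motif_positions, gene_class, links)
    return SyntheticBundle(
        cfg, genome, replicates, segmentation, signal_tracks, sequence,
        rem_elements, genes, expression, partner, ses, fps, truth,
    )


# ---------------------------------------------------------------------------
# On-disk materialization (text formats only)


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write every artifact under *outdir*; returns name -> path."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(p("genome.tsv"), "w") as fh:
        for chrom, L in bundle.genome.chromosomes:
            fh.write(f"{chrom}\t{L}\n")
    for i, rep in enumerate(bundle.replicates):
        write_bed(rep, p(f"replicate{i + 1}.narrowPeak"), narrowpeak=True)
    write_bed(bundle.truth.true_peaks, p("true_peaks.narrowPeak"), narrowpeak=True)
    write_bed(bundle.segmentation.segments, p("segmentation.bed"))
    for name, track in bundle.signal_tracks.items():
        write_bedgraph(track, p(f"{name}.bedgraph"))
    with open(p("genome.fa"), "w") as fh:
        for chrom, seq in bundle.sequence.items():
            fh.write(f">{chrom}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
    write_bed(bundle.rem_elements, p("rem_map.bed"))
    with open(p("genes.tsv"), "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tstart\tend\n")
        for g in bundle.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.start}\t{g.end}\n")
    bundle.expression.to_csv(p("expression.tsv"), sep="\t", index=False)
    write_bed(bundle.partner, p("partner.bed"))
    write_bed(bundle.super_enhancers, p("super_enhancers.bed"))
    write_bed(bundle.footprints, p("footprints.bed"))
    truth = bundle.truth
    with open(p("ground_truth.json"), "w") as fh:
        json.dump(
            {
                "peak_cluster_labels": truth.peak_cluster_labels,
                "motif_positions": truth.motif_positions,
                "gene_class": truth.gene_class,
                "peak_gene_links": {
                    k: sorted(v) for k, v in truth.peak_gene_links.items()
                },
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths
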