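"""End-to-end pipeline: consensus -> states -> clustering -> colocalization
-> motifs -> targets, with a YAML config, per-stage TSV/JSON artifacts and
a run manifest (parameters, seeds, input checksums).

Reruns with the same config are byte-identical: every random behaviour
takes an explicit seed from the config and no hidden global state is used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .coloc import bh_adjust, hierarchical_cluster, mc_coloc_test, pairwise_matrix
from .consensus import consensus_peaks
from .intervals import Genome, GenomicIntervalSet, read_bed, write_bed
from .motifs import BUILTIN_PWMS, enrich, extract_peak_sequences, make_background, read_jaspar
from .signals import (
    Gene,
    build_signal_matrix,
    category_fractions,
    categorize_peaks,
    kmeans_cluster,
    read_bedgraph,
)
from .states import assign_states, read_segmentation, state_distribution
from .targets import (
    REMMap,
    annotate_peaks,
    classify_targets,
    direct_target_report,
    genes_per_cluster,
    read_expression_table,
    setoverlap_report,
)

log = logging.getLogger("peakscape")

STAGES = ("consensus", "states", "cluster", "coloc", "motifs", "targets")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genome: str
    replicates: list[str]
    segmentation: str
    tracks: dict[str, str]
    fasta: str
    rem_map: str
    genes: str
    expression: str
    super_enhancers: str | None = None
    footprints: str | None = None
    partner: str | None = None
    pwms: str | None = None  # JASPAR file; built-in library when absent
    outdir: str = "peakscape_out"
    min_frac: float = 0.5
    k: int = 5
    flank_bp: int = 2000
    bin_bp: int = 50
    n_mc: int = 99
    alpha: float = 0.05
    threshold_frac: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "genome": self.genome,
            "segmentation": self.segmentation,
            "fasta": self.fasta,
            "rem_map": self.rem_map,
            "genes": self.genes,
            "expression": self.expression,
        }
        for i, rep in enumerate(self.replicates):
            paths[f"replicate{i + 1}"] = rep
        for name, p in self.tracks.items():
            paths[f"track:{name}"] = p
        for opt in ("super_enhancers", "footprints", "partner", "pwms"):
            if getattr(self, opt):
                paths[opt] = getattr(self, opt)
        return paths

    def validate(self) -> None:
        missing = [p for p in self.input_paths().values() if not os.path.exists(p)]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def read_genome_tsv(path) -> Genome:
    chroms = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split("\t")[:2]
                chroms.append((name, int(length)))
    return Genome(chroms)


def read_genes_tsv(path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t")
    return [
        Gene(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the report bundle also written to disk."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict[str, Any] = {}
    manifest = {
        "version": __version__,
        "parameters": {
            k: v
            for k, v in vars(cfg).items()
            if k != "outdir" and not isinstance(v, (list, dict))
        },
        "inputs": {k: _sha256(p) for k, p in sorted(cfg.input_paths().items())},
        "stages": [],
    }

    genome = read_genome_tsv(cfg.genome)
    stage = "setup"
    try:
        stage = "consensus"
        log.info("stage %s: %d replicates, min_frac=%g", stage, len(cfg.replicates), cfg.min_frac)
        reps = [read_bed(p, genome) for p in cfg.replicates]
        cres = consensus_peaks(reps, min_frac=cfg.min_frac)
        write_bed(cres.consensus, os.path.join(cfg.outdir, "consensus.narrowPeak"),
                  narrowpeak=True)
        with open(os.path.join(cfg.outdir, "venn.tsv"), "w") as fh:
            fh.write("replicates\tcount\n")
            for subset in sorted(cres.venn_counts, key=lambda s: (len(s), sorted(s))):
                key = "&".join(str(i + 1) for i in sorted(subset))
                fh.write(f"{key}\t{cres.venn_counts[subset]}\n")
        report["consensus"] = {
            "n_consensus": cres.n_consensus,
            "per_replicate_counts": cres.per_replicate_counts,
        }
        manifest["stages"].append(stage)

        stage = "states"
        log.info("stage %s", stage)
        seg = read_segmentation(cfg.segmentation, genome)
        assignment = assign_states(cres.consensus, seg)
        dist = state_distribution(assignment)
        pd.DataFrame(
            {
                "state": list(dist.per_state_count),
                "count": list(dist.per_state_count.values()),
                "fraction": [dist.per_state_fraction[s] for s in dist.per_state_count],
            }
        ).sort_values("state").to_csv(
            os.path.join(cfg.outdir, "state_distribution.tsv"), sep="\t", index=False
        )
        report["states"] = {
            "grouped_fraction": dist.grouped_fraction,
            "n": dist.n,
        }
        manifest["stages"].append(stage)

        stage = "cluster"
        log.info("stage %s: k=%d seed=%d", stage, cfg.k, cfg.seed)
        tracks = {n: read_bedgraph(p, genome) for n, p in cfg.tracks.items()}
        matrix = build_signal_matrix(
            cres.consensus, tracks, flank_bp=cfg.flank_bp, bin_bp=cfg.bin_bp,
            anchor="summit",
        )
        assign = kmeans_cluster(matrix, k=cfg.k, seed=cfg.seed)
        with open(os.path.join(cfg.outdir, "clusters.bed"), "w") as fh:
            for iv in cres.consensus:
                pid = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{assign.labels[pid]}\n")
        genes = read_genes_tsv(cfg.genes)
        cats = categorize_peaks(cres.consensus, genes)
        per_cluster = category_fractions(cats, assign.labels)
        report["cluster"] = {
            "k": cfg.k,
            "sizes": {
                c: sum(1 for v in assign.labels.values() if v == c)
                for c in sorted(set(assign.labels.values()))
            },
            "category_fractions": per_cluster,
        }
        manifest["stages"].append(stage)

        stage = "coloc"
        log.info("stage %s: n_mc=%d", stage, cfg.n_mc)
        named = {"peaks": cres.consensus}
        for opt in ("partner", "super_enhancers", "footprints"):
            if getattr(cfg, opt):
                named[opt] = read_bed(getattr(cfg, opt), genome)
        coloc_report = {}
        if len(named) >= 2:
            mat = pairwise_matrix(named, statistic="jaccard")
            mat.to_csv(os.path.join(cfg.outdir, "jaccard_matrix.tsv"), sep="\t")
            tree = hierarchical_cluster(mat)
            with open(os.path.join(cfg.outdir, "jaccard_tree.nwk"), "w") as fh:
                fh.write(tree.newick + "\n")
            rows = []
            for name, s in named.items():
                if name == "peaks":
                    continue
                res = mc_coloc_test(
                    s, named["peaks"], genome, statistic="tetrachoric",
                    n_mc=cfg.n_mc, seed=cfg.seed,
                )
                rows.append(
                    {
                        "query": name,
                        "coefficient": res.coefficient,
                        "overlap_bp": res.overlap_bp,
                        "p": res.p_value,
                    }
                )
            if rows:
                df = pd.DataFrame(rows)
                df["p_adj"] = bh_adjust(df["p"].tolist())
                df.to_csv(
                    os.path.join(cfg.outdir, "colocalization.tsv"),
                    sep="\t", index=False,
                )
                coloc_report = df.set_index("query")["p_adj"].to_dict()
        report["coloc"] = coloc_report
        manifest["stages"].append(stage)

        stage = "motifs"
        log.info("stage %s: threshold_frac=%g", stage, cfg.threshold_frac)
        fasta = Fasta(cfg.fasta)
        target_seqs = extract_peak_sequences(cres.consensus, fasta)
        bg_seqs = make_background(
            target_seqs, n=2 * len(target_seqs), seed=cfg.seed, mode="shuffle"
        )
        pwms = (
            read_jaspar(cfg.pwms) if cfg.pwms else list(BUILTIN_PWMS.values())
        )
        rows = enrich(target_seqs, bg_seqs, pwms, threshold_frac=cfg.threshold_frac)
        pd.DataFrame(
            [
                {
                    "motif": r.motif,
                    "target_hits": r.target_hits,
                    "target_total": r.target_total,
                    "target_pct": r.target_pct,
                    "bg_hits": r.bg_hits,
                    "bg_total": r.bg_total,
                    "bg_pct": r.bg_pct,
                    "p": r.p,
                    "p_adj": r.p_adj,
                }
                for r in rows
            ]
        ).to_csv(os.path.join(cfg.outdir, "motif_enrichment.tsv"), sep="\t",
                 index=False)
        report["motifs"] = {
            "top_motif": rows[0].motif,
            "threshold_frac": cfg.threshold_frac,
            "n_motifs": len(rows),
        }
        manifest["stages"].append(stage)

        stage = "targets"
        log.info("stage %s: alpha=%g", stage, cfg.alpha)
        rems = REMMap(read_bed(cfg.rem_map, genome))
        peak_to_genes, gene_to_peaks = annotate_peaks(cres.consensus, rems)
        expr = read_expression_table(cfg.expression)
        classification = classify_targets(expr, alpha=cfg.alpha)
        direct = direct_target_report(classification, gene_to_peaks)
        direct.to_csv(os.path.join(cfg.outdir, "direct_targets.tsv"), sep="\t",
                      index=False)
        overlap_reports = []
        for opt in ("super_enhancers", "footprints"):
            if getattr(cfg, opt):
                overlap_reports.append(
                    setoverlap_report(cres.consensus, named[opt], opt)
                )
        pd.DataFrame(overlap_reports).to_csv(
            os.path.join(cfg.outdir, "set_overlaps.tsv"), sep="\t", index=False
        )
        cluster_genes, subset_counts = genes_per_cluster(assign.labels, gene_to_peaks)
        report["targets"] = {
            "direct": direct.to_dict(orient="records"),
            "set_overlaps": overlap_reports,
            "genes_per_cluster": {c: len(g) for c, g in sorted(cluster_genes.items())},
        }
        manifest["stages"].append(stage)
    except Exception as exc:  # abort with stage name and cause
        raise PipelineError(stage, exc) from exc

    report["manifest"] = manifest
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return report
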