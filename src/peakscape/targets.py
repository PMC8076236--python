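"""Peak-to-gene linkage through a regulatory-element (REM) map and
classification of knockdown/rescue-responsive genes.

A gene is *responsive* when its knockdown contrast is significant.  Among
responsive genes, rescue by the wild-type construct but not the
pioneering-deficient mutant defines a *pioneer* gene; rescue by both
defines a *non-pioneer* gene.  "Rescued" requires both significance and a
log2FC opposing the knockdown change.  A responsive gene is a *direct*
target when at least one of its REM elements overlaps a peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import floor
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GenomicIntervalSet, intersect

__all__ = [
    "CONTRASTS",
    "REMMap",
    "TargetClassification",
    "read_expression_table",
    "annotate_peaks",
    "classify_targets",
    "direct_target_report",
    "setoverlap_report",
    "genes_per_cluster",
    "round_half_up_pct",
]

CONTRASTS = ("KD_vs_ctrl", "WT_rescue_vs_KD", "D152V_rescue_vs_KD")


class REMMap:
    """Regulatory elements, each labeled with exactly one target gene."""

    def __init__(self, elements: GenomicIntervalSet):
        for iv in elements:
            if not iv.name:
                raise ValueError("every REM element needs a gene_id name")
        self.elements = elements

    @property
    def genome(self):
        return self.elements.genome

    def genes(self) -> set[str]:
        return {iv.name for iv in self.elements}


def read_expression_table(path) -> pd.DataFrame:
    """TSV with header gene_id/contrast/log2fc/padj; one row per
    gene x contrast."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "contrast", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    if df.duplicated(["gene_id", "contrast"]).any():
        raise ValueError("duplicate gene x contrast rows")
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("padj outside [0, 1]")
    return df


def _peak_id(iv) -> str:
    return iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"


def annotate_peaks(
    peaks: GenomicIntervalSet, rems: REMMap
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Link peaks and genes by >=1 bp overlap with labeled REM elements.

    Returns ``(peak_to_genes, gene_to_peaks)``; peaks without links are
    present with empty sets in the first map.
    """
    peak_to_genes: dict[str, set[str]] = {_peak_id(iv): set() for iv in peaks}
    gene_to_peaks: dict[str, set[str]] = {}
    for iv_peak, iv_rem, _ in intersect(peaks, rems.elements):
        pid = _peak_id(iv_peak)
        peak_to_genes[pid].add(iv_rem.name)
        gene_to_peaks.setdefault(iv_rem.name, set()).add(pid)
    return peak_to_genes, gene_to_peaks


@dataclass
class GeneCall:
    gene_id: str
    responsive: bool
    gene_class: str  # pioneer | non-pioneer | none
    direction: str | None  # activated | repressed (by the TF), if responsive
    direct: bool = False


@dataclass
class TargetClassification:
    calls: dict[str, GeneCall]
    alpha: float

    def by_class(self, gene_class: str) -> list[GeneCall]:
        return [c for c in self.calls.values() if c.gene_class == gene_class]

    def responsive_genes(self) -> list[str]:
        return [g for g, c in self.calls.items() if c.responsive]


def classify_targets(expr: pd.DataFrame, alpha: float = 0.05) -> TargetClassification:
    """Classify genes as pioneer / non-pioneer / none from the three
    knockdown/rescue contrasts.

    A gene is responsive when padj(KD) < alpha.  A rescue contrast counts
    as rescue when it is significant *and* its log2FC opposes the KD
    log2FC.  Pioneer: rescued by WT, not by the mutant; non-pioneer:
    rescued by both.  Direction: genes down after KD are "activated" by
    the TF, genes up are "repressed".  Genes missing a contrast are
    excluded with a warning.
    """
    wide_fc = expr.pivot(index="gene_id", columns="contrast", values="log2fc")
    wide_p = expr.pivot(index="gene_id", columns="contrast", values="padj")
    calls: dict[str, GeneCall] = {}
    skipped = []
    for gene in wide_fc.index:
        if any(
            c not in wide_fc.columns
            or pd.isna(wide_fc.loc[gene, c])
            or pd.isna(wide_p.loc[gene, c])
            for c in CONTRASTS
        ):
            skipped.append(gene)
            continue
        kd_fc = wide_fc.loc[gene, "KD_vs_ctrl"]
        responsive = wide_p.loc[gene, "KD_vs_ctrl"] < alpha
        gene_class, direction = "none", None
        if responsive:
            direction = "activated" if kd_fc < 0 else "repressed"

            def rescued(contrast: str) -> bool:
                return (
                    wide_p.loc[gene, contrast] < alpha
                    and wide_fc.loc[gene, contrast] * kd_fc < 0
                )

            wt, mut = rescued("WT_rescue_vs_KD"), rescued("D152V_rescue_vs_KD")
            if wt and not mut:
                gene_class = "pioneer"
            elif wt and mut:
                gene_class = "non-pioneer"
        calls[gene] = GeneCall(gene, bool(responsive), gene_class, direction)
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene(s) missing a contrast were excluded",
            stacklevel=2,
        )
    return TargetClassification(calls, alpha)


def round_half_up_pct(numerator: int, denominator: int) -> int:
    """Integer percent, rounding halves up (5/8 -> 63, 1/8 -> 13)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return int(floor(100 * numerator / denominator + 0.5))


def direct_target_report(
    classification: TargetClassification,
    gene_to_peaks: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Per class: total genes, genes with >=1 linked peak, integer percent.

    An empty class reports percent NA.  Also marks each call's ``direct``
    flag in place.
    """
    for call in classification.calls.values():
        call.direct = bool(gene_to_peaks.get(call.gene_id))
    rows = []
    for gene_class in ("pioneer", "non-pioneer"):
        members = classification.by_class(gene_class)
        n_total = len(members)
        n_direct = sum(c.direct for c in members)
        pct = round_half_up_pct(n_direct, n_total) if n_total else pd.NA
        rows.append(
            {
                "class": gene_class,
                "n_total": n_total,
                "n_direct": n_direct,
                "n_indirect": n_total - n_direct,
                "percent_direct": pct,
            }
        )
    return pd.DataFrame(rows)


def setoverlap_report(
    peaks: GenomicIntervalSet, other: GenomicIntervalSet, label: str
) -> dict:
    """How many elements of *other* share >=1 bp with any peak.

    Mirrors element-wise overlap reporting for auxiliary sets (e.g. super-
    enhancers, digital footprints): total, overlapped, not overlapped and
    round-half-up integer percent.
    """
    if len(other) == 0:
        raise ValueError("empty comparison set")
    hit = {
        (iv_o.chrom, iv_o.start, iv_o.end, iv_o.name)
        for _, iv_o, _ in intersect(peaks, other)
    }
    n_overlapped = sum(
        (iv.chrom, iv.start, iv.end, iv.name) in hit for iv in other
    )
    total = len(other)
    return {
        "label": label,
        "n_total": total,
        "n_overlapped": n_overlapped,
        "n_not_overlapped": total - n_overlapped,
        "percent_overlapped": round_half_up_pct(n_overlapped, total),
    }


def genes_per_cluster(
    labels: Mapping[str, str],
    gene_to_peaks: Mapping[str, set[str]],
) -> tuple[dict[str, set[str]], dict[frozenset, int]]:
    """Gene sets per cluster label and upset-style exact-membership counts.

    A gene belongs to cluster c when >=1 of its linked peaks is labeled c;
    genes can belong to several clusters.  The second return maps each
    non-empty cluster subset to the number of genes whose membership is
    exactly that subset.
    """
    cluster_genes: dict[str, set[str]] = {}
    membership: dict[str, frozenset] = {}
    for gene, peak_ids in gene_to_peaks.items():
        clusters = frozenset(
            labels[p] for p in peak_ids if p in labels
        )
        if not clusters:
            continue
        membership[gene] = clusters
        for c in clusters:
            cluster_genes.setdefault(c, set()).add(gene)
    subset_counts: dict[frozenset, int] = {}
    for clusters in membership.values():
        subset_counts[clusters] = subset_counts.get(clusters, 0) + 1
    return cluster_genes, subset_counts
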