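"""Genomic-feature classification of peaks and CGI partitioning.

Region definitions, as signed offsets in the direction of transcription
(negative = upstream of the TSS):

* core promoter: peak midpoint offset in [-3000, +2000] around the TSS
* downstream extremity: offset-from-TES in [-2000, +3000]
* exon / intron: midpoint inside the assigned gene's transcript span
* distal: offset in [-50000, -3000)
* intergenic: beyond 50 kb upstream of every gene (and in no other class)

Categories are mutually exclusive and tested in the priority order
core_promoter -> downstream_extremity -> exon -> intron -> distal ->
intergenic.  The peak anchor is its midpoint; the assigned gene is the one
with the nearest TSS (ties broken by smaller gene_id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomeModel, GenomicInterval, overlaps

CATEGORIES = (
    "core_promoter",
    "downstream_extremity",
    "exon",
    "intron",
    "distal",
    "intergenic",
)


@dataclass(frozen=True)
class FeatureClassification:
    peak: GenomicInterval
    category: str
    assigned_gene: str | None
    signed_offset: int | None


@dataclass
class CGIPartition:
    cgi_peaks: list[GenomicInterval]
    non_cgi_peaks: list[GenomicInterval]

    @property
    def cgi_fraction(self) -> float:
        total = len(self.cgi_peaks) + len(self.non_cgi_peaks)
        return len(self.cgi_peaks) / total if total else float("nan")


def signed_offset_from(position: int, anchor: int, strand: str) -> int:
    """Offset of ``position`` from ``anchor`` in the direction of transcription."""
    return position - anchor if strand == "+" else anchor - position


def classify_peak(peak: GenomicInterval, genome: GenomeModel) -> FeatureClassification:
    """Assign the peak to exactly one genomic-feature category."""
    if not genome.genes:
        raise ValueError("genome model has no genes")
    mid = peak.midpoint
    same_chrom = [g for g in genome.genes if g.chrom == peak.chrom]
    if not same_chrom:
        return FeatureClassification(peak, "intergenic", None, None)
    gene = min(same_chrom, key=lambda g: (abs(mid - g.tss), g.gene_id))
    off_tss = signed_offset_from(mid, gene.tss, gene.strand)
    off_tes = signed_offset_from(mid, gene.tes, gene.strand)

    if -3000 <= off_tss <= 2000:
        category = "core_promoter"
    elif -2000 <= off_tes <= 3000:
        category = "downstream_extremity"
    else:
        lo, hi = min(gene.tss, gene.tes), max(gene.tss, gene.tes)
        inside = lo <= mid <= hi
        if inside and any(e.start <= mid < e.end for e in gene.exons):
            category = "exon"
        elif inside:
            category = "intron"
        elif -50000 <= off_tss < -3000:
            category = "distal"
        else:
            category = "intergenic"
    assigned = None if category == "intergenic" else gene.gene_id
    offset = None if category == "intergenic" else off_tss
    return FeatureClassification(peak, category, assigned, offset)


def classify_peaks(peaks: list[GenomicInterval], genome: GenomeModel) -> list[FeatureClassification]:
    return [classify_peak(p, genome) for p in peaks]


def partition_by_cgi(
    peaks: list[GenomicInterval], cgis: list[GenomicInterval]
) -> CGIPartition:
    """Split peaks into CGI-overlapping and non-CGI sets (>= 1 shared base)."""
    cgi_peaks, non_cgi = [], []
    for p in peaks:
        (cgi_peaks if any(overlaps(p, c) for c in cgis) else non_cgi).append(p)
    return CGIPartition(cgi_peaks=cgi_peaks, non_cgi_peaks=non_cgi)


def peak_width_distribution(
    peaks: list[GenomicInterval], bin_edges: np.ndarray | None = None
) -> dict:
    """Median/IQR plus a fixed-bin histogram of peak widths (end - start)."""
    if not peaks:
        return {"n": 0}
    widths = np.array([p.width for p in peaks], dtype=float)
    if bin_edges is None:
        bin_edges = np.arange(0, 2050, 50)
    counts, edges = np.histogram(widths, bins=bin_edges)
    q25, q50, q75 = np.percentile(widths, [25, 50, 75])
    return {
        "n": len(widths),
        "median": float(q50),
        "iqr": (float(q25), float(q75)),
        "hist_counts": counts,
        "hist_edges": edges,
    }


def promoter_subset(classifications: list[FeatureClassification]) -> list[GenomicInterval]:
    """Peaks classified as core_promoter (the TSS-proximal subset)."""
    return [c.peak for c in classifications if c.category == "core_promoter"]
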