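"""Readers/writers for the plain-text interchange formats the pipeline uses.

BED3+ for peaks and CGIs, a UCSC-style tab-separated gene-model table
(txStart/txEnd converted to TSS/TES by strand), FASTA via Biopython, and a
minimal 4-row count-matrix PWM format::

    >p53_half_site
    6 6 6 0 0 0 0 0 0 0    (A row)
    ...                    (C, G, T rows)
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .intervals import GeneRecord, GenomeModel, GenomicInterval, Peak


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file; name/score columns are tolerated and ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def read_peaks_bed(path: str | os.PathLike, condition: str, replicate: int) -> list[Peak]:
    """Read a peak BED; column 5 (score) is used when present."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            peaks.append(Peak(iv, score=score, condition=condition, replicate=replicate))
    return peaks


def write_bed(
    path: str | os.PathLike,
    intervals: Iterable[GenomicInterval],
    names: Iterable[str] | None = None,
    scores: Iterable[float] | None = None,
) -> None:
    ivs = list(intervals)
    names_l = list(names) if names is not None else ["."] * len(ivs)
    scores_l = list(scores) if scores is not None else [0.0] * len(ivs)
    with open(path, "w") as fh:
        for iv, nm, sc in zip(ivs, names_l, scores_l):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t{sc:g}\t{iv.strand}\n")


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "txStart", "txEnd", "exonStarts", "exonEnds"]


def read_gene_table(path: str | os.PathLike) -> list[GeneRecord]:
    """Read a UCSC-style gene table into strand-resolved :class:`GeneRecord` s.

    txStart/txEnd are genomic (txStart < txEnd).  Conversion: on the + strand
    TSS = txStart and TES = txEnd - 1; on the - strand TSS = txEnd - 1 and
    TES = txStart (TSS/TES are single base positions, 0-based).
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        tx_start, tx_end = int(row.txStart), int(row.txEnd)
        if row.strand == "+":
            tss, tes = tx_start, tx_end - 1
        else:
            tss, tes = tx_end - 1, tx_start
        exons: tuple[GenomicInterval, ...] = ()
        if isinstance(row.exonStarts, str) and row.exonStarts.strip(","):
            starts = [int(x) for x in row.exonStarts.strip(",").split(",")]
            ends = [int(x) for x in row.exonEnds.strip(",").split(",")]
            exons = tuple(GenomicInterval(row.chrom, s, e) for s, e in zip(starts, ends))
        probes: tuple[str, ...] = ()
        if hasattr(row, "probe_ids") and isinstance(row.probe_ids, str) and row.probe_ids:
            probes = tuple(row.probe_ids.split(","))
        genes.append(
            GeneRecord(str(row.gene_id), row.chrom, row.strand, tss, tes, exons, probes)
        )
    return genes


def write_gene_table(path: str | os.PathLike, genes: Iterable[GeneRecord]) -> None:
    rows = []
    for g in genes:
        tx_start = min(g.tss, g.tes)
        tx_end = max(g.tss, g.tes) + 1
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "txStart": tx_start,
                "txEnd": tx_end,
                "exonStarts": ",".join(str(e.start) for e in g.exons),
                "exonEnds": ",".join(str(e.end) for e in g.exons),
                "probe_ids": ",".join(g.probe_ids),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genome_model(
    genes_path: str | os.PathLike,
    cgis_path: str | os.PathLike | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomeModel:
    genes = read_gene_table(genes_path)
    cgis = read_bed(cgis_path) if cgis_path is not None else []
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            hi = max(g.tss, g.tes) + 1
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), hi + 200_000)
        for c in cgis:
            chrom_sizes[c.chrom] = max(chrom_sizes.get(c.chrom, 0), c.end)
    return GenomeModel(genes=genes, cgis=cgis, chrom_sizes=chrom_sizes)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_pwm_counts(path: str | os.PathLike) -> tuple[str, np.ndarray]:
    """Read a ``>motif_id`` header plus 4 whitespace-separated rows (A,C,G,T)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("PWM file must start with a '>motif_id' header line")
    motif_id = lines[0][1:].strip()
    rows = [[float(x) for x in ln.split()] for ln in lines[1:5]]
    counts = np.array(rows, dtype=float)
    if counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ValueError("PWM must have 4 rows (A,C,G,T) and >=1 column")
    return motif_id, counts
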