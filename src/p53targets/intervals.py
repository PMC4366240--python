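"""Genomic interval primitives and the gene/CGI coordinate frame.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Signed promoter offsets (upstream negative, in the direction of transcription)
are computed at annotation time; nothing in this module is strand-aware except
the ``GeneRecord`` TSS/TES bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded); it is carried but
    ignored by :func:`overlaps` and :func:`merge_intervals`.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A peak-caller call with condition/replicate provenance."""

    interval: GenomicInterval
    score: float = 0.0
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("peak score must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate id must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    """One gene model: TSS/TES are strand-resolved transcript ends.

    On the + strand ``tss < tes``; on the - strand ``tss > tes``.  Exons are
    plain genomic intervals lying within the transcript span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[GenomicInterval, ...] = ()
    probe_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.start < lo or ex.end > hi + 1:
                raise ValueError(f"{self.gene_id}: exon {ex} outside transcript span")

    @property
    def span(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1, self.strand)


@dataclass
class GenomeModel:
    """Gene records plus CGI intervals plus chromosome sizes."""

    genes: list[GeneRecord] = field(default_factory=list)
    cgis: list[GenomicInterval] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and max(g.tss, g.tes) >= size:
                raise ValueError(f"{g.gene_id} extends beyond {g.chrom} ({size} bp)")
        for c in self.cgis:
            size = self.chrom_sizes.get(c.chrom)
            if size is not None and c.end > size:
                raise ValueError(f"CGI {c} extends beyond {c.chrom}")

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open spans share at least one base.

    Strand is ignored; intervals on different chromosomes never overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping (transitively chained) intervals into their union.

    Returns disjoint intervals sorted by (chrom, start).  Abutting half-open
    intervals ([0,10) and [10,20)) are coalesced: the result is the maximal
    runs of the per-base union, so it matches any bitmap representation of
    the same set of bases.  (The overlap *predicate* still requires a shared
    base; only the merged representation coalesces abutment.)
    """
    if not intervals:
        return []
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out
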