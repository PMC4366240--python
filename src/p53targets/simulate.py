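"""Toy-genome simulator with planted p53-bound / p53-responsive genes.

The generator emulates the data structure of a chronic-p53 study: four ChIP
conditions — normal growth (2 replicates) and three p53-activating states,
acute DNA damage (acDDR), RAS-induced senescence (RIS) and pro-apoptotic
E1A/RAS (pApo), 3 replicates each — plus a 3-vs-3 knockdown-vs-vector
expression contrast.  A configurable subset of genes is "bound" (receives
TSS-proximal peaks and enriched ChIP bin counts in the activated conditions)
and a subset is "responsive" (shifts log2 expression under knockdown);
direct targets are the bound AND responsive genes, drawn preferentially from
CGI-promoter genes to mirror the CGI association of chronically active p53.

Everything is deterministic under the config seed.  Read positions are
generated FROM the emitted count table (uniform within each gene's TSS
window), so recounting the reads reproduces the table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import BinCountTable, BinSpec, SampleInfo
from .intervals import GeneRecord, GenomeModel, GenomicInterval, Peak

CHRONIC_CONDITIONS = ("RIS", "pApo")
DEFAULT_CONDITIONS = (("Grow", 2), ("acDDR", 3), ("RIS", 3), ("pApo", 3))


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    gene_spacing: int = 120_000  # centre-to-centre; leaves room for distal/intergenic
    gene_length: int = 20_000
    cgi_promoter_fraction: float = 0.5
    conditions: tuple[tuple[str, int], ...] = DEFAULT_CONDITIONS
    n_expr_replicates: int = 3
    n_bound_genes: int = 250
    n_responsive_genes: int = 250
    n_target_genes: int = 150  # bound AND responsive, CGI-biased
    cgi_target_odds: float = 3.0
    frac_repressed: float = 0.3
    chip_mean_background: float = 20.0
    chip_fold_enrichment: float = 5.0
    nb_dispersion: float = 0.1
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.0
    expr_sd: float = 0.3
    expr_effect: float = 1.0
    peak_jitter_sd: float = 50.0
    peak_dropout_prob: float = 0.2
    decoy_fraction: float = 0.1
    seed: int = 20150319

    def __post_init__(self) -> None:
        if not 0 <= self.cgi_promoter_fraction <= 1:
            raise ValueError("cgi_promoter_fraction must be in [0,1]")
        if not 0 <= self.peak_dropout_prob <= 1:
            raise ValueError("peak_dropout_prob must be in [0,1]")
        if not 0 <= self.frac_repressed <= 1:
            raise ValueError("frac_repressed must be in [0,1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_bound_genes > self.n_genes or self.n_responsive_genes > self.n_genes:
            raise ValueError("bound/responsive counts cannot exceed n_genes")
        if self.n_target_genes > min(self.n_bound_genes, self.n_responsive_genes):
            raise ValueError("n_target_genes cannot exceed n_bound or n_responsive")

    @property
    def chrom_length(self) -> int:
        return self.gene_spacing * (self.n_genes + 1)


@dataclass
class TruthTable:
    """Planted per-gene ground truth."""

    table: pd.DataFrame  # index gene_id; bound, responsive, direction, is_target, promoter_class

    def __post_init__(self) -> None:
        t = self.table
        bad = t.loc[(t["direction"] != "none") != t["responsive"]]
        if len(bad):
            raise ValueError("direction must be none iff not responsive")

    @property
    def bound(self) -> pd.Index:
        return self.table.index[self.table["bound"]]

    @property
    def responsive(self) -> pd.Index:
        return self.table.index[self.table["responsive"]]

    @property
    def targets(self) -> pd.Index:
        return self.table.index[self.table["is_target"]]


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # stable sub-stream derivation (string hash must not vary across processes)
    import zlib

    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def simulate_genome(config: SimulationConfig) -> GenomeModel:
    """Place n_genes on one toy chromosome, alternating strands, CGIs at a
    configurable fraction of promoters."""
    spacing, length = config.gene_spacing, config.gene_length
    if spacing < length + 100_000:
        raise ValueError(
            f"gene_spacing {spacing} too small for gene_length {length}: need "
            ">= 100 kb flanks so distal and intergenic classes are realizable"
        )
    rng = _rng(config, "genome")
    genes: list[GeneRecord] = []
    cgis: list[GenomicInterval] = []
    n_cgi = int(round(config.cgi_promoter_fraction * config.n_genes))
    cgi_gene_idx = set(rng.choice(config.n_genes, size=n_cgi, replace=False).tolist())
    for i in range(config.n_genes):
        centre = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        lo, hi = centre - length // 2, centre + length // 2
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        # two exons at the transcript extremities, intron between
        ex1 = GenomicInterval("chrS", lo, lo + 2000)
        ex2 = GenomicInterval("chrS", hi - 2000, hi)
        genes.append(
            GeneRecord(
                gene_id=f"g{i:04d}",
                chrom="chrS",
                strand=strand,
                tss=tss,
                tes=tes,
                exons=(ex1, ex2),
                probe_ids=(f"p{i:04d}",),
            )
        )
        if i in cgi_gene_idx:
            # CGI overlapping [TSS-500, TSS+500)
            off = int(rng.integers(-200, 200))
            cgis.append(GenomicInterval("chrS", tss - 300 + off, tss + 300 + off))
    return GenomeModel(genes=genes, cgis=cgis, chrom_sizes={"chrS": config.chrom_length})


def _promoter_classes(genome: GenomeModel) -> pd.Series:
    from .intervals import overlaps

    classes = {}
    for g in genome.genes:
        window = GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500)
        has_cgi = any(overlaps(window, c) for c in genome.cgis)
        classes[g.gene_id] = "CGI" if has_cgi else "nonCGI"
    return pd.Series(classes, name="promoter_class")


def plant_truth(genome: GenomeModel, config: SimulationConfig) -> TruthTable:
    """Draw bound/responsive/target labels; targets prefer CGI promoters.

    Targets are sampled with per-gene weight ``cgi_target_odds`` for
    CGI-promoter genes versus 1 for the rest; the remaining bound-only and
    responsive-only quotas are filled uniformly from disjoint pools.
    """
    rng = _rng(config, "truth")
    classes = _promoter_classes(genome)
    gene_ids = np.array([g.gene_id for g in genome.genes])
    n = len(gene_ids)
    if config.n_bound_genes + config.n_responsive_genes - config.n_target_genes > n:
        raise ValueError("requested bound+responsive labels exceed the gene pool")

    weights = np.where(classes.loc[gene_ids].to_numpy() == "CGI", config.cgi_target_odds, 1.0)
    p = weights / weights.sum()
    targets = rng.choice(gene_ids, size=config.n_target_genes, replace=False, p=p)
    rest = np.setdiff1d(gene_ids, targets)
    rng.shuffle(rest)
    n_bound_only = config.n_bound_genes - config.n_target_genes
    n_resp_only = config.n_responsive_genes - config.n_target_genes
    bound_only = rest[:n_bound_only]
    resp_only = rest[n_bound_only : n_bound_only + n_resp_only]

    bound = pd.Series(False, index=gene_ids)
    bound[targets] = True
    bound[bound_only] = True
    responsive = pd.Series(False, index=gene_ids)
    responsive[targets] = True
    responsive[resp_only] = True

    direction = pd.Series("none", index=gene_ids)
    resp_ids = responsive.index[responsive].to_numpy()
    n_rep = int(round(config.frac_repressed * resp_ids.size))
    repressed = rng.choice(resp_ids, size=n_rep, replace=False)
    direction[resp_ids] = "induced"
    direction[repressed] = "repressed"

    table = pd.DataFrame(
        {
            "bound": bound,
            "responsive": responsive,
            "direction": direction,
            "is_target": bound & responsive,
            "promoter_class": classes.loc[gene_ids],
        }
    )
    return TruthTable(table)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2 via gamma-Poisson mixture."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, np.asarray(mean, dtype=float) * phi)
    return rng.poisson(lam)


def simulate_chip(
    genome: GenomeModel,
    truth: TruthTable,
    config: SimulationConfig,
    bin_spec: BinSpec = BinSpec(),
) -> tuple[dict[str, list[Peak]], dict[str, np.ndarray], BinCountTable]:
    """Per-replicate peak calls, per-sample read positions, and bin counts.

    Peaks: every bound gene gets one peak per replicate in each p53-active
    condition, centred near the TSS with Gaussian jitter and per-replicate
    dropout; decoy peaks (``decoy_fraction`` of gene count) land at random
    non-bound promoters in exactly one replicate.  The growing condition has
    background binding only (decoys).  Counts: ChIP bins of bound genes are
    NB(background x fold); everything else NB(background).  Reads are then
    placed uniformly inside each gene's TSS window to match the counts.
    """
    rng = _rng(config, "chip")
    gene_ids = truth.table.index.to_numpy()
    bound_mask = truth.table["bound"].to_numpy()
    gene_by_id = {g.gene_id: g for g in genome.genes}

    peaks: dict[str, list[Peak]] = {}
    for cond, n_reps in config.conditions:
        active = cond != "Grow"
        for rep in range(1, n_reps + 1):
            name = f"{cond}_rep{rep}"
            plist: list[Peak] = []
            if active:
                for gid in gene_ids[bound_mask]:
                    if rng.random() < config.peak_dropout_prob:
                        continue
                    g = gene_by_id[gid]
                    centre = int(g.tss + rng.normal(0, config.peak_jitter_sd))
                    width = max(50, int(rng.normal(200 + 4 * config.peak_jitter_sd,
                                                   config.peak_jitter_sd)))
                    start = max(0, centre - width // 2)
                    iv = GenomicInterval(g.chrom, start, start + width)
                    plist.append(Peak(iv, score=float(rng.uniform(50, 300)),
                                      condition=cond, replicate=rep))
            # decoy singletons: appear in exactly one replicate
            n_decoy = int(round(config.decoy_fraction * config.n_genes / max(n_reps, 1)))
            decoy_pool = gene_ids[~bound_mask]
            for gid in rng.choice(decoy_pool, size=n_decoy, replace=False):
                g = gene_by_id[gid]
                centre = int(g.tss + rng.normal(0, 4 * config.peak_jitter_sd))
                width = max(50, int(rng.normal(200, 50)))
                start = max(0, centre - width // 2)
                iv = GenomicInterval(g.chrom, start, start + width)
                plist.append(Peak(iv, score=float(rng.uniform(20, 80)),
                                  condition=cond, replicate=rep))
            peaks[name] = plist

    # bin counts, then reads from counts
    samples: dict[str, SampleInfo] = {}
    count_cols: dict[str, np.ndarray] = {}
    crng = _rng(config, "counts")
    for cond, n_reps in config.conditions:
        active = cond != "Grow"
        for rep in range(1, n_reps + 1):
            chip_name = f"chip_{cond}_rep{rep}"
            mean = np.full(len(gene_ids), config.chip_mean_background)
            if active:
                mean[bound_mask] *= config.chip_fold_enrichment
            count_cols[chip_name] = _nb_draw(crng, mean, config.nb_dispersion)
            samples[chip_name] = SampleInfo("chip", cond, rep)
            input_name = f"input_{cond}_rep{rep}"
            count_cols[input_name] = _nb_draw(
                crng, np.full(len(gene_ids), config.chip_mean_background), config.nb_dispersion
            )
            samples[input_name] = SampleInfo("input", cond, rep)
    counts = pd.DataFrame(count_cols, index=gene_ids)
    table = BinCountTable(counts=counts, samples=samples)

    rrng = _rng(config, "reads")
    reads: dict[str, np.ndarray] = {}
    windows = {g.gene_id: bin_spec.window(g) for g in genome.genes}
    for name in counts.columns:
        pos_chunks = []
        col = counts[name].to_numpy()
        for gid, c in zip(gene_ids, col):
            if c == 0:
                continue
            lo, hi = windows[gid]
            pos_chunks.append(rrng.integers(max(lo, 0), hi, size=int(c)))
        reads[name] = np.sort(np.concatenate(pos_chunks)) if pos_chunks else np.array([], dtype=int)
    return peaks, reads, table


def simulate_expression(
    genome: GenomeModel, truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vector-arm and knockdown-arm log2 intensity matrices (probes x reps).

    Responsive genes shift by ±expr_effect in the knockdown arm: induced
    targets DROP under knockdown (they needed p53), repressed targets RISE.
    """
    rng = _rng(config, "expr")
    probes = [g.probe_ids[0] for g in genome.genes]
    gene_ids = [g.gene_id for g in genome.genes]
    n = len(probes)
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=n)
    direction = truth.table.loc[gene_ids, "direction"].to_numpy()
    shift = np.where(direction == "induced", -config.expr_effect,
                     np.where(direction == "repressed", config.expr_effect, 0.0))
    k = config.n_expr_replicates
    vec = baseline[:, None] + rng.normal(0, config.expr_sd, size=(n, k))
    sh = (baseline + shift)[:, None] + rng.normal(0, config.expr_sd, size=(n, k))
    vec_df = pd.DataFrame(vec, index=probes, columns=[f"vector_{i+1}" for i in range(k)])
    sh_df = pd.DataFrame(sh, index=probes, columns=[f"shp53_{i+1}" for i in range(k)])
    return vec_df, sh_df


def plant_motif_sequences(
    n_sequences: int,
    length: int,
    motif: str,
    offsets: list[int] | None,
    seed: int,
) -> list[str]:
    """Uniform-background sequences with ``motif`` planted at given offsets.

    ``offsets`` gives the planting position per sequence; None plants
    uniformly at random.  Used by motif-scanning tests and the positional
    histogram demonstration (focused vs dispersed placements).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs = []
    for i in range(n_sequences):
        seq = rng.choice(bases, size=length)
        off = (
            offsets[i % len(offsets)]
            if offsets is not None
            else int(rng.integers(0, length - len(motif) + 1))
        )
        seq[off : off + len(motif)] = list(motif)
        seqs.append("".join(seq))
    return seqs
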