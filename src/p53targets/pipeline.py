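"""End-to-end driver: simulate -> consensus -> annotate -> DE -> enrichment
-> joint posterior, with evaluation against the planted truth.

This is the programmatic equivalent of the ``run-all`` command; each stage is
the corresponding module's public API, so the numbers it reports are the
pipeline's own outputs, not re-derivations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, consensus, de, enrichment, integrate, simulate
from .enrichment import BinSpec, NBModelParams
from .intervals import GenomeModel, overlaps
from .simulate import SimulationConfig, TruthTable

CHRONIC_DEFAULT = "RIS"


@dataclass
class PipelineResult:
    config: SimulationConfig
    genome: GenomeModel
    truth: TruthTable
    hc_sets: dict
    annotations: dict
    de_table: pd.DataFrame  # gene-level
    enrich_tables: dict[str, pd.DataFrame]
    rcade: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC (Mann-Whitney), ties handled by midranks."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def run_pipeline(
    config: SimulationConfig | None = None,
    condition: str = CHRONIC_DEFAULT,
    exclude_conditions: tuple[str, ...] = ("acDDR",),
    threshold: float = integrate.B_THRESHOLD,
) -> PipelineResult:
    """Run every stage on one simulated dataset and evaluate against truth.

    ``condition`` selects the ChIP condition whose enrichment posterior feeds
    the joint posterior; acDDR is excluded from integration by default (the
    acute condition's TSS-local signal is not the chronic-binding readout the
    joint model targets), but enrichment tables are computed for all
    non-excluded p53-active conditions.
    """
    config = config or SimulationConfig()
    genome = simulate.simulate_genome(config)
    truth = simulate.plant_truth(genome, config)
    peaks_by_rep, reads, counts = simulate.simulate_chip(genome, truth, config)
    expr_vec, expr_sh = simulate.simulate_expression(genome, truth, config)

    # consensus peaks per condition
    peaks_by_cond: dict[str, list] = {}
    for name, plist in peaks_by_rep.items():
        cond = name.rsplit("_rep", 1)[0]
        peaks_by_cond.setdefault(cond, []).extend(plist)
    hc_sets = consensus.build_hc_peakset(peaks_by_cond)

    # annotation of HC peaks
    annotations = {
        cond: annotate.classify_peaks(hc.peaks, genome) for cond, hc in hc_sets.items()
    }

    # expression arm
    de_probe = de.run_de(expr_vec, expr_sh)
    probe_to_gene = {g.probe_ids[0]: g.gene_id for g in genome.genes}
    de_gene = de.collapse_to_genes(de_probe, probe_to_gene)

    # ChIP arm
    norm = enrichment.normalize_counts(counts, method="quantile")
    params = NBModelParams(phi=enrichment.estimate_dispersion(counts))
    enrich_tables = {}
    active = [c for c, _ in config.conditions if c != "Grow" and c not in exclude_conditions]
    for cond in active:
        enrich_tables[cond] = enrichment.enrichment_posterior(
            norm, params=params, condition=cond, seed=config.seed % (2**31 - 1),
            estimate_pi=True,
        )

    rcade = integrate.integrate(de_gene, enrich_tables[condition], threshold=threshold)

    result = PipelineResult(
        config=config,
        genome=genome,
        truth=truth,
        hc_sets=hc_sets,
        annotations=annotations,
        de_table=de_gene,
        enrich_tables=enrich_tables,
        rcade=rcade,
    )
    result.metrics = evaluate(result, condition=condition)
    return result


def evaluate(result: PipelineResult, condition: str = CHRONIC_DEFAULT) -> dict:
    """Headline metrics of one pipeline run against the planted truth."""
    truth = result.truth.table
    rcade = result.rcade
    aligned = truth.loc[rcade.index]
    is_target = aligned["is_target"].to_numpy()

    # finite surrogate for ranking: p_joint is monotone in B and bounded
    roc = auroc(rcade["p_joint"].to_numpy(), is_target)
    called = set(rcade.index[rcade["pass"]])
    true_targets = set(result.truth.targets)
    tp = len(called & true_targets)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(true_targets) if true_targets else float("nan")

    bound_only = aligned["bound"] & ~aligned["responsive"]
    resp_only = aligned["responsive"] & ~aligned["bound"]
    b_finite = np.clip(rcade["B"].to_numpy(), -745.0, 745.0)
    median_b = {
        "targets": float(np.median(b_finite[is_target])),
        "bound_only": float(np.median(b_finite[bound_only.to_numpy()])),
        "responsive_only": float(np.median(b_finite[resp_only.to_numpy()])),
    }

    # HC recovery of planted bound loci in each chronic condition
    hc_recovery = {}
    bound_tss = [
        result.genome.gene(g).tss for g in result.truth.bound
    ]
    for cond in ("RIS", "pApo"):
        hc = result.hc_sets.get(cond)
        if hc is None:
            continue
        from .intervals import GenomicInterval

        found = 0
        for tss in bound_tss:
            probe = GenomicInterval("chrS", max(0, tss - 500), tss + 500)
            if any(overlaps(probe, pk) for pk in hc.peaks):
                found += 1
        hc_recovery[cond] = found / len(bound_tss) if bound_tss else float("nan")

    # CGI association of HC peaks vs the genome-wide promoter rate
    cgi_fraction = {}
    promoter_fraction = {}
    for cond, hc in result.hc_sets.items():
        part = annotate.partition_by_cgi(hc.peaks, result.genome.cgis)
        cgi_fraction[cond] = part.cgi_fraction
        cls = result.annotations[cond]
        promoter_fraction[cond] = (
            len(annotate.promoter_subset(cls)) / len(cls) if cls else float("nan")
        )

    return {
        "auroc": roc,
        "n_pass": len(called),
        "precision": precision,
        "recall": recall,
        "median_B": median_b,
        "hc_recovery": hc_recovery,
        "cgi_fraction_hc": cgi_fraction,
        "promoter_fraction_hc": promoter_fraction,
        "condition": condition,
    }
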