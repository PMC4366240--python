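"""High-confidence (HC) peak sets from replicated ChIP-seq peak calls.

Within each condition, peaks from all replicates are single-linkage clustered
by overlap; a cluster supported by two or more distinct replicates is
replicated and enters the HC set.  Singleton clusters (one supporting
replicate) can be rescued by the cross-condition rules:

  (i)  the singleton overlaps at least one peak in each of >= 2 other
       conditions, or
  (ii) some single other condition has peaks overlapping the singleton in
       >= 2 distinct replicates.

Finally, all admitted spans are merged per condition.  "Support" always means
distinct replicate ids, never peak counts: two peaks from the same replicate
contribute support 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import GenomicInterval, Peak, merge_intervals, overlaps

logger = logging.getLogger(__name__)

REPLICATED = "replicated"
RESCUED_CROSS_CONDITION = "rescued_cross_condition"
RESCUED_OTHER_CONDITION_REPLICATES = "rescued_other_condition_replicates"
DROPPED = "dropped"


@dataclass
class PeakCluster:
    """A maximal set of transitively overlapping peaks within one condition."""

    member_peaks: list[Peak]
    condition: str

    @property
    def span(self) -> GenomicInterval:
        merged = merge_intervals([p.interval for p in self.member_peaks])
        if len(merged) != 1:
            raise AssertionError("cluster members must overlap transitively")
        return merged[0]

    @property
    def support_replicates(self) -> set[int]:
        return {p.replicate for p in self.member_peaks}

    @property
    def replicated(self) -> bool:
        return len(self.support_replicates) >= 2

    @property
    def score(self) -> float:
        """Cluster score = max member score (used for ranking parity)."""
        return max(p.score for p in self.member_peaks)


@dataclass
class HCPeakSet:
    """Final merged HC peaks for one condition with per-peak provenance."""

    condition: str
    peaks: list[GenomicInterval] = field(default_factory=list)
    provenance: list[set[str]] = field(default_factory=list)


def cluster_within_condition(replicate_peaks: list[Peak], condition: str) -> list[PeakCluster]:
    """Single-linkage cluster all replicates' peaks of one condition by overlap."""
    peaks = [p for p in replicate_peaks if p.condition == condition]
    if len(peaks) != len(replicate_peaks):
        raise ValueError("all peaks must carry the stated condition")
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    clusters: list[PeakCluster] = []
    current = [peaks[0]]
    cur_chrom, cur_end = peaks[0].interval.chrom, peaks[0].interval.end
    for p in peaks[1:]:
        if p.interval.chrom == cur_chrom and p.interval.start < cur_end:
            current.append(p)
            cur_end = max(cur_end, p.interval.end)
        else:
            clusters.append(PeakCluster(current, condition))
            current = [p]
            cur_chrom, cur_end = p.interval.chrom, p.interval.end
    clusters.append(PeakCluster(current, condition))
    return clusters


def _rescue_one(
    span: GenomicInterval,
    condition: str,
    catalogue: dict[str, list[Peak]],
    strict: bool,
    replicated_spans: dict[str, list[GenomicInterval]] | None,
) -> str:
    """Return the provenance tag for a singleton span, or DROPPED."""
    conditions_hit: set[str] = set()
    rule_ii = False
    for other, peaks in catalogue.items():
        if other == condition:
            continue
        reps_hit: set[int] = set()
        for p in peaks:
            if not overlaps(span, p.interval):
                continue
            if strict and replicated_spans is not None:
                if not any(overlaps(p.interval, r) for r in replicated_spans.get(other, [])):
                    continue
            reps_hit.add(p.replicate)
        if reps_hit:
            conditions_hit.add(other)
        if len(reps_hit) >= 2:
            rule_ii = True
    if len(conditions_hit) >= 2:
        return RESCUED_CROSS_CONDITION
    if rule_ii:
        return RESCUED_OTHER_CONDITION_REPLICATES
    return DROPPED


def rescue_singletons(
    singletons: dict[str, list[PeakCluster]],
    all_peaks: dict[str, list[Peak]],
    strict: bool = False,
) -> dict[str, list[tuple[PeakCluster, str]]]:
    """Apply the cross-condition rescue rules to singleton clusters.

    ``all_peaks`` maps condition -> every peak called in that condition (all
    replicates).  With ``strict=True`` only partner peaks that are themselves
    members of replicated clusters in their own condition count towards
    rescue; the default is the permissive reading (any peak counts).

    Returns per condition the list of (cluster, provenance tag) for rescued
    clusters only.
    """
    replicated_spans: dict[str, list[GenomicInterval]] | None = None
    if strict:
        replicated_spans = {}
        for cond, peaks in all_peaks.items():
            replicated_spans[cond] = [
                c.span for c in cluster_within_condition(peaks, cond) if c.replicated
            ]
    rescued: dict[str, list[tuple[PeakCluster, str]]] = {}
    for cond, singles in singletons.items():
        others = [c for c in all_peaks if c != cond]
        if len(others) < 2 and singles:
            logger.warning(
                "condition %s: only %d other condition(s) present; "
                "cross-condition rule (i) cannot be satisfied",
                cond,
                len(others),
            )
        kept = []
        for cluster in singles:
            tag = _rescue_one(cluster.span, cond, all_peaks, strict, replicated_spans)
            if tag != DROPPED:
                kept.append((cluster, tag))
        rescued[cond] = kept
    return rescued


def build_hc_peakset(
    peaks_by_condition: dict[str, list[Peak]],
    strict_rescue: bool = False,
) -> dict[str, HCPeakSet]:
    """Build the final HC peak set for every condition.

    HC = merge(replicated cluster spans ∪ rescued singleton spans); provenance
    of each merged peak is the union of the tags of its sources.
    """
    clusters = {
        cond: cluster_within_condition(peaks, cond)
        for cond, peaks in peaks_by_condition.items()
    }
    singletons = {
        cond: [c for c in cl if not c.replicated] for cond, cl in clusters.items()
    }
    rescued = rescue_singletons(singletons, peaks_by_condition, strict=strict_rescue)

    result: dict[str, HCPeakSet] = {}
    for cond in peaks_by_condition:
        sources: list[tuple[GenomicInterval, str]] = [
            (c.span, REPLICATED) for c in clusters[cond] if c.replicated
        ]
        sources += [(c.span, tag) for c, tag in rescued[cond]]
        merged = merge_intervals([s for s, _ in sources])
        provenance = []
        for m in merged:
            tags = {tag for s, tag in sources if overlaps(m, s)}
            provenance.append(tags)
        result[cond] = HCPeakSet(condition=cond, peaks=merged, provenance=provenance)
    return result


def audit_table(peaks_by_condition: dict[str, list[Peak]], strict_rescue: bool = False):
    """Per-cluster audit rows: condition, span, support, rule that admitted it."""
    import pandas as pd

    rows = []
    for cond, peaks in peaks_by_condition.items():
        clusters = cluster_within_condition(peaks, cond)
        singles = [c for c in clusters if not c.replicated]
        rescued = rescue_singletons({cond: singles}, peaks_by_condition, strict=strict_rescue)
        tag_of = {id(c): tag for c, tag in rescued[cond]}
        for c in clusters:
            if c.replicated:
                rule = REPLICATED
            else:
                rule = tag_of.get(id(c), DROPPED)
            s = c.span
            rows.append(
                {
                    "condition": cond,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "n_peaks": len(c.member_peaks),
                    "support_replicates": len(c.support_replicates),
                    "score": c.score,
                    "rule": rule,
                }
            )
    return pd.DataFrame(rows)
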