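"""Independent brute-force reference implementations used only by tests.

Everything here works on per-base sets/bitmaps over a small toy chromosome,
deliberately avoiding the package's interval arithmetic so the two code
paths share nothing but the rules they implement.
"""

from __future__ import annotations

import numpy as np

from p53targets.intervals import GenomicInterval, Peak


def merge_oracle(intervals: list[GenomicInterval], chrom_len: int = 10_000):
    """Per-base bitmap union -> maximal runs, per chromosome."""
    by_chrom: dict[str, np.ndarray] = {}
    for iv in intervals:
        bits = by_chrom.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))
        bits[iv.start : iv.end] = True
    out = []
    for chrom in sorted(by_chrom):
        bits = by_chrom[chrom]
        padded = np.concatenate([[False], bits, [False]]).astype(int)
        d = np.diff(padded)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def _bases(p: Peak) -> set[int]:
    return set(range(p.interval.start, p.interval.end))


def hc_oracle(
    peaks_by_cond: dict[str, list[Peak]], chrom_len: int = 10_000
) -> dict[str, list[tuple[int, int]]]:
    """Literal per-base application of the consensus + rescue + merge rules.

    Assumes a single chromosome.  Returns per condition the sorted list of
    final HC (start, end) spans.
    """
    # within-condition connected components by shared bases (transitive)
    components: dict[str, list[list[Peak]]] = {}
    for cond, peaks in peaks_by_cond.items():
        comps: list[tuple[set[int], list[Peak]]] = []
        for p in peaks:
            pb = _bases(p)
            touching = [c for c in comps if c[0] & pb]
            merged_bases = set(pb)
            merged_peaks = [p]
            for c in touching:
                merged_bases |= c[0]
                merged_peaks.extend(c[1])
                comps.remove(c)
            comps.append((merged_bases, merged_peaks))
        components[cond] = [c[1] for c in comps]

    final: dict[str, list[tuple[int, int]]] = {}
    for cond, comps in components.items():
        admitted = np.zeros(chrom_len, dtype=bool)
        for members in comps:
            reps = {p.replicate for p in members}
            span_bases = set().union(*(_bases(p) for p in members))
            keep = len(reps) >= 2
            if not keep:
                # rescue rules against every other condition's peaks
                conds_hit = 0
                rule_ii = False
                for other, opeaks in peaks_by_cond.items():
                    if other == cond:
                        continue
                    reps_hit = {p.replicate for p in opeaks if _bases(p) & span_bases}
                    if reps_hit:
                        conds_hit += 1
                    if len(reps_hit) >= 2:
                        rule_ii = True
                keep = conds_hit >= 2 or rule_ii
            if keep:
                admitted[list(span_bases)] = True
        padded = np.concatenate([[False], admitted, [False]]).astype(int)
        d = np.diff(padded)
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        final[cond] = [(int(s), int(e)) for s, e in zip(starts, ends)]
    return final


def random_peak_instance(rng: np.random.Generator, chrom_len: int = 10_000):
    """Random multi-condition peak catalogue (<=20 peaks, 4 conditions, <=3 reps)."""
    conditions = ["Grow", "acDDR", "RIS", "pApo"]
    reps = {c: int(rng.integers(1, 4)) for c in conditions}
    reps["Grow"] = min(reps["Grow"], 2)
    n_peaks = int(rng.integers(0, 21))
    peaks_by_cond: dict[str, list[Peak]] = {c: [] for c in conditions}
    for _ in range(n_peaks):
        cond = conditions[int(rng.integers(0, 4))]
        rep = int(rng.integers(1, reps[cond] + 1))
        start = int(rng.integers(0, chrom_len - 500))
        width = int(rng.integers(20, 500))
        iv = GenomicInterval("chrS", start, start + width)
        peaks_by_cond[cond].append(Peak(iv, condition=cond, replicate=rep))
    return peaks_by_cond


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Step-up BH by direct definition: sort, p*m/rank, cumulative min from top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def pooled_t_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Classical two-sample pooled-variance t pieces: (log2fc, s2, t)."""
    n1, n2 = len(x), len(y)
    fc = np.mean(x) - np.mean(y)
    s2 = (np.sum((x - np.mean(x)) ** 2) + np.sum((y - np.mean(y)) ** 2)) / (n1 + n2 - 2)
    t = fc / np.sqrt(s2 * (1 / n1 + 1 / n2))
    return fc, s2, t


def full_site_pairs_oracle(half_hits, half_len: int, min_spacer: int = 0, max_spacer: int = 13):
    """All same-strand ordered pairs of half hits whose gap is in range."""
    pairs = []
    for a in half_hits:
        for b in half_hits:
            if a is b or a.strand != b.strand:
                continue
            if b.position <= a.position:
                continue
            gap = b.position - (a.position + half_len)
            if min_spacer <= gap <= max_spacer:
                pairs.append((a, b))
    return pairs
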