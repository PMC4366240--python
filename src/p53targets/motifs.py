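"""PWM scanning for p53 response elements.

The canonical p53 response element is two decameric half-sites (consensus
RRRCWWGYYY) separated by a 0-13 bp spacer; lone half-sites can also be
functional and are reported by the plain scanner.  Scores are log-odds
against a background base distribution, min-max normalized per motif into a
matrix similarity score (MSS) in [0, 1]; calls use an MSS cutoff (default
0.8) and, optionally, a "core" cutoff computed over the five consecutive
most informative columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Declared default half-site count matrix for RRRCWWGYYY: purines (A/G) split
# evenly in R columns, pyrimidines in Y, A/T in W, fixed C and G anchors.
# This is a synthetic stand-in for proprietary matrix libraries.
P53_HALF_SITE_COUNTS = np.array(
    [
        # R  R  R  C  W  W  G  Y  Y  Y
        [6, 6, 6, 0, 6, 6, 0, 0, 0, 0],  # A
        [0, 0, 0, 12, 0, 0, 0, 6, 6, 6],  # C
        [6, 6, 6, 0, 0, 0, 12, 0, 0, 0],  # G
        [0, 0, 0, 0, 6, 6, 0, 6, 6, 6],  # T
    ],
    dtype=float,
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    motif_id: str
    counts: np.ndarray  # 4 x L, rows A,C,G,T
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be 4 x L with L >= 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L log-odds matrix with pseudocounts."""
        padded = self.counts + self.pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        return np.log2(probs / self.background[:, None])

    @property
    def information(self) -> np.ndarray:
        """Per-column information content (bits) relative to the background."""
        padded = self.counts + self.pseudocount
        probs = padded / padded.sum(axis=0, keepdims=True)
        return (probs * np.log2(probs / self.background[:, None])).sum(axis=0)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.counts, axis=0))

    def core_window(self, width: int = 5) -> tuple[int, int]:
        """Start/end of the ``width`` consecutive most informative columns."""
        info = self.information
        if self.length <= width:
            return 0, self.length
        sums = np.convolve(info, np.ones(width), mode="valid")
        s = int(np.argmax(sums))
        return s, s + width


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    position: int  # 0-based offset of the match start on the forward strand
    strand: str
    score: float  # raw log-odds
    mss: float  # min-max normalized score in [0, 1]


def _mss_bounds(lo: np.ndarray) -> tuple[float, float]:
    return float(lo.min(axis=0).sum()), float(lo.max(axis=0).sum())


def _score_strand(seq: str, lo: np.ndarray) -> np.ndarray:
    """Sliding log-odds scores at every start position; N scores 0."""
    L = lo.shape[1]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    idx = np.full(len(seq), -1, dtype=int)
    for b, base in enumerate(_BASES):
        idx[[i for i, ch in enumerate(seq) if ch == base]] = b
    scores = np.zeros(n)
    for j in range(L):
        col_idx = idx[j : j + n]
        col = np.where(col_idx >= 0, lo[np.clip(col_idx, 0, 3), j], 0.0)
        scores += col
    return scores


def scan_pwm(
    seq: str,
    pwm: PWM,
    min_mss: float = 0.8,
    sequence_id: str = "seq",
    core_filter: bool = False,
    min_core: float = 0.8,
) -> list[MotifHit]:
    """Scan both strands; report hits with MSS >= min_mss.

    Hit positions always refer to the forward strand (start of the matched
    span).  With ``core_filter`` the five most informative consecutive
    columns must additionally reach ``min_core`` on their own min-max scale.
    """
    seq = seq.upper()
    lo = pwm.log_odds
    L = pwm.length
    if len(seq) < L:
        return []
    mn, mx = _mss_bounds(lo)
    span = mx - mn if mx > mn else 1.0
    cs, ce = pwm.core_window()
    core_lo = lo[:, cs:ce]
    cmn, cmx = _mss_bounds(core_lo)
    cspan = cmx - cmn if cmx > cmn else 1.0

    hits: list[MotifHit] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        scores = _score_strand(s, lo)
        mss = (scores - mn) / span
        keep = np.nonzero(mss >= min_mss)[0]
        if core_filter and keep.size:
            core_scores = _score_strand(s, lo[:, cs:ce])
            pass_core = []
            for i in keep:
                # core columns sit at offset cs within the full match
                c = core_scores[i + cs] if i + cs < core_scores.size else cmn
                if (c - cmn) / cspan >= min_core:
                    pass_core.append(i)
            keep = np.array(pass_core, dtype=int)
        for i in keep:
            pos = int(i) if strand == "+" else len(seq) - L - int(i)
            hits.append(
                MotifHit(sequence_id, pos, strand, float(scores[i]), float(mss[i]))
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass
class FullSiteModel:
    half_pwm: PWM
    min_spacer: int = 0
    max_spacer: int = 13

    def __post_init__(self) -> None:
        if not (0 <= self.min_spacer <= self.max_spacer <= 13):
            raise ValueError("spacer range must lie within 0-13")


@dataclass(frozen=True)
class FullSiteHit:
    sequence_id: str
    start: int  # forward-strand start of the first half-site
    end: int  # forward-strand end (exclusive) of the second half-site
    strand: str
    spacer: int
    score: float  # sum of half-site log-odds scores


def scan_full_sites(
    seq: str,
    model: FullSiteModel,
    min_mss: float = 0.8,
    sequence_id: str = "seq",
) -> list[FullSiteHit]:
    """Pair same-strand half-site hits separated by an in-range spacer.

    Full sites are formed greedily by descending summed score; a half-site
    hit joins at most one full site, and overlapping full sites are resolved
    in favour of the higher-scoring one.
    """
    halves = scan_pwm(seq, model.half_pwm, min_mss=min_mss, sequence_id=sequence_id)
    L = model.half_pwm.length
    by_strand: dict[str, list[MotifHit]] = {"+": [], "-": []}
    for h in halves:
        by_strand[h.strand].append(h)
    candidates: list[FullSiteHit] = []
    for strand, hs in by_strand.items():
        hs = sorted(hs, key=lambda h: h.position)
        for i, a in enumerate(hs):
            for b in hs[i + 1 :]:
                gap = b.position - (a.position + L)
                if gap > model.max_spacer:
                    break
                if gap < model.min_spacer:
                    continue
                candidates.append(
                    FullSiteHit(
                        sequence_id,
                        a.position,
                        b.position + L,
                        strand,
                        gap,
                        a.score + b.score,
                    )
                )
    chosen: list[FullSiteHit] = []
    used: set[tuple[str, int]] = set()
    for c in sorted(candidates, key=lambda c: (-c.score, c.start)):
        k1, k2 = (c.strand, c.start), (c.strand, c.end - L)
        if k1 in used or k2 in used:
            continue
        if any(not (c.end <= o.start or o.end <= c.start) for o in chosen):
            continue
        chosen.append(c)
        used.update((k1, k2))
    chosen.sort(key=lambda c: c.start)
    return chosen


def positional_histogram(
    hits: list[MotifHit],
    anchors: dict[str, tuple[int, str]],
    window: int = 1000,
    bin_size: int = 50,
) -> np.ndarray:
    """Frequency of hits per signed-offset bin across anchored regions.

    ``anchors`` maps sequence_id -> (anchor position within the sequence,
    anchor strand).  A hit contributes to the bin of its start's signed,
    strand-aware offset from the anchor; offsets in [-window, +window) are
    kept (2*window/bin_size bins).  Frequencies divide by the number of
    anchored regions, not by hit count.
    """
    if (2 * window) % bin_size != 0:
        raise ValueError("window must be divisible by the bin size")
    n_bins = 2 * window // bin_size
    counts = np.zeros(n_bins)
    if not anchors:
        return counts
    for h in hits:
        if h.sequence_id not in anchors:
            continue
        pos, strand = anchors[h.sequence_id]
        off = h.position - pos if strand == "+" else pos - h.position
        if -window <= off < window:
            counts[(off + window) // bin_size] += 1
    return counts / len(anchors)


def promoter_enrichment_ztest(
    fg_seqs: dict[str, str], bg_seqs: dict[str, str], pwm: PWM
) -> tuple[float, float]:
    """Best-hit MSS difference between foreground and background promoters.

    z = (mean_fg - mean_bg) / sqrt(var_fg/n_fg + var_bg/n_bg), two-sided
    normal p.  All sequences must have equal length so best-hit scores are
    comparable (longer sequences get more chances at a high maximum).
    """
    from scipy import stats

    lens = {len(s) for s in fg_seqs.values()} | {len(s) for s in bg_seqs.values()}
    if len(lens) != 1:
        raise ValueError("foreground and background sequences must be equal length")

    def best_mss(seqs: dict[str, str]) -> np.ndarray:
        lo = pwm.log_odds
        mn, mx = _mss_bounds(lo)
        span = mx - mn if mx > mn else 1.0
        out = []
        for s in seqs.values():
            fwd = _score_strand(s.upper(), lo)
            rev = _score_strand(reverse_complement(s.upper()), lo)
            best = max(fwd.max(initial=mn), rev.max(initial=mn))
            out.append((best - mn) / span)
        return np.array(out)

    fg, bg = best_mss(fg_seqs), best_mss(bg_seqs)
    se = np.sqrt(fg.var(ddof=1) / fg.size + bg.var(ddof=1) / bg.size)
    z = (fg.mean() - bg.mean()) / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def default_half_site_pwm() -> PWM:
    return PWM("p53_half_site_RRRCWWGYYY", P53_HALF_SITE_COUNTS.copy())
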