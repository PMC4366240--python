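"""Empirical-Bayes differential expression for the sh-p53 vs vector contrast.

The pipeline works on log2 intensity matrices (probes x samples).  After
quantile normalization, each probe gets a two-sample contrast
``log2fc = mean(sh-p53) - mean(vector)`` with pooled residual variance s²
on df = n1 + n2 - 2 degrees of freedom.  Variances are shrunk towards a
prior by the standard moderated-t machinery,

    s̃²_g = (d0·s0² + df·s²_g) / (d0 + df),

with (d0, s0²) estimated by moment-matching the scaled-F distribution of
the sample variances on the log scale.  Posterior probabilities of
differential expression come from a two-groups model: under the null the
moderated t follows a t distribution with d0 + df degrees of freedom; under
the alternative its scale is inflated by ``sqrt(1 + v_prior)``; prior odds
are p0/(1 - p0).

Sign convention: the contrast is knockdown minus control, so genes that p53
ACTIVATES have negative log2fc (their expression drops when p53 is removed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

DEFAULT_P0 = 0.05
DEFAULT_V_PRIOR = 8.0
D0_CAP = 1e6  # effectively infinite prior df


@dataclass
class EBayesHyperparams:
    d0: float
    s0sq: float
    p0: float = DEFAULT_P0
    v_prior: float = DEFAULT_V_PRIOR

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0 (use a large value for ~infinite)")
        if not self.s0sq > 0:
            raise ValueError("s0sq must be > 0")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0,1)")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the cross-sample mean of order statistics.

    Ties within a column receive the mean of the reference values at their
    rank positions, so the operation is idempotent.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("quantile normalization requires finite values")
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        # average reference values over tied ranks so ties stay tied
        ranks = stats.rankdata(col, method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def fit_contrast(
    matrix: pd.DataFrame, arm_labels: list[str] | np.ndarray
) -> pd.DataFrame:
    """Per-probe two-sample contrast: sh-p53 minus vector.

    ``arm_labels`` gives each column's arm, "sh" or "vector".  Returns a frame
    with log2fc, s2 (pooled residual variance) and df.
    """
    labels = np.asarray(arm_labels)
    sh = matrix.loc[:, labels == "sh"].to_numpy(dtype=float)
    vec = matrix.loc[:, labels == "vector"].to_numpy(dtype=float)
    n1, n2 = sh.shape[1], vec.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs >= 2 samples for a residual variance")
    log2fc = sh.mean(axis=1) - vec.mean(axis=1)
    ss = ((sh - sh.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((vec - vec.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = ss / df
    return pd.DataFrame(
        {"log2fc": log2fc, "s2": s2, "df": df, "n1": n1, "n2": n2},
        index=matrix.index,
    )


def estimate_prior_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0²) from sample variances ~ s0²·F(df, d0).

    Uses the log-scale moments of the scaled-F: for z = log(s²),
    E[z] = log(s0²) + ψ(df/2) - log(df/2) - ψ(d0/2) + log(d0/2) and
    Var[z] = ψ'(df/2) + ψ'(d0/2).  When the empirical variance of z does not
    exceed ψ'(df/2), the variances carry no extra spread and d0 is reported
    as (effectively) infinite.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError(
            "all sample variances are zero; cannot estimate a variance prior "
            "(check for constant or duplicated samples)"
        )
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    # target: polygamma(1, d0/2) = var(e) - polygamma(1, df/2)
    excess = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if excess <= 1e-10:
        d0 = D0_CAP
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0sq


def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate(
    s2: np.ndarray, df: float, hyper: EBayesHyperparams | None = None
) -> tuple[np.ndarray, float, EBayesHyperparams]:
    """Shrink per-probe variances towards the prior; returns (s̃², df_total, hyper)."""
    s2 = np.asarray(s2, dtype=float)
    if hyper is None:
        d0, s0sq = estimate_prior_variance(s2, df)
        hyper = EBayesHyperparams(d0=d0, s0sq=s0sq)
    s2_post = (hyper.d0 * hyper.s0sq + df * s2) / (hyper.d0 + df)
    df_total = min(hyper.d0 + df, D0_CAP)
    return s2_post, float(df_total), hyper


def moderated_t(
    log2fc: np.ndarray,
    s2_post: np.ndarray,
    n1: int,
    n2: int,
    df_total: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and its two-sided p from a t distribution with df_total."""
    log2fc = np.asarray(log2fc, dtype=float)
    s2_post = np.asarray(s2_post, dtype=float)
    scale = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, log2fc / np.where(scale > 0, scale, 1.0), np.inf * np.sign(log2fc))
    t = np.where((scale == 0) & (log2fc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p ranks)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_posterior(
    t: np.ndarray,
    df_total: float,
    p0: float = DEFAULT_P0,
    v_prior: float = DEFAULT_V_PRIOR,
) -> np.ndarray:
    """Posterior probability of differential expression from the two-groups model.

    log-odds O = log(p0/(1-p0)) + log f1(t) - log f0(t), with f0 the central
    t density (df_total) and f1 the same density scaled by sqrt(1 + v_prior).
    """
    t = np.asarray(t, dtype=float)
    c = np.sqrt(1.0 + v_prior)
    df_eff = min(df_total, D0_CAP)
    t_finite = np.clip(t, -1e6, 1e6)
    log_f0 = stats.t.logpdf(t_finite, df_eff)
    log_f1 = stats.t.logpdf(t_finite / c, df_eff) - np.log(c)
    odds = np.log(p0 / (1.0 - p0)) + log_f1 - log_f0
    return special.expit(odds)


def run_de(
    expr_vector: pd.DataFrame,
    expr_sh: pd.DataFrame,
    hyper: EBayesHyperparams | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full per-probe DE table for the knockdown-vs-vector contrast."""
    if not expr_vector.index.equals(expr_sh.index):
        raise ValueError("the two arms must share the same probe index")
    matrix = pd.concat([expr_vector, expr_sh], axis=1)
    labels = ["vector"] * expr_vector.shape[1] + ["sh"] * expr_sh.shape[1]
    if normalize:
        matrix = quantile_normalize(matrix)
    fit = fit_contrast(matrix, labels)
    s2_post, df_total, hyper = moderate(fit["s2"].to_numpy(), float(fit["df"].iloc[0]), hyper)
    t, p = moderated_t(
        fit["log2fc"].to_numpy(), s2_post, int(fit["n1"].iloc[0]), int(fit["n2"].iloc[0]), df_total
    )
    q = bh_adjust(p)
    pde = de_posterior(t, df_total, p0=hyper.p0, v_prior=hyper.v_prior)
    return pd.DataFrame(
        {
            "log2fc": fit["log2fc"],
            "s2": fit["s2"],
            "s2_post": s2_post,
            "t_mod": t,
            "p": p,
            "q": q,
            "pDE": pde,
        },
        index=matrix.index,
    )


def select_de_genes(
    results: pd.DataFrame, q_cut: float = 0.01, lfc_cut: float = 0.58
) -> pd.Index:
    """Probes passing FDR < q_cut AND |log2fc| > lfc_cut."""
    mask = (results["q"] < q_cut) & (results["log2fc"].abs() > lfc_cut)
    return results.index[mask]


def collapse_to_genes(results: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Gene-level table: pDE = max over the gene's probes; log2fc/t/q from that probe."""
    tbl = results.copy()
    tbl["gene"] = [probe_to_gene.get(p) for p in tbl.index]
    tbl = tbl.dropna(subset=["gene"])
    idx = tbl.groupby("gene")["pDE"].idxmax()
    out = tbl.loc[idx].set_index("gene").sort_index()
    return out
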