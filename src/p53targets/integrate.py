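"""Joint posterior of binding and response: the target-calling core.

Per gene, the posterior probability of being a direct p53 target is taken as
the product of the two arms' posteriors,

    p_joint = Pr(DE | data) * Pr(C | data),

treating the expression and ChIP experiments as independent evidence.  The
product is logit-transformed into a B value, B = ln(p/(1-p)); genes with
B strictly greater than -1.5 are called putative direct targets.  Direction
comes from the knockdown-minus-vector log2 fold change: negative means the
gene needed p53 (induced target), positive means p53 repressed it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

B_THRESHOLD = -1.5
B_CAP = 1e308  # serialized stand-in for +/- infinity at p = 1 or 0


def combine_posteriors(p_de, p_c):
    """p_joint = pDE * pC (independence of the two data modalities)."""
    p_de = np.asarray(p_de, dtype=float)
    p_c = np.asarray(p_c, dtype=float)
    if np.any((p_de < 0) | (p_de > 1)) or np.any((p_c < 0) | (p_c > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    return p_de * p_c


def logit_b(p):
    """B = ln(p / (1-p)); exact 0/1 map to -/+ 1e308 sentinels."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        b = np.log(p) - np.log1p(-p)
    b = np.where(p == 0.0, -B_CAP, b)
    b = np.where(p == 1.0, B_CAP, b)
    return b if b.ndim else float(b)


def inv_logit(b):
    from scipy.special import expit

    return expit(b)


def direction_call(log2fc) -> np.ndarray:
    """Knockdown-minus-vector sign -> induced (<0), repressed (>0), undetermined (0)."""
    log2fc = np.asarray(log2fc, dtype=float)
    return np.where(
        log2fc < 0, "induced", np.where(log2fc > 0, "repressed", "undetermined")
    )


def rank_and_threshold(results: pd.DataFrame, threshold: float = B_THRESHOLD) -> pd.DataFrame:
    """Sort descending by B (ties by gene id) and flag pass = B > threshold."""
    out = results.copy()
    out["pass"] = out["B"] > threshold
    # stable sort on a pre-sorted index makes gene id the deterministic tie-break
    out = out.sort_index().sort_values("B", ascending=False, kind="stable")
    return out


def integrate(
    de_genes: pd.DataFrame,
    enrich: pd.DataFrame,
    threshold: float = B_THRESHOLD,
    direction: str = "both",
) -> pd.DataFrame:
    """Join the gene-level DE and enrichment tables and compute B values.

    ``de_genes`` must carry pDE and log2fc (gene-indexed); ``enrich`` must
    carry pC.  Genes missing from either arm are dropped (no evidence, no
    call).  ``direction`` filters the output to induced or repressed targets
    ("both" keeps everything, including undetermined).
    """
    common = de_genes.index.intersection(enrich.index)
    pde = de_genes.loc[common, "pDE"].to_numpy()
    pc = enrich.loc[common, "pC"].to_numpy()
    p_joint = combine_posteriors(pde, pc)
    b = logit_b(p_joint)
    out = pd.DataFrame(
        {
            "pDE": pde,
            "pC": pc,
            "p_joint": p_joint,
            "B": b,
            "log2fc": de_genes.loc[common, "log2fc"].to_numpy(),
            "direction": direction_call(de_genes.loc[common, "log2fc"].to_numpy()),
        },
        index=common,
    )
    out.index.name = "gene"
    out = rank_and_threshold(out, threshold)
    if direction in ("induced", "repressed"):
        out = out.loc[out["direction"] == direction]
    elif direction != "both":
        raise ValueError("direction must be both, induced or repressed")
    return out
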