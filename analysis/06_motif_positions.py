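#!/usr/bin/env python
"""Positional distribution of p53 response-element motifs around the TSS.

Demonstrates the focused-vs-dispersed contrast on planted sequence sets:
promoters with a response element at a fixed position (-100 bp) produce a
single-bin positional peak, while uniformly placed elements spread across
the +/- 1 kb window.  Also runs the foreground-vs-background promoter
enrichment z-test.  Writes results/motif_histograms.tsv.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from p53targets.motifs import (  # noqa: E402
    default_half_site_pwm,
    positional_histogram,
    promoter_enrichment_ztest,
    scan_pwm,
)
from p53targets.simulate import plant_motif_sequences  # noqa: E402

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
N, LENGTH, ANCHOR = 150, 2000, 1000


def hist_for(seqs, pwm):
    hits = []
    for i, s in enumerate(seqs):
        hits.extend(scan_pwm(s, pwm, min_mss=0.95, sequence_id=f"s{i}"))
    return positional_histogram(hits, {f"s{i}": (ANCHOR, "+") for i in range(N)})


def run() -> None:
    pwm = default_half_site_pwm()
    cons = pwm.consensus()
    focused = plant_motif_sequences(N, LENGTH, cons, [ANCHOR - 100], seed=20150319)
    dispersed = plant_motif_sequences(N, LENGTH, cons, None, seed=20150320)
    h_focus, h_disp = hist_for(focused, pwm), hist_for(dispersed, pwm)
    edges = np.arange(-1000, 1000, 50)
    pd.DataFrame(
        {"bin_start": edges, "focused": h_focus, "dispersed": h_disp}
    ).to_csv(os.path.join(BASE, "motif_histograms.tsv"), sep="\t", index=False)
    print(f"focused planting: peak bin at {edges[h_focus.argmax()]} bp "
          f"(frequency {h_focus.max():.2f}); dispersed max {h_disp.max():.2f}")

    bg = plant_motif_sequences(N, LENGTH, "", [0], seed=20150321)
    z, p = promoter_enrichment_ztest(
        {f"f{i}": s for i, s in enumerate(focused)},
        {f"b{i}": s for i, s in enumerate(bg)},
        pwm,
    )
    print(f"promoter enrichment z-test (planted vs background): z = {z:.1f}, p = {p:.2e}")


if __name__ == "__main__":
    run()
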