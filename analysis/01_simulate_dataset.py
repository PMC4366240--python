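#!/usr/bin/env python
"""Generate the default synthetic study dataset and summarize its truth.

Writes the full dataset (gene models, CGIs, per-replicate peak calls, read
positions, TSS-bin counts, expression matrices, truth table) under
results/sim/ and prints the planted composition: how many genes are bound,
responsive, and direct targets, and how CGI-biased the targets are.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from p53targets.cli import main as cli  # noqa: E402

OUTDIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "sim")


def run() -> None:
    cli.main(["simulate", "--outdir", OUTDIR], standalone_mode=False)
    truth = pd.read_csv(os.path.join(OUTDIR, "truth.tsv"), sep="\t", index_col=0)
    targets = truth[truth["is_target"]]
    print(f"\ngenes: {len(truth)}")
    print(f"bound: {int(truth['bound'].sum())}  responsive: {int(truth['responsive'].sum())}")
    print(f"direct targets (bound AND responsive): {len(targets)}")
    cgi_share = (targets["promoter_class"] == "CGI").mean()
    base_share = (truth["promoter_class"] == "CGI").mean()
    print(f"CGI share of targets: {cgi_share:.2f} (genome-wide promoter rate {base_share:.2f})")
    induced = (targets["direction"] == "induced").sum()
    print(f"target direction: {induced} induced, {len(targets) - induced} repressed")


if __name__ == "__main__":
    run()
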