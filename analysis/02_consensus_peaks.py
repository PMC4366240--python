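#!/usr/bin/env python
"""Build high-confidence peak sets from the simulated replicate peak calls.

Reads the per-replicate BED files written by 01_simulate_dataset.py, applies
the within-condition replicate-consensus rule and the cross-condition
singleton rescues, and reports per condition how many clusters were admitted
by each rule.  Outputs hc_<condition>.bed plus the full audit table under
results/hc_peaks/.
"""

import glob
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from p53targets import consensus, io  # noqa: E402

SIMDIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "sim")
OUTDIR = os.path.join(os.path.dirname(__file__), "..", "results", "hc_peaks")
TABLES = os.path.join(os.path.dirname(__file__), "..", "scratch", "tables")


def run() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    by_cond: dict[str, list] = {}
    for path in sorted(glob.glob(os.path.join(SIMDIR, "peaks_*_rep*.bed"))):
        stem = os.path.basename(path)[len("peaks_"):-len(".bed")]
        cond, rep = stem.rsplit("_rep", 1)
        by_cond.setdefault(cond, []).extend(
            io.read_peaks_bed(path, condition=cond, replicate=int(rep))
        )
    hc = consensus.build_hc_peakset(by_cond)
    audit = consensus.audit_table(by_cond)
    os.makedirs(TABLES, exist_ok=True)
    audit.to_csv(os.path.join(TABLES, "consensus_audit.tsv"), sep="\t", index=False)
    for cond, hcset in hc.items():
        io.write_bed(
            os.path.join(OUTDIR, f"hc_{cond}.bed"),
            hcset.peaks,
            names=["+".join(sorted(t)) for t in hcset.provenance],
        )
    print("admission rule counts per condition:")
    print(audit.groupby(["condition", "rule"]).size().unstack(fill_value=0))
    for cond, hcset in sorted(hc.items()):
        widths = [p.width for p in hcset.peaks]
        med = sorted(widths)[len(widths) // 2] if widths else 0
        print(f"{cond}: {len(hcset.peaks)} HC peaks, median width {med} bp")


if __name__ == "__main__":
    run()
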