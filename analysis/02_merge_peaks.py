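"""Merge per-replicate peak calls into consensus binding segments.

Applies the 80%-of-shortest reciprocal-overlap rule within each
condition and keeps segments supported by at least 2 of 4 replicates.
Writes consensus BED + membership tables and a support-level summary
under results/, and reports how well the consensus recovers the planted
sites.
"""

import argparse
import json
from pathlib import Path

from chiptargets import TAGGED, merge_replicates, read_peaks, write_bed
from chiptargets.consensus import consensus_summary
from chiptargets.simulate import score_against_truth

CONDITIONS = ("low_cu", "control_cu")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-frac", type=float, default=0.8)
    ap.add_argument("--min-support", type=int, default=2)
    args = ap.parse_args()
    sim = args.results / "sim"

    consensus = {}
    for cond in CONDITIONS:
        peaks = []
        for rep in range(1, 5):
            peaks.extend(
                read_peaks(sim / f"peaks_{cond}_R{rep}.narrowPeak", f"R{rep}", cond, TAGGED)
            )
        cons = merge_replicates(peaks, args.min_frac, args.min_support)
        consensus[cond] = cons
        write_bed(cons, args.results / f"consensus_{cond}.bed")
        print(f"{cond}: {len(peaks)} replicate peaks -> {len(cons)} consensus peaks")

    summary = consensus_summary([c for cons in consensus.values() for c in cons])
    summary.to_csv(args.results / "consensus_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    truth = json.load(open(sim / "truth.json"))
    scores = score_against_truth(consensus, truth)
    for cond, s in scores["site_recovery"].items():
        print(
            f"{cond}: recall {s['recall']:.3f}, precision {s['precision']:.3f} "
            f"({s['n_consensus']} consensus vs {s['n_true_sites']} true sites)"
        )


if __name__ == "__main__":
    main()
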