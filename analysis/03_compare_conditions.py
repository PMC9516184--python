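"""Classify consensus peaks as condition-specific or shared.

Matches peaks across the two Cu conditions by overlap of their
center ± 30%-length windows, and flags peaks intersecting the mock
(untagged-control) peak sets. Writes the per-peak classification and a
Venn-count JSON under results/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chiptargets import TAGGED, UNTAGGED_CONTROL, read_peaks
from chiptargets.condition import apply_presence_flags, classify_presence, flag_control_overlap
from chiptargets.consensus import ConsensusPeak


def read_consensus_bed(path, condition):
    return [
        ConsensusPeak(
            interval=p.interval,
            support=int(p.score or 0),
            member_ids=(),
            condition=condition,
            genotype=TAGGED,
            name=p.name,
        )
        for p in read_peaks(path, "consensus", condition, TAGGED)
    ]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--window-frac", type=float, default=0.3)
    args = ap.parse_args()

    low = read_consensus_bed(args.results / "consensus_low_cu.bed", "low_cu")
    ctrl = read_consensus_bed(args.results / "consensus_control_cu.bed", "control_cu")
    low_cls, ctrl_cls, venn = classify_presence(low, ctrl, args.window_frac)

    mocks = []
    for cond in ("low_cu", "control_cu"):
        mocks.extend(
            read_peaks(args.results / "sim" / f"mock_{cond}.narrowPeak", "mock", cond,
                       UNTAGGED_CONTROL)
        )
    flags, n_flagged = flag_control_overlap(low + ctrl, mocks)
    low_cls = apply_presence_flags(low_cls, flags)
    ctrl_cls = apply_presence_flags(ctrl_cls, flags)
    venn["mock_flagged"] = n_flagged

    pd.DataFrame(
        [
            {
                "peak_id": c.consensus_peak.peak_id,
                "condition": c.consensus_peak.condition,
                "presence": c.presence,
                "control_flagged": c.control_flagged,
            }
            for c in low_cls + ctrl_cls
        ]
    ).to_csv(args.results / "peak_classes.tsv", sep="\t", index=False)
    with open(args.results / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=1, sort_keys=True)
    print(
        f"low-Cu only {venn['low_cu_only']}, shared {venn['shared_low_cu']}"
        f"/{venn['shared_control_cu']} (per side), "
        f"control-Cu only {venn['control_cu_only']}; "
        f"{n_flagged} peaks overlap a mock peak"
    )


if __name__ == "__main__":
    main()
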