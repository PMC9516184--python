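"""Generate the synthetic study dataset with known ground truth.

Emits a two-chromosome genome, 260 non-overlapping genes, 200 planted
promoter binding sites (each carrying a concrete GTACTRC instance),
4 replicate peak sets per condition with jitter/dropout plus background
peaks, single-replicate mock peak sets, and a WT-vs-mutant DE table for
the low-Cu and control-Cu contrasts. Everything lands in results/sim/.
"""

import argparse
import json
from pathlib import Path

from chiptargets.simulate import SimConfig, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    paths, truth = simulate(SimConfig(seed=args.seed), args.results / "sim")
    n_shared = sum(s["presence"] == "shared" for s in truth["sites"])
    print(f"wrote {len(paths)} files under {args.results / 'sim'}")
    print(
        f"planted {len(truth['sites'])} true sites "
        f"({n_shared} shared, {len(truth['sites']) - n_shared} low-Cu-only) "
        f"across {len(truth['gene_classes'])} genes"
    )
    tc = truth["target_classes"]["low_cu"]
    print(
        f"planted low-Cu effects: {len(tc['activated'])} bound-activated, "
        f"{len(tc['repressed'])} bound-repressed genes"
    )


if __name__ == "__main__":
    main()
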