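"""Scan consensus peaks for the degenerate binding motifs.

Counts GTACTRC and TCTTCTST occurrences inside low-Cu consensus peaks
(both strands, overlapping matches included) and summarizes the three
positional statistics: copies per peak, distance to peak center (75-bp
bins), and the metagene profile with every gene body rescaled to
2,000 bp (200-bp bins). The planted GTACTRC sites sit ~150 bp upstream
of the TSS, so the profile mode should land in the [-200, 0) bin.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from chiptargets import read_gff3_genes
from chiptargets.motif import (
    center_distance_density,
    normalized_position_profile,
    sites_per_peak,
)

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "compare_step", Path(__file__).parent / "03_compare_conditions.py"
)
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
read_consensus_bed = _mod.read_consensus_bed


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--motifs", nargs="+", default=["GTACTRC", "TCTTCTST"])
    args = ap.parse_args()
    sim = args.results / "sim"

    cons = read_consensus_bed(args.results / "consensus_low_cu.bed", "low_cu")
    genome = {rec.name: str(rec[:]) for rec in Fasta(str(sim / "genome.fa"))}
    genes = {g.gene_id: g for g in read_gff3_genes(sim / "genes.gff3")}
    links = pd.read_csv(args.results / "peak_gene_links.tsv", sep="\t")
    links = links[links.condition == "low_cu"]
    best = (
        links.assign(absd=links.signed_distance.abs())
        .sort_values("absd")
        .drop_duplicates("peak_id")
        .set_index("peak_id")["gene_id"]
    )

    for pattern in args.motifs:
        sites, per_peak, hist = sites_per_peak(cons, genome, pattern)
        n_with = sum(1 for v in per_peak.values() if v)
        print(f"{pattern}: {len(sites)} sites in {n_with}/{len(cons)} peaks; "
              f"copies-per-peak histogram {dict(sorted(hist.items()))}")

        edges, dens = center_distance_density(sites)
        if dens.size:
            k = int(np.argmax(dens))
            print(f"{pattern}: peak-center distance mode in "
                  f"[{edges[k]:.1f}, {edges[k + 1]:.1f}) bp")

        linked = [(s, best[s.peak_id]) for s in sites if s.peak_id in best.index]
        pedges, counts, skipped = normalized_position_profile(linked, genes)
        pd.DataFrame({"bin_lo": pedges[:-1].astype(int),
                      "bin_hi": pedges[1:].astype(int),
                      "count": counts}).to_csv(
            args.results / f"motif_{pattern}_profile.tsv", sep="\t", index=False)
        if counts.sum():
            k = int(np.argmax(counts))
            print(f"{pattern}: metagene profile mode in "
                  f"[{int(pedges[k])}, {int(pedges[k + 1])}) "
                  f"({counts.sum()} mapped sites, {skipped} skipped)")


if __name__ == "__main__":
    main()
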