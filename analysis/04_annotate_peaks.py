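"""Associate consensus peaks with genes and locate them around the TSS.

Links each peak to every gene whose body or 2-kb promoter it touches,
assigns P (promoter) / S (start-overlapping) / G (gene-body) codes, and
bins the signed TSS-to-peak-center distances. The modal bin should sit
just upstream of the TSS, where the generator plants its sites.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from chiptargets import read_gff3_genes
from chiptargets.annotate import associate_peaks, tss_distance_histogram

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
    ap.add_argument("--upstream", type=int, default=2000)
    ap.add_argument("--bin", type=int, default=200)
    args = ap.parse_args()

    genes = read_gff3_genes(args.results / "sim" / "genes.gff3")
    rows = []
    for cond in ("low_cu", "control_cu"):
        cons = read_consensus_bed(args.results / f"consensus_{cond}.bed", cond)
        links = associate_peaks(cons, genes, args.upstream)
        rows.extend(
            {
                "peak_id": ln.consensus_peak.peak_id,
                "condition": cond,
                "gene_id": ln.gene_id,
                "localization": ln.localization,
                "signed_distance": ln.signed_distance,
                "support": ln.consensus_peak.support,
            }
            for ln in links
        )
        n_genes = len({ln.gene_id for ln in links})
        locs = pd.Series([ln.localization for ln in links]).value_counts().to_dict()
        print(f"{cond}: {len(links)} peak-gene links, {n_genes} genes, P/S/G = {locs}")

        edges = np.arange(-args.upstream, args.upstream + args.bin, args.bin, dtype=float)
        counts = tss_distance_histogram(links, edges)
        modal = int(edges[int(np.argmax(counts))])
        print(f"{cond}: modal TSS-distance bin [{modal}, {modal + args.bin}) bp")

    df = pd.DataFrame(rows)
    df.to_csv(args.results / "peak_gene_links.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
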