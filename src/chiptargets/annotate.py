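"""Peak-to-gene association and TSS-relative positioning.

A consensus peak is linked to every gene whose body it overlaps and to
every gene whose TSS lies at most ``upstream_bp`` (default 2,000)
downstream of any part of the peak, in gene orientation — i.e. the peak
touches the promoter window. One peak may link to several genes and one
gene to several peaks.

Each link carries a localization code:

* ``S`` — the peak interval contains the TSS coordinate;
* ``P`` — the peak lies entirely 5' (upstream) of the TSS;
* ``G`` — the peak lies entirely 3' of the TSS, in (or extending past)
  the gene body.

and a signed distance from TSS to peak center in gene orientation
(negative = upstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .consensus import ConsensusPeak
from .io import GeneModel

PROMOTER = "P"
START = "S"
GENE_BODY = "G"


@dataclass(frozen=True)
class PeakGeneLink:
    consensus_peak: ConsensusPeak
    gene_id: str
    localization: str
    signed_distance: float


def localize(peak: ConsensusPeak, gene: GeneModel) -> str:
    """P/S/G code of a peak relative to a gene's TSS."""
    iv = peak.interval
    tss = gene.tss
    if iv.start <= tss < iv.end:
        return START
    if gene.strand == "+":
        return PROMOTER if iv.end <= tss else GENE_BODY
    return PROMOTER if iv.start > tss else GENE_BODY


def associate_peaks(
    consensus: Sequence[ConsensusPeak],
    genes: Sequence[GeneModel],
    upstream_bp: int = 2000,
) -> list[PeakGeneLink]:
    """Link consensus peaks to genes (body overlap or promoter overlap).

    Output is ordered by (chrom, peak start, gene id) and deterministic.
    """
    import logging

    if not genes:
        logging.getLogger(__name__).warning("associate_peaks: empty gene list")
        return []
    links: list[PeakGeneLink] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: (g.interval.start, g.gene_id))
    for peak in sorted(
        consensus, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end)
    ):
        iv = peak.interval
        for gene in by_chrom.get(iv.chrom, []):
            giv = gene.interval
            body_hit = iv.overlaps(giv)
            if gene.strand == "+":
                promoter_lo, promoter_hi = giv.start - upstream_bp, giv.start
            else:
                promoter_lo, promoter_hi = giv.end, giv.end + upstream_bp
            promoter_hit = iv.start < promoter_hi and promoter_lo < iv.end
            if not (body_hit or promoter_hit):
                continue
            links.append(
                PeakGeneLink(
                    consensus_peak=peak,
                    gene_id=gene.gene_id,
                    localization=localize(peak, gene),
                    signed_distance=gene.oriented_offset(iv.center),
                )
            )
    return links


def tss_distance_histogram(
    links: Iterable[PeakGeneLink], bin_edges: Sequence[float]
) -> np.ndarray:
    """Counts of signed TSS-to-peak-center distances in half-open bins.

    ``bin_edges`` must be strictly increasing; distances outside
    [edges[0], edges[-1]) are not counted.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be a strictly increasing sequence")
    d = np.array([ln.signed_distance for ln in links], dtype=float)
    if d.size == 0:
        return np.zeros(len(edges) - 1, dtype=int)
    # np.histogram closes the last bin; shave its right edge to keep all
    # bins half-open
    counts, _ = np.histogram(d[(d >= edges[0]) & (d < edges[-1])], bins=edges)
    return counts.astype(int)


def localization_code_string(links: Sequence[PeakGeneLink]) -> str:
    """Per-gene code like ``"4G"`` or ``"4P, 2P"``.

    Each distinct peak linked to the gene contributes
    ``<replicate support><localization letter>``; multiple peaks are
    comma-joined, ordered by descending support then by code letter.
    """
    if not links:
        raise ValueError("localization_code_string requires at least one link")
    seen = {}
    for ln in links:
        seen[ln.consensus_peak.peak_id] = (ln.consensus_peak.support, ln.localization)
    codes = sorted(seen.values(), key=lambda sl: (-sl[0], sl[1]))
    return ", ".join(f"{support}{loc}" for support, loc in codes)
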