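"""IUPAC degenerate motif scanning and positional statistics.

The scanner reports every exact degenerate match on both strands (minus
strand sites are matches of the reverse-complement pattern, reported in
plus-strand coordinates). Overlapping matches are all reported; an ``N``
in the sequence matches only an ``N`` motif position. Positional
statistics use the site midpoint: distance to the consensus-peak center
(75-bp bins by default) and a metagene profile in which every gene body
is rescaled to a common length (2,000 bp by default) while upstream and
downstream flanks stay in real bp.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .consensus import ConsensusPeak
from .io import GeneModel, GenomicInterval

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Motifs of interest shipped as presets: the degenerate binding motif of
#: the copper-deficiency factor (R = A/G), the second enriched motif, the
#: bare GTAC core recognized by the SBP DNA-binding domain, and its
#: extended variants.
PRESET_MOTIFS: dict[str, str] = {
    "GTACTRC": "GTACTRC",
    "TCTTCTST": "TCTTCTST",
    "GTAC_core": "GTAC",
    "AGTACA": "AGTACA",
    "TGTACT": "TGTACT",
}


def reverse_complement(pattern: str) -> str:
    """Reverse complement over the full IUPAC alphabet."""
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate nucleotide pattern, max 20 bp."""

    pattern: str

    def __post_init__(self):
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not 1 <= len(pat) <= 20:
            raise ValueError(f"motif length must be 1..20, got {len(pat)}")
        for ch in pat:
            if ch not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {ch!r} in motif {pat!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def revcomp(self) -> "IupacMotif":
        return IupacMotif(reverse_complement(self.pattern))


@dataclass(frozen=True)
class MotifSite:
    """One motif occurrence in plus-strand genomic coordinates."""

    interval: GenomicInterval
    strand: str
    matched_text: str
    peak_id: Optional[str] = None
    offset_from_peak_center: Optional[float] = None

    @property
    def midpoint(self) -> float:
        return self.interval.center


def _match_positions(seq_codes: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions of exact degenerate matches on the given strand."""
    m = len(pattern)
    n = len(seq_codes)
    if n < m:
        return np.array([], dtype=int)
    ok = np.ones(n - m + 1, dtype=bool)
    for j, ch in enumerate(pattern):
        allowed = np.frombuffer(
            "".join(sorted(IUPAC_CODES[ch])).encode(), dtype=np.uint8
        )
        ok &= np.isin(seq_codes[j : j + n - m + 1], allowed)
    return np.flatnonzero(ok)


def scan(
    seq: str,
    motif: Union[IupacMotif, str],
    both_strands: bool = True,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifSite]:
    """All exact degenerate matches of ``motif`` in ``seq``.

    ``offset`` shifts reported coordinates so that ``seq[0]`` sits at
    genomic position ``offset`` on chromosome ``chrom``. Minus-strand
    sites are matches of the reverse-complement pattern; their
    ``matched_text`` is given 5'->3' on the minus strand. Results are
    ordered by position, plus strand before minus at ties.
    """
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters {sorted(bad)}")
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    m = len(motif)
    hits: list[tuple[int, str]] = [(int(p), "+") for p in _match_positions(codes, motif.pattern)]
    if both_strands:
        rc = motif.revcomp.pattern
        hits += [(int(p), "-") for p in _match_positions(codes, rc)]
    hits.sort(key=lambda ps: (ps[0], ps[1]))
    sites = []
    for pos, strand in hits:
        text = seq[pos : pos + m]
        if strand == "-":
            text = reverse_complement(text)
        sites.append(
            MotifSite(
                interval=GenomicInterval(chrom, offset + pos, offset + pos + m, strand),
                strand=strand,
                matched_text=text,
            )
        )
    return sites


def _chrom_seq(genome, chrom: str) -> str:
    """Fetch a full chromosome string from a dict or a pyfaidx.Fasta."""
    seq = genome[chrom]
    return seq if isinstance(seq, str) else str(seq[:])


def sites_per_peak(
    peaks: Sequence[ConsensusPeak],
    genome,
    motif: Union[IupacMotif, str],
    both_strands: bool = True,
) -> tuple[list[MotifSite], dict[str, int], Counter]:
    """Motif occurrences inside consensus peaks and copies-per-peak counts.

    ``genome`` maps chromosome name -> sequence (a plain dict or a
    ``pyfaidx.Fasta``). A site belongs to a peak when its midpoint lies
    inside the peak interval; the scanned window is widened by one motif
    length on each side so boundary-straddling sites are not missed.
    Returns (sites, per-peak counts, histogram over copy number
    including the zero class).
    """
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    m = len(motif)
    all_sites: list[MotifSite] = []
    per_peak: dict[str, int] = {}
    for peak in peaks:
        iv = peak.interval
        chrom_seq = _chrom_seq(genome, iv.chrom)
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"peak {peak.peak_id} extends past the end of {iv.chrom} "
                f"({iv.end} > {len(chrom_seq)})"
            )
        lo = max(0, iv.start - (m - 1))
        hi = min(len(chrom_seq), iv.end + (m - 1))
        window_sites = scan(
            chrom_seq[lo:hi], motif, both_strands, chrom=iv.chrom, offset=lo
        )
        n_in = 0
        for s in window_sites:
            mid = s.midpoint
            if iv.start <= mid < iv.end:
                n_in += 1
                all_sites.append(
                    MotifSite(
                        interval=s.interval,
                        strand=s.strand,
                        matched_text=s.matched_text,
                        peak_id=peak.peak_id,
                        offset_from_peak_center=mid - iv.center,
                    )
                )
        per_peak[peak.peak_id] = n_in
    histogram = Counter(per_peak.values())
    return all_sites, per_peak, histogram


def center_distance_density(
    sites: Sequence[MotifSite],
    bin_bp: float = 75.0,
    absolute: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned density of motif-to-peak-center offsets.

    Bins are half-open, ``bin_bp`` wide and centered on zero (edges at
    ±(k + 1/2)·bin_bp). Returns (edges, densities); densities sum to 1
    when sites exist, and both arrays are empty when none do. With
    ``absolute=True`` offsets are folded to |offset| first (bins then
    start at 0).
    """
    offsets = np.array(
        [s.offset_from_peak_center for s in sites if s.offset_from_peak_center is not None],
        dtype=float,
    )
    if offsets.size == 0:
        return np.array([]), np.array([])
    if absolute:
        offsets = np.abs(offsets)
        kmax = int(np.floor(offsets.max() / bin_bp)) + 1
        edges = np.arange(0, kmax + 1) * bin_bp
    else:
        # symmetric edges at ±(k+1/2)·bin_bp, central bin straddling zero
        kmax = int(np.floor(np.abs(offsets).max() / bin_bp + 0.5)) + 1
        edges = (np.arange(-kmax, kmax) + 0.5) * bin_bp
    counts, _ = np.histogram(offsets, bins=edges)
    return edges, counts / counts.sum()


def normalized_gene_coordinate(
    oriented_offset: float, gene_length: int, body_norm: int = 2000
) -> float:
    """Map a TSS-relative offset onto the metagene axis.

    Upstream offsets (< 0) stay in real bp; a position at fraction f of
    the gene body maps to f·body_norm; positions past the gene end map
    to body_norm plus their real distance beyond the end.
    """
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if oriented_offset < 0:
        return oriented_offset
    if oriented_offset < gene_length:
        return oriented_offset / gene_length * body_norm
    return body_norm + (oriented_offset - gene_length)


def normalized_position_profile(
    linked_sites: Sequence[tuple[MotifSite, str]],
    genes: Mapping[str, GeneModel],
    upstream_bp: int = 2000,
    downstream_bp: int = 2000,
    body_norm: int = 2000,
    bin_bp: int = 200,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Metagene motif-frequency profile with the gene body length-normalized.

    ``linked_sites`` pairs each site with the gene id it is assigned to.
    The profile covers [-upstream_bp, body_norm + downstream_bp) in
    ``bin_bp`` half-open bins; sites whose gene is unknown or whose
    coordinate falls outside the range are skipped (skip count is the
    third return value). Returns (edges, counts, n_skipped).
    """
    import logging

    edges = np.arange(-upstream_bp, body_norm + downstream_bp + bin_bp, bin_bp, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    skipped = 0
    for site, gene_id in linked_sites:
        gene = genes.get(gene_id)
        if gene is None or site.interval.chrom != gene.interval.chrom:
            skipped += 1
            continue
        coord = normalized_gene_coordinate(
            gene.oriented_offset(site.midpoint), gene.length, body_norm
        )
        if not (-upstream_bp <= coord < body_norm + downstream_bp):
            skipped += 1
            continue
        counts[int((coord + upstream_bp) // bin_bp)] += 1
    if skipped:
        logging.getLogger(__name__).info(
            "normalized_position_profile: %d sites skipped", skipped
        )
    return edges, counts, skipped
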