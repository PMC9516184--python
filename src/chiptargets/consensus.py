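"""Consensus peak construction across replicates.

Two replicate peaks belong together when at least ``min_frac`` (default
80%) of the length of the shorter segment overlaps the other segment.
Peaks are merged as connected components of that pairwise criterion
(single linkage over the original replicate peaks; merged segments are
not re-tested). The consensus interval is the union span of the
component's members, so it is always at least as long as the broadest
member — an invariant asserted on every output. Components supported by
fewer than ``min_support`` distinct replicates are dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import GenomicInterval, Peak

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusPeak:
    """A merged segment with its replicate support."""

    interval: GenomicInterval
    support: int
    member_ids: tuple[str, ...]
    condition: str
    genotype: str
    name: Optional[str] = None

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return self.name or f"{self.condition}:{iv.chrom}:{iv.start}-{iv.end}"


def merge_criterion(
    a: GenomicInterval, b: GenomicInterval, min_frac: float = 0.8
) -> bool:
    """True when the overlap covers >= ``min_frac`` of the shorter segment.

    Symmetric; different chromosomes simply do not merge.
    """
    if not 0.0 < min_frac <= 1.0:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if a.chrom != b.chrom:
        return False
    overlap = a.overlap_length(b)
    return overlap >= min_frac * min(a.length, b.length)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_replicates(
    peaks: Iterable[Peak],
    min_frac: float = 0.8,
    min_support: int = 2,
) -> list[ConsensusPeak]:
    """Merge one (condition, genotype) group of replicate peaks.

    Returns consensus peaks ordered by (chrom, start, end); the result is
    independent of input order. Identical duplicate peaks from the same
    replicate are deduplicated with a warning. Support counts distinct
    replicate ids, not member peaks, so two peaks from the same replicate
    in one component contribute support 1.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    peaks = list(peaks)
    if not peaks:
        return []
    conditions = {p.condition for p in peaks}
    genotypes = {p.genotype for p in peaks}
    if len(conditions) > 1 or len(genotypes) > 1:
        raise ValueError(
            "merge_replicates expects a single (condition, genotype) group; "
            f"got conditions={sorted(conditions)} genotypes={sorted(genotypes)}"
        )
    condition, genotype = conditions.pop(), genotypes.pop()

    seen: set[tuple] = set()
    unique: list[Peak] = []
    for p in peaks:
        key = (p.replicate_id, p.interval)
        if key in seen:
            logger.warning("duplicate peak %s from replicate %s dropped", p.interval, p.replicate_id)
            continue
        seen.add(key)
        unique.append(p)
    # canonical order removes any input-order dependence
    unique.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.replicate_id))

    uf = _UnionFind(len(unique))
    # sweep: peaks satisfying the criterion necessarily overlap, and after
    # sorting by start an overlapping pair is never separated by a peak
    # whose start lies beyond the earlier peak's end
    active: list[int] = []
    current_chrom = None
    for i, p in enumerate(unique):
        iv = p.interval
        if iv.chrom != current_chrom:
            active = []
            current_chrom = iv.chrom
        active = [j for j in active if unique[j].interval.end > iv.start]
        for j in active:
            if merge_criterion(iv, unique[j].interval, min_frac):
                uf.union(i, j)
        active.append(i)

    components: dict[int, list[int]] = {}
    for i in range(len(unique)):
        components.setdefault(uf.find(i), []).append(i)

    out: list[ConsensusPeak] = []
    dropped = 0
    for members in components.values():
        ivs = [unique[i].interval for i in members]
        support = len({unique[i].replicate_id for i in members})
        if support < min_support:
            dropped += 1
            continue
        union = GenomicInterval(
            ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
        )
        assert union.length >= max(iv.length for iv in ivs), (
            "consensus segment shorter than a member peak"
        )
        out.append(
            ConsensusPeak(
                interval=union,
                support=support,
                member_ids=tuple(sorted(unique[i].peak_id for i in members)),
                condition=condition,
                genotype=genotype,
            )
        )
    if dropped:
        logger.info(
            "dropped %d consensus segments with support < %d", dropped, min_support
        )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return [
        ConsensusPeak(
            interval=c.interval,
            support=c.support,
            member_ids=c.member_ids,
            condition=c.condition,
            genotype=c.genotype,
            name=f"{c.condition}_peak_{k:05d}",
        )
        for k, c in enumerate(out, start=1)
    ]


def consensus_summary(consensus: Iterable[ConsensusPeak]) -> pd.DataFrame:
    """Counts of consensus peaks per (condition, support) level."""
    counts = Counter((c.condition, c.support) for c in consensus)
    rows = [
        {"condition": cond, "support": sup, "n_peaks": n}
        for (cond, sup), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["condition", "support", "n_peaks"])
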