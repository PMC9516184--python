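"""Shared factories and independent brute-force oracles for the tests.

The oracles here deliberately use naive algorithms (all-pairs graphs,
regex expansion, exact rational enumeration) so they share no code path
with the implementations they check.
"""

from __future__ import annotations

import re
from fractions import Fraction
from math import comb

from chiptargets.condition import windows_overlap
from chiptargets.consensus import ConsensusPeak, merge_criterion
from chiptargets.io import LOW_CU, TAGGED, GenomicInterval, Peak
from chiptargets.motif import IUPAC_CODES


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def peak(start, end, rep="R1", chrom="chr1", condition=LOW_CU, genotype=TAGGED, score=None):
    return Peak(GenomicInterval(chrom, start, end), rep, condition, genotype, score)


def cons(start, end, chrom="chr1", support=2, condition=LOW_CU, name=None):
    return ConsensusPeak(
        interval=GenomicInterval(chrom, start, end),
        support=support,
        member_ids=(),
        condition=condition,
        genotype=TAGGED,
        name=name,
    )


def brute_force_components(peaks, min_frac=0.8):
    """Connected components of the pairwise merge criterion, by BFS on an
    explicitly built O(n^2) adjacency list."""
    n = len(peaks)
    adj = [
        [j for j in range(n) if j != i
         and merge_criterion(peaks[i].interval, peaks[j].interval, min_frac)]
        for i in range(n)
    ]
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        seen.add(i)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(frozenset(peaks[k].peak_id for k in comp))
    return set(comps)


def brute_force_presence(low, ctrl, frac=0.3):
    """All-pairs condition-presence classification."""
    low_shared = {
        p.peak_id for p in low if any(windows_overlap(p, q, frac) for q in ctrl)
    }
    ctrl_shared = {
        q.peak_id for q in ctrl if any(windows_overlap(q, p, frac) for p in low)
    }
    return low_shared, ctrl_shared


def iupac_regex(pattern):
    return "".join(
        ch if len(IUPAC_CODES[ch]) == 1 else "[" + "".join(sorted(IUPAC_CODES[ch])) + "]"
        for ch in pattern
    )


def regex_scan(seq, pattern, revcomp_pattern):
    """(position, strand) pairs of all overlapping degenerate matches,
    via lookahead regex on the plus-strand sequence."""
    hits = []
    for pat, strand in ((pattern, "+"), (revcomp_pattern, "-")):
        rx = re.compile("(?=" + iupac_regex(pat) + ")")
        hits.extend((m.start(), strand) for m in rx.finditer(seq))
    return sorted(hits)


def hypergeom_enumerate(N, K, n, k):
    """Exact upper-tail hypergeometric probability as a Fraction."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return acc
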