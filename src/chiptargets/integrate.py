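"""ChIP x expression integration and gene-set overlap testing.

Candidate direct targets are genes that carry a consensus binding peak
under a condition AND are differentially expressed between wild type and
mutant under the matching contrast: higher in WT = candidate for direct
activation by the factor, lower in WT = candidate for direct repression.
Gene-set overlaps against external lists (e.g. in-vitro binding maps)
are tested with the upper-tail hypergeometric distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotate import PeakGeneLink
from .condition import LOW_ONLY, CONTROL_ONLY, SHARED, PeakClass
from .io import DERecord

ACTIVATED = "activated"
REPRESSED = "repressed"
UNCHANGED = "unchanged"

DIRECT_ACTIVATION = "direct_activation_candidate"
DIRECT_REPRESSION = "direct_repression_candidate"


@dataclass(frozen=True)
class RegulationClass:
    gene_id: str
    condition: str
    regulation: str  # activated / repressed / unchanged


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    condition: str
    verdict: str
    peak_ids: tuple[str, ...]
    log2fc: float
    padj: Optional[float]


@dataclass(frozen=True)
class OverlapTestResult:
    universe_size: int
    set_a_size: int
    set_b_size: int
    observed_overlap: int
    expected_overlap: float
    p_value: float


def classify_regulation(
    de: Iterable[DERecord],
    padj_max: float = 0.05,
    min_abs_log2fc: float = 0.0,
    contrast_to_condition: Optional[Mapping[str, str]] = None,
) -> list[RegulationClass]:
    """Threshold DE records into activated / repressed / unchanged.

    Activated: log2fc > min_abs_log2fc and padj <= padj_max (fold change
    oriented WT over mutant, so activated means the factor sustains the
    transcript). Missing padj is always unchanged. ``contrast_to_condition``
    optionally renames contrast labels to condition labels.
    """
    if not 0.0 < padj_max <= 1.0:
        raise ValueError(f"padj_max must be in (0, 1], got {padj_max}")
    if min_abs_log2fc < 0:
        raise ValueError("min_abs_log2fc must be >= 0")
    out = []
    for rec in de:
        condition = (
            contrast_to_condition.get(rec.contrast, rec.contrast)
            if contrast_to_condition
            else rec.contrast
        )
        if rec.padj is None or rec.padj > padj_max:
            cls = UNCHANGED
        elif rec.log2fc > min_abs_log2fc:
            cls = ACTIVATED
        elif rec.log2fc < -min_abs_log2fc:
            cls = REPRESSED
        else:
            cls = UNCHANGED
        out.append(RegulationClass(rec.gene_id, condition, cls))
    return out


def call_targets(
    links_by_condition: Mapping[str, Sequence[PeakGeneLink]],
    classes: Iterable[RegulationClass],
    de_by_gene: Optional[Mapping[tuple[str, str], DERecord]] = None,
    peak_presence_filter: str = "any",
    presence_by_peak: Optional[Mapping[str, str]] = None,
) -> tuple[list[TargetCall], dict]:
    """Intersect peak-linked genes with DE classes, per condition.

    ``peak_presence_filter="any"`` accepts every consensus peak present
    under the condition (shared peaks included);
    ``"condition_specific"`` keeps only peaks classified as specific to
    that condition, which requires ``presence_by_peak`` (peak_id ->
    presence label). Genes are deduplicated; one call per (gene,
    condition). Returns (calls, per-condition set-size summary).
    """
    if peak_presence_filter not in ("any", "condition_specific"):
        raise ValueError(f"unknown peak_presence_filter {peak_presence_filter!r}")
    if peak_presence_filter == "condition_specific" and presence_by_peak is None:
        raise ValueError("condition_specific filtering needs presence_by_peak")

    specific_label = {"low_cu": LOW_ONLY, "control_cu": CONTROL_ONLY}
    class_by_gene = {(c.gene_id, c.condition): c.regulation for c in classes}
    calls: list[TargetCall] = []
    counts: dict[str, dict[str, int]] = {}
    for condition, links in links_by_condition.items():
        gene_peaks: dict[str, set[str]] = {}
        for ln in links:
            pid = ln.consensus_peak.peak_id
            if peak_presence_filter == "condition_specific":
                wanted = specific_label.get(condition, condition)
                if presence_by_peak.get(pid, SHARED) != wanted:
                    continue
            gene_peaks.setdefault(ln.gene_id, set()).add(pid)
        n_act = n_rep = 0
        for gene_id in sorted(gene_peaks):
            reg = class_by_gene.get((gene_id, condition), UNCHANGED)
            if reg == UNCHANGED:
                continue
            verdict = DIRECT_ACTIVATION if reg == ACTIVATED else DIRECT_REPRESSION
            rec = de_by_gene.get((gene_id, condition)) if de_by_gene else None
            calls.append(
                TargetCall(
                    gene_id=gene_id,
                    condition=condition,
                    verdict=verdict,
                    peak_ids=tuple(sorted(gene_peaks[gene_id])),
                    log2fc=rec.log2fc if rec else float("nan"),
                    padj=rec.padj if rec else None,
                )
            )
            if verdict == DIRECT_ACTIVATION:
                n_act += 1
            else:
                n_rep += 1
        counts[condition] = {
            "genes_with_peak": len(gene_peaks),
            DIRECT_ACTIVATION: n_act,
            DIRECT_REPRESSION: n_rep,
        }
    return calls, counts


def hypergeom_overlap(N: int, K: int, n: int, k: int) -> OverlapTestResult:
    """Upper-tail hypergeometric test of a gene-set overlap.

    ``N`` universe size, ``K`` genes in set A, ``n`` genes in set B,
    ``k`` observed shared genes. p = P(X >= k) for X ~ Hypergeom(N, K, n),
    evaluated via the survival function (stable in log space inside
    scipy); expected overlap is nK/N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N, got N={N} K={K} n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    if k == 0:
        p = 1.0
    else:
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    return OverlapTestResult(
        universe_size=N,
        set_a_size=K,
        set_b_size=n,
        observed_overlap=k,
        expected_overlap=n * K / N if N else float("nan"),
        p_value=p,
    )


def overlap_test(
    universe: Iterable[str], set_a: Iterable[str], set_b: Iterable[str]
) -> OverlapTestResult:
    """Convenience wrapper: overlap test on explicit gene-id sets.

    Sets are intersected with the universe first so stray identifiers
    cannot inflate the counts.
    """
    uni = set(universe)
    a = set(set_a) & uni
    b = set(set_b) & uni
    return hypergeom_overlap(len(uni), len(a), len(b), len(a & b))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values, for batches of overlap tests."""
    if len(p_values) == 0:
        return np.array([])
    return multipletests(p_values, method="fdr_bh")[1]
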