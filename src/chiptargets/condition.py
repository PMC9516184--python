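"""Cross-condition peak matching and negative-control flagging.

A consensus peak is considered present in both conditions when the
center windows of a peak pair — peak mid-point ± ``frac`` (default 30%)
of the segment length — overlap by any amount. Window bounds are kept as
exact reals (half-integer centers are never rounded). Negative-control
(mock) overlap uses plain >=1 bp interval intersection instead; flagged
peaks are reported, not removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .consensus import ConsensusPeak
from .io import GenomicInterval, Peak

LOW_ONLY = "low_cu_only"
CONTROL_ONLY = "control_cu_only"
SHARED = "shared"


@dataclass(frozen=True)
class PeakClass:
    """Condition-presence verdict for one consensus peak."""

    consensus_peak: ConsensusPeak
    presence: str
    control_flagged: bool = False
    matched_partner: Optional[str] = None


def center_window(peak: ConsensusPeak, frac: float = 0.3) -> tuple[float, float]:
    """(lo, hi) of the peak-center ± frac·length window, exact reals."""
    iv = peak.interval
    half = frac * iv.length
    return iv.center - half, iv.center + half


def windows_overlap(p: ConsensusPeak, q: ConsensusPeak, frac: float = 0.3) -> bool:
    """True when the two center windows intersect (half-open comparison)."""
    if frac <= 0:
        raise ValueError(f"window fraction must be > 0, got {frac}")
    if p.interval.chrom != q.interval.chrom:
        return False
    lo_p, hi_p = center_window(p, frac)
    lo_q, hi_q = center_window(q, frac)
    return lo_p < hi_q and lo_q < hi_p


def classify_presence(
    low: Sequence[ConsensusPeak],
    ctrl: Sequence[ConsensusPeak],
    frac: float = 0.3,
) -> tuple[list[PeakClass], list[PeakClass], dict]:
    """Classify each peak of both conditions as condition-specific or shared.

    A low-Cu peak is shared when its center window overlaps that of ANY
    control-condition peak, and vice versa; counts are per peak, not per
    matched pair, so the shared count may differ slightly between sides
    when matches are one-to-many. Returns (low classes, control classes,
    venn counts).
    """
    low_sorted = sorted(low, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    ctrl_sorted = sorted(ctrl, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))

    def _classes(peaks, others, own_only):
        out = []
        for p in peaks:
            partner = next(
                (q for q in others if windows_overlap(p, q, frac)), None
            )
            if partner is not None:
                out.append(PeakClass(p, SHARED, matched_partner=partner.peak_id))
            else:
                out.append(PeakClass(p, own_only))
        return out

    low_classes = _classes(low_sorted, ctrl_sorted, LOW_ONLY)
    ctrl_classes = _classes(ctrl_sorted, low_sorted, CONTROL_ONLY)
    venn = {
        "low_cu_only": sum(c.presence == LOW_ONLY for c in low_classes),
        "shared_low_cu": sum(c.presence == SHARED for c in low_classes),
        "shared_control_cu": sum(c.presence == SHARED for c in ctrl_classes),
        "control_cu_only": sum(c.presence == CONTROL_ONLY for c in ctrl_classes),
    }
    return low_classes, ctrl_classes, venn


def flag_control_overlap(
    consensus: Sequence[ConsensusPeak], mock_peaks: Iterable[Peak]
) -> tuple[dict[str, bool], int]:
    """Flag consensus peaks intersecting any untagged-control (mock) peak.

    Plain >=1 bp overlap on the raw intervals — deliberately not the
    center-window rule. Returns ({peak_id: flagged}, flagged count);
    callers decide whether to exclude flagged peaks.
    """
    mock_ivs = [m.interval for m in mock_peaks]
    flags = {
        c.peak_id: any(c.interval.overlaps(m) for m in mock_ivs)
        for c in consensus
    }
    return flags, sum(flags.values())


def apply_presence_flags(
    classes: Sequence[PeakClass], flags: dict[str, bool]
) -> list[PeakClass]:
    """Return classes with ``control_flagged`` filled from a flag map."""
    return [
        PeakClass(
            consensus_peak=c.consensus_peak,
            presence=c.presence,
            control_flagged=flags.get(c.consensus_peak.peak_id, False),
            matched_partner=c.matched_partner,
        )
        for c in classes
    ]
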