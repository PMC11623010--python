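"""Nucleus selection, HER2/CEP17 ratio and amplification status.

The region score follows dual-probe ISH practice: qualified nuclei are
ranked by their HER2−CEP17 differentiation, at least 20 representatives are
selected, and the region ratio is the sum of HER2 signals over the sum of
CEP17 signals across the selection.  Mean HER2 copies per nucleus is also
computed; when it lands in the ASCO/CAP equivocal copy-number band [4, 6) a
second set of 20 nuclei is counted and the totals recomputed over >= 40
nuclei before the status call.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .nuclei import NucleusRecord

POSITIVE = "Positive"
NEGATIVE = "Negative"
EQUIVOCAL = "Equivocal"


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed ratio tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StatusThresholds:
    """Cutoffs for the amplification call.

    ``binary_ratio`` (default): Positive iff ratio >= ``binary_cutoff``.
    ``three_way_ratio``: Negative < 1.8 <= Equivocal <= 2.0 < Positive.
    ``asco_full``: ratio rule first, then copy-number bands (>= 6 Positive,
    [4, 6) Equivocal) for sub-cutoff ratios.
    """

    binary_cutoff: float = 2.0
    negative_below: float = 1.8
    equivocal_upper: float = 2.0
    copy_positive: float = 6.0
    copy_equivocal_low: float = 4.0
    mode: str = "binary_ratio"

    def __post_init__(self) -> None:
        if self.mode not in ("binary_ratio", "three_way_ratio", "asco_full"):
            raise ValueError(f"unknown status mode {self.mode!r}")
        if not self.negative_below <= self.equivocal_upper:
            raise ValueError("negative_below must be <= equivocal_upper")
        if not self.copy_equivocal_low <= self.copy_positive:
            raise ValueError("copy_equivocal_low must be <= copy_positive")


@dataclass
class ScoreResult:
    """Region-level quantification outcome."""

    n_quantified: int
    total_her2: int
    total_cep17: int
    ratio: float  # rounded to 2 decimals for reporting
    raw_ratio: float
    copies_per_nucleus: float
    status: str
    fallback_used: bool = False
    extra_set_counted: bool = False
    low_confidence: bool = False


def rank_nuclei(records: list[NucleusRecord]) -> list[NucleusRecord]:
    """Descending differentiation (HER2−CEP17); ties broken by higher HER2
    count, then lower label — a deterministic total order."""
    return sorted(
        records, key=lambda r: (-r.differentiation, -r.her2_count, r.label)
    )


def select_nuclei(
    ranked: list[NucleusRecord], n: int = 20
) -> tuple[list[NucleusRecord], bool]:
    """First ``min(n, available)`` ranked nuclei.

    Returns ``(selection, low_confidence)``; ``low_confidence`` is set when
    fewer than ``n`` nuclei were available.
    """
    if not ranked:
        raise ValueError("no quantifiable nuclei to select from")
    return ranked[:n], len(ranked) < n


def compute_ratio(selection: list[NucleusRecord]) -> float:
    """HER2/CEP17 ratio over the selection: sum HER2 / sum CEP17 (raw)."""
    if not selection:
        raise ValueError("cannot compute a ratio over an empty selection")
    total_cep17 = sum(r.cep17_count for r in selection)
    if total_cep17 == 0:
        raise ZeroDivisionError(
            "total CEP17 is zero over the selection; qualify nuclei through "
            "the single-CEP17 fallback before scoring"
        )
    return sum(r.her2_count for r in selection) / total_cep17


def copies_per_nucleus(selection: list[NucleusRecord]) -> float:
    """Mean HER2 copies per quantified nucleus."""
    if not selection:
        raise ValueError("cannot compute copies over an empty selection")
    return sum(r.her2_count for r in selection) / len(selection)


def classify(
    ratio: float, copies: float = 0.0, thresholds: StatusThresholds | None = None
) -> str:
    """Amplification status from the (unrounded) ratio and copy number."""
    t = thresholds or StatusThresholds()
    if t.mode == "binary_ratio":
        return POSITIVE if ratio >= t.binary_cutoff else NEGATIVE
    if t.mode == "three_way_ratio":
        if ratio < t.negative_below:
            return NEGATIVE
        if ratio <= t.equivocal_upper:
            return EQUIVOCAL
        return POSITIVE
    # asco_full: ratio rule first, copy-number bands for sub-cutoff ratios
    if ratio >= t.binary_cutoff:
        return POSITIVE
    if copies >= t.copy_positive:
        return POSITIVE
    if copies >= t.copy_equivocal_low:
        return EQUIVOCAL
    return NEGATIVE


def score_roi(
    records: list[NucleusRecord],
    thresholds: StatusThresholds | None = None,
    n_first: int = 20,
    n_extra: int = 20,
    fallback_used: bool = False,
) -> ScoreResult:
    """Score a region from its qualified nucleus records.

    Rank, select ``n_first``, compute ratio and copies; if copies lands in
    the equivocal copy-number band and more ranked nuclei exist, count the
    next ``n_extra`` and recompute over the enlarged selection before
    classifying.
    """
    t = thresholds or StatusThresholds()
    if not records:
        raise ValueError("scoring failed: zero qualified nuclei after filtering")
    ranked = rank_nuclei(records)
    selection, low_confidence = select_nuclei(ranked, n_first)
    copies = copies_per_nucleus(selection)
    extra_set_counted = False
    if (
        t.copy_equivocal_low <= copies < t.copy_positive
        and len(ranked) > len(selection)
    ):
        selection = ranked[: n_first + n_extra]
        copies = copies_per_nucleus(selection)
        extra_set_counted = True
    raw_ratio = compute_ratio(selection)
    status = classify(raw_ratio, copies, t)
    return ScoreResult(
        n_quantified=len(selection),
        total_her2=sum(r.her2_count for r in selection),
        total_cep17=sum(r.cep17_count for r in selection),
        ratio=round_half_away(raw_ratio, 2),
        raw_ratio=raw_ratio,
        copies_per_nucleus=copies,
        status=status,
        fallback_used=fallback_used,
        extra_set_counted=extra_set_counted,
        low_confidence=low_confidence,
    )
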