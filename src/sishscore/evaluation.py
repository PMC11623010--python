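"""Method-comparison statistics against reference (expert) scores.

Bland-Altman agreement analysis on paired region ratios: bias is the mean
of (method − reference) differences, the 95 % limits of agreement are
bias ± 1.96 × SD of the differences (sample SD, 1.96 multiplier as in
standard Bland-Altman practice).  A paired t-test checks whether the bias
differs from zero, and a misclassification table compares thresholded
method ratios with the reference amplification status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

LOA_MULTIPLIER = 1.96


@dataclass
class MethodComparison:
    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    sidedness: str = "two_sided"
    misclassified: int = 0
    false_positives: list = field(default_factory=list)
    false_negatives: list = field(default_factory=list)


def _paired(method: Sequence[float], reference: Sequence[float]) -> np.ndarray:
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("method and reference must be equal-length 1-D vectors")
    if m.size < 2:
        raise ValueError("method comparison needs at least 2 pairs")
    return m - r


def bland_altman(
    method: Sequence[float], reference: Sequence[float]
) -> MethodComparison:
    """Bias and 95 % limits of agreement for paired measurements."""
    d = _paired(method, reference)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return MethodComparison(
        n_pairs=d.size,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
    )


def bias_confidence_interval(
    method: Sequence[float], reference: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Standard CI of the bias: bias ± t_{1−α/2, n−1} · sd/√n."""
    d = _paired(method, reference)
    bias = float(d.mean())
    se = float(d.std(ddof=1)) / np.sqrt(d.size)
    tq = stats.t.ppf(0.5 + level / 2, df=d.size - 1)
    return bias - tq * se, bias + tq * se


def paired_t_test(
    method: Sequence[float],
    reference: Sequence[float],
    sidedness: str = "two_sided",
) -> tuple[float, float]:
    """Paired t-test on the differences; returns ``(t, p)``.

    ``sidedness``: ``two_sided``, ``greater`` (method > reference) or
    ``less``.  Zero-variance differences are handled explicitly: a nonzero
    bias is then infinitely significant (p = 0 toward the favored side),
    while identical vectors give t = 0 with p = 1 (two-sided) or 0.5
    (one-sided) — the null exactly true.
    """
    if sidedness not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    d = _paired(method, reference)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if bias == 0.0:
            return 0.0, 1.0 if sidedness == "two_sided" else 0.5
        t = float("inf") if bias > 0 else float("-inf")
        if sidedness == "two_sided":
            return t, 0.0
        favored = (sidedness == "greater") == (bias > 0)
        return t, 0.0 if favored else 1.0
    t = bias / (sd / np.sqrt(d.size))
    df = d.size - 1
    if sidedness == "two_sided":
        p = 2 * stats.t.sf(abs(t), df)
    elif sidedness == "greater":
        p = stats.t.sf(t, df)
    else:
        p = stats.t.cdf(t, df)
    return float(t), float(p)


def misclassification_table(
    method_ratios: Sequence[float],
    reference_status: Sequence[str],
    cutoff: float = 2.0,
    ids: Sequence | None = None,
) -> tuple[int, list, list]:
    """Disagreements between thresholded method ratios and reference calls.

    False positive: method ratio >= cutoff while the reference is negative;
    false negative: method ratio < cutoff while the reference is positive.
    Returns ``(misclassified, false_positive_ids, false_negative_ids)``.
    """
    m = np.asarray(method_ratios, dtype=float)
    if len(reference_status) != m.size:
        raise ValueError("method_ratios and reference_status lengths differ")
    if ids is None:
        ids = list(range(m.size))
    pos_tokens = {"pos", "positive", "amplified"}
    neg_tokens = {"neg", "negative", "non_amplified", "non-amplified"}
    fps, fns = [], []
    for i, (ratio, status) in enumerate(zip(m, reference_status)):
        token = str(status).strip().lower()
        if token in pos_tokens:
            ref_pos = True
        elif token in neg_tokens:
            ref_pos = False
        else:
            raise ValueError(f"unknown status token {status!r} in row {i}")
        call_pos = ratio >= cutoff
        if call_pos and not ref_pos:
            fps.append(ids[i])
        elif not call_pos and ref_pos:
            fns.append(ids[i])
    return len(fps) + len(fns), fps, fns


def pearson_correlation(
    method: Sequence[float], reference: Sequence[float]
) -> float:
    """Product-moment correlation between the paired measurements."""
    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.size < 2:
        raise ValueError("correlation needs two equal-length vectors, n >= 2")
    if m.std() == 0 or r.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(m, r)[0, 1])


def compare_methods(
    method: Sequence[float],
    reference_ratio: Sequence[float],
    reference_status: Sequence[str],
    ids: Sequence | None = None,
    cutoff: float = 2.0,
    sidedness: str = "two_sided",
) -> MethodComparison:
    """Full comparison: Bland-Altman, paired t-test, misclassification."""
    comp = bland_altman(method, reference_ratio)
    comp.t_statistic, comp.p_value = paired_t_test(method, reference_ratio, sidedness)
    comp.sidedness = sidedness
    comp.misclassified, comp.false_positives, comp.false_negatives = (
        misclassification_table(method, reference_status, cutoff, ids)
    )
    return comp


def bland_altman_plot(
    method: Sequence[float],
    reference: Sequence[float],
    path=None,
    title: str = "Bland-Altman agreement",
):
    """Bland-Altman figure with bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = np.asarray(method, dtype=float)
    r = np.asarray(reference, dtype=float)
    comp = bland_altman(m, r)
    means = (m + r) / 2
    diffs = m - r
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, color="#444")
    ax.axhline(comp.bias, color="red", label=f"bias = {comp.bias:.2f}")
    ax.axhline(comp.loa_high, color="blue", ls="--",
               label=f"upper LoA = {comp.loa_high:.2f}")
    ax.axhline(comp.loa_low, color="green", ls="--",
               label=f"lower LoA = {comp.loa_low:.2f}")
    lo, hi = bias_confidence_interval(m, r)
    ax.axhspan(lo, hi, color="red", alpha=0.12, label="95% CI of bias")
    ax.set_xlabel("mean of method and reference ratio")
    ax.set_ylabel("method − reference")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
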