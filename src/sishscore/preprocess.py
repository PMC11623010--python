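"""Region-of-interest containers and intensity standardization.

Brightfield SISH regions come from whole-slide scans at ~0.13 µm/pixel and
vary in illumination and stain intensity between slides.  Before probe
signals are thresholded by color, each ROI is brought onto a common
intensity range by per-channel min–max (or percentile) normalization, and a
gamma transfer curve may be applied to stretch the dark end where the
silver-stained HER2 dots live.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RoiImage:
    """An RGB region of interest with physical pixel calibration.

    ``pixels`` is an ``H×W×3`` array.  Integer arrays are interpreted as
    8-bit channel data in ``[0, 255]``; floating arrays as normalized data
    in ``[0, 1]`` (the working representation after :func:`normalize_image`).
    """

    pixels: np.ndarray
    resolution_um_per_px: float = 0.13
    image_id: str = "roi"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"RoiImage expects an H×W×3 array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("RoiImage must have at least one pixel")
        if not self.resolution_um_per_px > 0:
            raise ValueError("resolution_um_per_px must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if np.issubdtype(self.pixels.dtype, np.integer):
            if lo < 0 or hi > 255:
                raise ValueError("8-bit channel values must lie in [0, 255]")
        else:
            if lo < -1e-9 or hi > 255 + 1e-9:
                raise ValueError("channel values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def as_float(self) -> np.ndarray:
        """Pixels as float64 scaled to [0, 1]."""
        px = self.pixels
        if np.issubdtype(px.dtype, np.integer):
            return px.astype(np.float64) / 255.0
        out = px.astype(np.float64)
        if out.max() > 1.0 + 1e-9:  # float data still on the 8-bit scale
            out = out / 255.0
        return np.clip(out, 0.0, 1.0)

    def um2_to_px(self, area_um2: float) -> float:
        """Convert a physical area (µm²) to a pixel area."""
        return area_um2 / self.resolution_um_per_px**2


@dataclass
class NormalizationParams:
    """Bounds of the target range (``value_range``) or clipping percentiles
    (``percentile``) for :func:`normalize`."""

    lower_bound: float = 1.0
    upper_bound: float = 99.8
    mode: str = "value_range"

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        if self.mode not in ("value_range", "percentile"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "percentile" and not (
            0 <= self.lower_bound and self.upper_bound <= 100
        ):
            raise ValueError("percentile bounds must lie in [0, 100]")


@dataclass
class GammaParams:
    """Power-law transfer curve ``out = clip(gain * x**gamma, 0, 1)``."""

    gamma: float = 0.5
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.gain > 0:
            raise ValueError("gain must be positive")


def normalize(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Rescale ``values`` onto a standard range.

    In ``value_range`` mode each element is mapped linearly so that the
    input minimum lands on ``lower_bound`` and the maximum on
    ``upper_bound``::

        x' = (x - min(x)) / (max(x) - min(x)) * (upper - lower) + lower

    In ``percentile`` mode the min/max are replaced by the ``lower_bound``-th
    and ``upper_bound``-th percentiles and the mapped result is clipped to
    ``[0, 1]`` — robust contrast stretching that ignores extreme outliers.

    A constant input (max = min) maps to ``lower_bound`` (0 in percentile
    mode) with a warning rather than failing on the 0/0.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot normalize an empty array")
    if params.mode == "value_range":
        lo, hi = float(x.min()), float(x.max())
        span_out = params.upper_bound - params.lower_bound
        if hi == lo:
            warnings.warn(
                "normalize: constant input mapped to lower_bound",
                stacklevel=2,
            )
            return np.full_like(x, params.lower_bound)
        return (x - lo) / (hi - lo) * span_out + params.lower_bound
    # percentile mode
    lo = float(np.percentile(x, params.lower_bound))
    hi = float(np.percentile(x, params.upper_bound))
    if hi == lo:
        warnings.warn(
            "normalize: degenerate percentile window mapped to 0", stacklevel=2
        )
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def gamma_adjust(values: np.ndarray, params: GammaParams) -> np.ndarray:
    """Apply ``clip(gain * values**gamma, 0, 1)`` to data already in [0, 1]."""
    x = np.asarray(values, dtype=np.float64)
    if x.size and (x.min() < -1e-12 or x.max() > 1 + 1e-12):
        raise ValueError("gamma_adjust expects values in [0, 1]")
    return np.clip(params.gain * np.power(np.clip(x, 0.0, 1.0), params.gamma), 0.0, 1.0)


def normalize_image(
    roi: RoiImage,
    norm: NormalizationParams | None = None,
    gamma: GammaParams | None = None,
) -> RoiImage:
    """Standardize an ROI for signal detection.

    Channels are normalized independently — the color identity of the black
    HER2 and red CEP17 probes must survive the rescaling.  When ``norm`` is
    in ``value_range`` mode the output is additionally brought onto [0, 1]
    so the downstream HSV color rules always see normalized data; in
    ``percentile`` mode the formula already lands there.  ``gamma`` (if
    given) is then applied per channel.
    """
    if norm is None:
        norm = NormalizationParams(mode="percentile")
    px = roi.as_float()
    out = np.empty_like(px)
    for c in range(3):
        ch = normalize(px[..., c], norm)
        if norm.mode == "value_range":
            span = norm.upper_bound - norm.lower_bound
            ch = (ch - norm.lower_bound) / span
        out[..., c] = ch
    if gamma is not None:
        out = gamma_adjust(out, gamma)
    return RoiImage(out, roi.resolution_um_per_px, roi.image_id)


def to_uint8(values: np.ndarray) -> np.ndarray:
    """Export float [0,1] data to 8-bit, rounding half away from zero."""
    x = np.clip(np.asarray(values, dtype=np.float64), 0.0, 1.0) * 255.0
    return (np.floor(x + 0.5)).astype(np.uint8)
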