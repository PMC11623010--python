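"""Detection of HER2 (black) and CEP17 (red) probe signals.

In brightfield SISH the HER2 probe deposits silver and appears as black
dots; the CEP17 centromere probe appears as red dots.  Detection is
classical: remove the near-white background, classify candidate pixels by a
hue/saturation/value rule per channel, group candidates into 8-connected
components, reject components outside physical size bounds, drop very faint
components, and optionally decompose large components into multiple signals
by comparing their area with the typical singleton dot area (pathologists
count a large probe cluster as several copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure
from skimage.color import rgb2hsv

from .preprocess import RoiImage

HER2 = "HER2"
CEP17 = "CEP17"


@dataclass
class Spot:
    """One detected probe signal (or decomposed cluster)."""

    channel: str
    centroid_rc: tuple[float, float]
    area_px: int
    signal_count: int = 1
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in (HER2, CEP17):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.area_px < 1:
            raise ValueError("area_px must be positive")
        if self.signal_count < 1:
            raise ValueError("signal_count must be >= 1")


@dataclass
class SpotDetectionConfig:
    """Color and size rules for both probe channels.

    HSV thresholds are on the [0, 1] scale of a normalized image; size
    bounds are physical equivalent diameters so the same configuration works
    across scanner resolutions.  HER2 contrast is darkness ``1 − V``; CEP17
    contrast is ``S × redness`` where redness decays linearly with angular
    hue distance from pure red.
    """

    her2_value_max: float = 0.35
    her2_saturation_max: float = 0.45
    cep17_hue_halfwidth_deg: float = 25.0
    cep17_saturation_min: float = 0.30
    cep17_value_min: float = 0.20
    cep17_value_max: float = 0.90
    min_spot_diameter_um: float = 0.4
    max_spot_diameter_um: float = 2.5
    faint_contrast_min: float = 0.15
    cluster_split: bool = True
    background_whiteness: float = 0.82

    def __post_init__(self) -> None:
        if not 0 < self.min_spot_diameter_um < self.max_spot_diameter_um:
            raise ValueError("need 0 < min_spot_diameter_um < max_spot_diameter_um")
        for name in ("her2_value_max", "her2_saturation_max", "cep17_saturation_min",
                     "cep17_value_min", "cep17_value_max", "faint_contrast_min",
                     "background_whiteness"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.cep17_hue_halfwidth_deg <= 180:
            raise ValueError("cep17_hue_halfwidth_deg must lie in (0, 180]")

    def area_bounds_px(self, resolution_um_per_px: float) -> tuple[float, float]:
        """Pixel-area bounds equivalent to the physical diameter bounds."""
        if not resolution_um_per_px or resolution_um_per_px <= 0:
            raise ValueError(
                "physical size bounds require a positive resolution_um_per_px "
                "calibration on the image"
            )
        r_min = self.min_spot_diameter_um / 2 / resolution_um_per_px
        r_max = self.max_spot_diameter_um / 2 / resolution_um_per_px
        return np.pi * r_min**2, np.pi * r_max**2


def remove_background(
    image: RoiImage, whiteness_threshold: float = 0.82
) -> np.ndarray:
    """Foreground-tissue mask: background is near-white (all channels above
    ``whiteness_threshold`` on the [0, 1] scale)."""
    px = image.as_float()
    background = np.all(px > whiteness_threshold, axis=-1)
    return ~background


def _channel_candidates(
    hsv: np.ndarray, channel: str, config: SpotDetectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean candidate mask and per-pixel contrast for one channel."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if channel == HER2:
        mask = (v <= config.her2_value_max) & (s <= config.her2_saturation_max)
        contrast = 1.0 - v
    else:
        # hue is periodic; distance from pure red (0°) in degrees
        hue_deg = h * 360.0
        dist = np.minimum(hue_deg, 360.0 - hue_deg)
        mask = (
            (dist <= config.cep17_hue_halfwidth_deg)
            & (s >= config.cep17_saturation_min)
            & (v >= config.cep17_value_min)
            & (v <= config.cep17_value_max)
        )
        redness = np.clip(1.0 - dist / 180.0, 0.0, 1.0)
        contrast = s * redness
    return mask, contrast


def detect_spots(
    image: RoiImage, channel: str, config: SpotDetectionConfig | None = None
) -> list[Spot]:
    """Detect probe signals of one channel in a normalized ROI.

    Returns one :class:`Spot` per surviving connected component, ordered by
    scan order of their labels.  With ``cluster_split`` enabled, a component
    much larger than the typical singleton dot is reported with
    ``signal_count = round(area / median singleton area)``.
    """
    if channel not in (HER2, CEP17):
        raise ValueError(f"unknown channel {channel!r}")
    config = config or SpotDetectionConfig()
    px = image.as_float()
    foreground = remove_background(image, config.background_whiteness)
    hsv = rgb2hsv(px)
    mask, contrast = _channel_candidates(hsv, channel, config)
    mask &= foreground

    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return []
    min_area, max_area = config.area_bounds_px(image.resolution_um_per_px)
    comps = [
        p
        for p in measure.regionprops(labels, intensity_image=contrast)
        if min_area <= p.area <= max_area
    ]
    if not comps:
        return []

    counts = np.ones(len(comps), dtype=int)
    if config.cluster_split:
        areas = np.array([p.area for p in comps], dtype=float)
        # singleton dot area estimated from the population: components no
        # larger than twice the lower-quartile area (robust both to large
        # clusters and to small border-clipped fragments)
        singleton = areas <= 2.0 * np.percentile(areas, 25)
        median_area = float(np.median(np.sort(areas[singleton])))
        counts = np.maximum(1, np.rint(areas / median_area).astype(int))

    return [
        Spot(
            channel=channel,
            centroid_rc=(float(p.centroid[0]), float(p.centroid[1])),
            area_px=int(p.area),
            signal_count=int(k),
            contrast=float(p.intensity_mean),
        )
        for p, k in zip(comps, counts)
    ]


def remove_faint(spots: list[Spot], faint_contrast_min: float) -> list[Spot]:
    """Drop spots whose contrast falls below the faint-signal floor."""
    return [s for s in spots if s.contrast >= faint_contrast_min]


def detect_all_spots(
    image: RoiImage, config: SpotDetectionConfig | None = None
) -> list[Spot]:
    """Both channels, faint-signal removal applied."""
    config = config or SpotDetectionConfig()
    spots: list[Spot] = []
    for channel in (HER2, CEP17):
        spots.extend(
            remove_faint(detect_spots(image, channel, config), config.faint_contrast_min)
        )
    return spots
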