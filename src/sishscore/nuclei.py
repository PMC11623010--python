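"""Nucleus instance segmentation and qualification.

Scoring is restricted to untruncated, non-overlapping single nuclei that
carry enough CEP17 reference signal.  Segmentation is delegated to a
pluggable backend: the default is a classical pipeline (stain thresholding,
hole filling, distance transform, watershed), and an adapter for a
pretrained star-convex-polygon segmenter is provided for environments where
its runtime is installed.  Qualification then applies three filters in a
fixed order: border-truncation exclusion, >50 %-overlap exclusion, and the
CEP17 >= 2 rule with a single-CEP17 fallback for highly amplified samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max

from .preprocess import RoiImage
from .signals import CEP17, HER2, Spot, remove_background


@dataclass
class NucleusRecord:
    """One segmented nucleus with its per-channel signal counts."""

    label: int
    area_px: int
    centroid_rc: tuple[float, float]
    her2_count: int = 0
    cep17_count: int = 0
    touches_border: bool = False
    max_overlap_fraction: float = 0.0
    qualified: bool = False

    @property
    def differentiation(self) -> int:
        """HER2 minus CEP17 count — the ranking key for nucleus selection."""
        return self.her2_count - self.cep17_count


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract for nucleus instance segmenters.

    ``segment`` maps an ROI to an H×W integer label map (0 = background)
    and must be deterministic for a fixed input.
    """

    name: str

    def segment(self, image: RoiImage) -> np.ndarray: ...


@dataclass
class WatershedBackend:
    """Classical nucleus segmenter.

    Thresholds the bluish/purple nuclear counterstain (probe dots punch
    holes that are filled back in), seeds a watershed at regional maxima of
    the distance transform with a minimum physical separation, and discards
    instances below a minimum nucleus area.
    """

    name: str = "watershed"
    nuclear_hue_range: tuple[float, float] = (0.50, 0.92)
    nuclear_saturation_min: float = 0.12
    min_separation_um: float = 3.0
    min_nucleus_area_um2: float = 20.0
    background_whiteness: float = 0.82

    def segment(self, image: RoiImage) -> np.ndarray:
        px = image.as_float()
        hsv = rgb2hsv(px)
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        foreground = remove_background(image, self.background_whiteness)
        lo, hi = self.nuclear_hue_range
        stain = foreground & (h >= lo) & (h <= hi) & (s >= self.nuclear_saturation_min)
        # probe dots sit inside nuclei; fill them back into the mask
        stain = ndimage.binary_fill_holes(stain)
        stain = morphology.opening(stain, morphology.disk(2))
        if not stain.any():
            return np.zeros(image.shape, dtype=np.int32)

        min_area_px = int(round(image.um2_to_px(self.min_nucleus_area_um2)))
        min_sep_px = max(1, int(round(self.min_separation_um / image.resolution_um_per_px)))
        distance = ndimage.distance_transform_edt(stain)
        peaks = peak_local_max(
            distance, min_distance=min_sep_px, labels=stain, exclude_border=False
        )
        markers = np.zeros(image.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            return np.zeros(image.shape, dtype=np.int32)
        labels = segmentation.watershed(-distance, markers, mask=stain)
        areas = np.bincount(labels.ravel())
        too_small = np.flatnonzero(areas < min_area_px)
        labels[np.isin(labels, too_small)] = 0
        return _relabel_sequential(labels)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    out, _, _ = segmentation.relabel_sequential(labels)
    return out.astype(np.int32)


@dataclass
class StarConvexBackend:
    """Adapter for a pretrained star-convex-polygon nucleus segmenter.

    Requires the ``stardist``/``csbdeep`` runtime; raises a clear error at
    construction when it is not installed.  Kept thin: the qualification
    filters and scoring downstream are backend-agnostic.
    """

    model_name: str = "2D_versatile_he"
    name: str = "stardist"

    def __post_init__(self) -> None:
        try:
            from stardist.models import StarDist2D  # type: ignore
            from csbdeep.utils import normalize as _cn  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional runtime
            raise ImportError(
                "the star-convex backend requires the 'stardist' and 'csbdeep' "
                "packages; install them or use the default watershed backend"
            ) from exc
        self._model = StarDist2D.from_pretrained(self.model_name)
        self._normalize = _cn

    def segment(self, image: RoiImage) -> np.ndarray:  # pragma: no cover
        img = self._normalize(image.as_float(), 1, 99.8)
        labels, _ = self._model.predict_instances(img)
        return labels.astype(np.int32)


def get_backend(name: str, **kwargs) -> SegmentationBackend:
    if name == "watershed":
        return WatershedBackend(**kwargs)
    if name == "stardist":
        return StarConvexBackend(**kwargs)
    raise ValueError(f"unknown segmentation backend {name!r}")


def segment_nuclei(image: RoiImage, backend: SegmentationBackend | None = None) -> np.ndarray:
    """Run the backend and return the instance label map."""
    backend = backend or WatershedBackend()
    try:
        labels = backend.segment(image)
    except Exception as exc:
        raise RuntimeError(f"segmentation backend {backend.name!r} failed: {exc}") from exc
    if labels.shape != image.shape:
        raise RuntimeError(
            f"backend {backend.name!r} returned label map of shape {labels.shape}, "
            f"expected {image.shape}"
        )
    return labels


def assign_spots(labels: np.ndarray, spots: list[Spot]) -> list[NucleusRecord]:
    """Attribute detected signals to nuclei by rounded-centroid membership.

    Each spot contributes its ``signal_count`` to the nucleus whose label
    covers its rounded centroid; spots over background are ignored.  Every
    nucleus in the label map yields one record, with zero counts if empty.
    """
    labels = np.asarray(labels)
    records: dict[int, NucleusRecord] = {}
    for p in measure.regionprops(labels):
        records[p.label] = NucleusRecord(
            label=int(p.label),
            area_px=int(p.area),
            centroid_rc=(float(p.centroid[0]), float(p.centroid[1])),
        )
    h, w = labels.shape
    for spot in spots:
        r = int(round(spot.centroid_rc[0]))
        c = int(round(spot.centroid_rc[1]))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(
                f"spot centroid {spot.centroid_rc} lies outside the {h}×{w} label map"
            )
        lab = int(labels[r, c])
        if lab == 0:
            continue
        rec = records[lab]
        if spot.channel == HER2:
            rec.her2_count += spot.signal_count
        elif spot.channel == CEP17:
            rec.cep17_count += spot.signal_count
        else:
            raise ValueError(f"unknown channel {spot.channel!r}")
    return sorted(records.values(), key=lambda rec: rec.label)


def filter_truncated(
    records: list[NucleusRecord], labels: np.ndarray
) -> list[NucleusRecord]:
    """Exclude nuclei whose mask touches any image edge (truncated nuclei)."""
    labels = np.asarray(labels)
    edge = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    edge_set = {int(v) for v in edge if v != 0}
    kept = []
    for rec in records:
        rec.touches_border = rec.label in edge_set
        if not rec.touches_border:
            kept.append(rec)
    return kept


def filter_overlapping(
    records: list[NucleusRecord],
    instance_masks: dict[int, np.ndarray] | None = None,
    max_overlap: float = 0.5,
) -> list[NucleusRecord]:
    """Exclude nuclei overlapping another by more than ``max_overlap`` of
    their own area.

    Polygon backends may emit overlapping instances; ``instance_masks`` maps
    label -> boolean mask (full-frame or consistently cropped is the
    caller's concern — full-frame here).  Rasterized label maps cannot
    overlap, so with no masks the filter passes everything through.
    Fractions are computed once on the full set; every nucleus whose largest
    fraction exceeds the bound is removed (when both members of a pair
    exceed it, both go — the larger first, without recomputation).
    """
    if instance_masks is None:
        for rec in records:
            rec.max_overlap_fraction = 0.0
        return list(records)
    areas = {lab: int(m.sum()) for lab, m in instance_masks.items()}
    labs = [rec.label for rec in records]
    frac = {lab: 0.0 for lab in labs}
    for i, a in enumerate(labs):
        for b in labs[i + 1 :]:
            inter = int(np.logical_and(instance_masks[a], instance_masks[b]).sum())
            if inter == 0:
                continue
            frac[a] = max(frac[a], inter / areas[a])
            frac[b] = max(frac[b], inter / areas[b])
    kept = []
    for rec in records:
        rec.max_overlap_fraction = frac[rec.label]
        if rec.max_overlap_fraction <= max_overlap:
            kept.append(rec)
    return kept


def filter_by_cep17(
    records: list[NucleusRecord], min_cep17: int = 2, allow_fallback: bool = True
) -> tuple[list[NucleusRecord], bool]:
    """Keep nuclei with at least ``min_cep17`` CEP17 signals.

    In highly amplified samples no nucleus may show two CEP17 signals; the
    fallback then admits single-CEP17 nuclei, mirroring manual practice.
    Returns ``(records, fallback_used)``.
    """
    strict = [r for r in records if r.cep17_count >= min_cep17]
    if strict or not allow_fallback:
        return strict, False
    relaxed = [r for r in records if r.cep17_count >= 1]
    return relaxed, True


def qualify_nuclei(
    records: list[NucleusRecord],
    labels: np.ndarray,
    instance_masks: dict[int, np.ndarray] | None = None,
    max_overlap: float = 0.5,
    min_cep17: int = 2,
    allow_fallback: bool = True,
) -> tuple[list[NucleusRecord], bool]:
    """Full qualification chain: truncation → overlap → CEP17 rule."""
    kept = filter_truncated(records, labels)
    kept = filter_overlapping(kept, instance_masks, max_overlap)
    kept, fallback_used = filter_by_cep17(kept, min_cep17, allow_fallback)
    for rec in kept:
        rec.qualified = True
    return kept, fallback_used
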