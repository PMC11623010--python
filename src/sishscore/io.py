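"""Readers and writers for the pipeline's file formats."""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .nuclei import NucleusRecord
from .preprocess import RoiImage
from .signals import Spot

logger = logging.getLogger("sishscore")


def read_roi(
    path: str | Path,
    resolution_um_per_px: float = 0.13,
    image_id: str | None = None,
) -> RoiImage:
    """Read an 8-bit RGB ROI from PNG or TIFF.

    RGBA inputs have their alpha dropped and grayscale inputs are replicated
    to three channels, with a logged notice either way.
    """
    p = Path(path)
    if image_id is None:
        image_id = p.stem
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = np.asarray(Image.open(p))
    if arr.ndim == 2:
        logger.info("%s: grayscale input replicated to RGB", p.name)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.info("%s: RGBA input, alpha channel dropped", p.name)
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{p}: unsupported image shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{p}: expected 8-bit channels, got dtype {arr.dtype}")
    return RoiImage(arr, resolution_um_per_px, image_id)


def write_roi(roi: RoiImage, path: str | Path) -> None:
    px = roi.pixels
    if not np.issubdtype(px.dtype, np.integer):
        from .preprocess import to_uint8

        px = to_uint8(px)
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, px.astype(np.uint8))
    else:
        Image.fromarray(px.astype(np.uint8)).save(p)


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Label maps travel as 16-bit single-channel TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map exceeds the 16-bit range")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def spots_to_frame(spots: list[Spot], image_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": image_id,
            "channel": [s.channel for s in spots],
            "row": [s.centroid_rc[0] for s in spots],
            "col": [s.centroid_rc[1] for s in spots],
            "area_px": [s.area_px for s in spots],
            "signal_count": [s.signal_count for s in spots],
            "contrast": [s.contrast for s in spots],
        }
    )


def records_to_frame(records: list[NucleusRecord], image_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": image_id,
            "label": [r.label for r in records],
            "area_px": [r.area_px for r in records],
            "her2": [r.her2_count for r in records],
            "cep17": [r.cep17_count for r in records],
            "differentiation": [r.differentiation for r in records],
            "touches_border": [r.touches_border for r in records],
            "max_overlap_fraction": [r.max_overlap_fraction for r in records],
            "qualified": [r.qualified for r in records],
        }
    )


def load_table4_fixture() -> pd.DataFrame:
    """The packaged reference-score table (33 regions: 22 non-amplified,
    11 amplified; two duplicate-ID rows retained as printed)."""
    with resources.files("sishscore.data").joinpath("table4_fixture.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"image_id": str})
    return df
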