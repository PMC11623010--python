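"""End-to-end ROI scoring and batch orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, build_config
from .evaluation import bland_altman_plot, compare_methods
from .nuclei import get_backend, assign_spots, qualify_nuclei, segment_nuclei
from .preprocess import RoiImage, normalize_image
from .io import read_roi
from .scoring import ScoreResult, score_roi
from .signals import detect_all_spots

logger = logging.getLogger("sishscore")


def score_image(
    roi: RoiImage,
    config: PipelineConfig | None = None,
    backend=None,
    return_intermediates: bool = False,
):
    """Run normalize → gamma → detect → segment → qualify → score on one ROI."""
    config = config or build_config()
    if backend is None:
        backend = get_backend(config.nuclei.backend)
    norm = normalize_image(roi, config.normalize, config.gamma)
    spots = detect_all_spots(norm, config.signals)
    labels = segment_nuclei(norm, backend)
    records = assign_spots(labels, spots)
    qualified, fallback_used = qualify_nuclei(
        records,
        labels,
        None,
        max_overlap=config.nuclei.max_overlap,
        min_cep17=config.nuclei.min_cep17,
        allow_fallback=config.nuclei.allow_fallback,
    )
    if not qualified:
        raise ValueError(
            "no qualified nuclei: all candidates failed the truncation/overlap/"
            "CEP17 filters"
        )
    result = score_roi(
        qualified,
        thresholds=config.scoring,
        n_first=config.scoring_n_first,
        n_extra=config.scoring_n_extra,
        fallback_used=fallback_used,
    )
    if return_intermediates:
        return result, {
            "spots": spots,
            "labels": labels,
            "records": records,
            "qualified": qualified,
        }
    return result


def _result_row(image_id: str, result: ScoreResult | None, n_detected: int,
                n_cep17ok: int, config: PipelineConfig, error: str = "") -> dict:
    row = {
        "image_id": image_id,
        "detected_nuclei": n_detected,
        "nuclei_with_2_cep17": n_cep17ok,
        "her2_signals": result.total_her2 if result else 0,
        "cep17_signals": result.total_cep17 if result else 0,
        "ratio": f"{result.ratio:.2f}" if result else "",
        "status": result.status if result else "failed",
        "n_quantified": result.n_quantified if result else 0,
        "fallback_used": result.fallback_used if result else False,
        "extra_set_counted": result.extra_set_counted if result else False,
        "low_confidence": result.low_confidence if result else False,
        "error": error,
        "config_hash": config.config_hash,
        "version": __version__,
    }
    return row


def run_score(
    image_paths: list[str | Path],
    config: PipelineConfig | None = None,
    out_dir: str | Path = ".",
    resolution_um_per_px: float = 0.13,
) -> pd.DataFrame:
    """Score a batch of ROI images; one CSV row per ROI.

    Per-ROI failures are logged and marked in the output, not fatal to the
    batch.  Returns the results frame (also written to ``results.csv``
    alongside one JSON per ROI).
    """
    if not image_paths:
        raise ValueError("no input images given")
    config = config or build_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    backend = get_backend(config.nuclei.backend)
    rows = []
    for path in image_paths:
        roi = read_roi(path, resolution_um_per_px)
        try:
            result, inter = score_image(roi, config, backend, return_intermediates=True)
            n_det = len(inter["records"])
            n_ok = sum(
                1 for r in inter["records"]
                if r.cep17_count >= config.nuclei.min_cep17 and not r.touches_border
            )
            row = _result_row(roi.image_id, result, n_det, n_ok, config)
            payload = {
                **asdict(result),
                "image_id": roi.image_id,
                "config_hash": config.config_hash,
                "version": __version__,
            }
            (out / f"{roi.image_id}.json").write_text(json.dumps(payload, indent=1))
        except Exception as exc:
            logger.error("scoring %s failed: %s", roi.image_id, exc)
            row = _result_row(roi.image_id, None, 0, 0, config, error=str(exc))
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "results.csv", index=False)
    return frame


def run_evaluate(
    results_csv: str | Path,
    reference_csv: str | Path,
    out_dir: str | Path = ".",
    cutoff: float = 2.0,
    sidedness: str = "two_sided",
    make_plot: bool = True,
) -> dict:
    """Compare method ratios against reference scores.

    The method file needs ``image_id`` and a ``ratio`` (or ``method_ratio``)
    column; the reference needs ``image_id``, ``expert_ratio`` and
    ``expert_status``.  Files with identical ``image_id`` sequences are
    paired positionally (reference tables may print legitimate repeated
    region IDs); otherwise rows are joined by ``image_id``, which must then
    be unique, and rows missing on either side are reported and excluded.
    """
    method = pd.read_csv(results_csv, dtype={"image_id": str})
    reference = pd.read_csv(reference_csv, dtype={"image_id": str})
    ratio_col = "method_ratio" if "method_ratio" in method.columns else "ratio"
    if ratio_col not in method.columns:
        raise ValueError("method file lacks a 'ratio'/'method_ratio' column")
    for col in ("expert_ratio", "expert_status"):
        if col not in reference.columns:
            raise ValueError(f"reference file lacks required column {col!r}")

    if list(method["image_id"]) == list(reference["image_id"]):
        merged = pd.DataFrame(
            {
                "image_id": method["image_id"].to_numpy(),
                "method_ratio": method[ratio_col].to_numpy(dtype=float),
                "expert_ratio": reference["expert_ratio"].to_numpy(dtype=float),
                "expert_status": reference["expert_status"].to_numpy(),
            }
        )
    else:
        for name, df in (("method", method), ("reference", reference)):
            if df["image_id"].duplicated().any():
                raise ValueError(
                    f"{name} file repeats image_id values; an unambiguous join "
                    "requires identical row order in both files"
                )
        merged = method[["image_id", ratio_col]].rename(
            columns={ratio_col: "method_ratio"}
        ).merge(
            reference[["image_id", "expert_ratio", "expert_status"]],
            on="image_id",
            how="inner",
        )
        dropped = (len(method) - len(merged)) + (len(reference) - len(merged))
        if dropped:
            logger.warning("%d rows present in only one file were excluded", dropped)
    if merged.empty:
        raise ValueError("no rows joined between method and reference files")

    comp = compare_methods(
        merged["method_ratio"],
        merged["expert_ratio"],
        merged["expert_status"],
        ids=list(merged["image_id"]),
        cutoff=cutoff,
        sidedness=sidedness,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {**asdict(comp), "cutoff": cutoff, "version": __version__}
    (out / "comparison.json").write_text(json.dumps(report, indent=1))
    if make_plot:
        bland_altman_plot(
            merged["method_ratio"], merged["expert_ratio"],
            path=out / "bland_altman.png",
        )
    return report
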