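"""Pipeline configuration: defaults, file loading, validation.

Configs are nested blocks (``normalize``, ``gamma``, ``signals``,
``nuclei``, ``scoring``, ``evaluation``, ``run``) in YAML or TOML; explicit
values are merged over documented defaults, unknown keys are rejected, and
every threshold is validated by the owning dataclass.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import GammaParams, NormalizationParams
from .scoring import StatusThresholds
from .signals import SpotDetectionConfig

logger = logging.getLogger("sishscore")

DEFAULTS: dict = {
    "normalize": {"lower": 1.0, "upper": 99.8, "mode": "value_range"},
    "gamma": {"gamma": 0.5, "gain": 1.0},
    "signals": {
        "her2_value_max": 0.35,
        "her2_saturation_max": 0.45,
        "cep17_hue_halfwidth_deg": 25.0,
        "cep17_saturation_min": 0.30,
        "cep17_value_min": 0.20,
        "cep17_value_max": 0.90,
        "min_spot_diameter_um": 0.4,
        "max_spot_diameter_um": 2.5,
        "faint_contrast_min": 0.15,
        "cluster_split": True,
        "background_whiteness": 0.82,
    },
    "nuclei": {
        "backend": "watershed",
        "min_separation_um": 4.0,
        "min_nucleus_area_um2": 20.0,
        "max_overlap": 0.5,
        "min_cep17": 2,
        "allow_fallback": True,
    },
    "scoring": {
        "binary_cutoff": 2.0,
        "negative_below": 1.8,
        "equivocal_upper": 2.0,
        "copy_positive": 6.0,
        "copy_equivocal_low": 4.0,
        "mode": "binary_ratio",
        "n_first": 20,
        "n_extra": 20,
    },
    "evaluation": {"cutoff": 2.0, "sidedness": "two_sided"},
    "run": {"seed": 0, "log_level": "INFO", "out_dir": "."},
}


@dataclass
class NucleiConfig:
    backend: str = "watershed"
    min_separation_um: float = 4.0
    min_nucleus_area_um2: float = 20.0
    max_overlap: float = 0.5
    min_cep17: int = 2
    allow_fallback: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_overlap <= 1:
            raise ValueError(f"nuclei.max_overlap must lie in [0, 1], got {self.max_overlap}")
        if self.min_cep17 < 1:
            raise ValueError("nuclei.min_cep17 must be >= 1")
        if self.min_separation_um <= 0 or self.min_nucleus_area_um2 <= 0:
            raise ValueError("nuclei sizes must be positive")


@dataclass
class EvaluationConfig:
    cutoff: float = 2.0
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if self.sidedness not in ("two_sided", "greater", "less"):
            raise ValueError(f"evaluation.sidedness invalid: {self.sidedness!r}")
        if self.cutoff <= 0:
            raise ValueError("evaluation.cutoff must be positive")


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."


@dataclass
class PipelineConfig:
    normalize: NormalizationParams
    gamma: GammaParams
    signals: SpotDetectionConfig
    nuclei: NucleiConfig
    scoring: StatusThresholds
    scoring_n_first: int
    scoring_n_extra: int
    evaluation: EvaluationConfig
    run: RunConfig
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        """Short stable hash of the effective configuration, for provenance."""
        canon = json.dumps(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in defaults.items()}
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


def build_config(overrides: dict | None = None) -> PipelineConfig:
    """Construct a validated config from defaults plus ``overrides``."""
    raw = _merge(DEFAULTS, overrides or {})
    norm = NormalizationParams(
        lower_bound=raw["normalize"]["lower"],
        upper_bound=raw["normalize"]["upper"],
        mode=raw["normalize"]["mode"],
    )
    gamma = GammaParams(**raw["gamma"])
    signals = SpotDetectionConfig(**raw["signals"])
    nuclei = NucleiConfig(**raw["nuclei"])
    sc = dict(raw["scoring"])
    n_first = int(sc.pop("n_first"))
    n_extra = int(sc.pop("n_extra"))
    if n_first < 1 or n_extra < 0:
        raise ValueError("scoring.n_first must be >= 1 and scoring.n_extra >= 0")
    thresholds = StatusThresholds(**sc)
    evaluation = EvaluationConfig(**raw["evaluation"])
    run = RunConfig(**raw["run"])
    return PipelineConfig(
        normalize=norm,
        gamma=gamma,
        signals=signals,
        nuclei=nuclei,
        scoring=thresholds,
        scoring_n_first=n_first,
        scoring_n_extra=n_extra,
        evaluation=evaluation,
        run=run,
        raw=raw,
    )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/TOML config file; an absent or empty file gives the
    documented defaults.  The effective config is echoed to the run log."""
    overrides: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        if p.suffix in (".yaml", ".yml"):
            overrides = yaml.safe_load(p.read_text()) or {}
        elif p.suffix == ".toml":
            import tomllib

            overrides = tomllib.loads(p.read_text())
        else:
            raise ValueError(
                f"config extension {p.suffix!r} not recognized (use .yaml/.yml/.toml)"
            )
        if not isinstance(overrides, dict):
            raise ValueError("config file must contain a mapping at top level")
    cfg = build_config(overrides)
    logger.info("effective config (hash %s): %s", cfg.config_hash,
                json.dumps(cfg.raw, sort_keys=True))
    return cfg
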