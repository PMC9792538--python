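"""Pipeline configuration: defaults, key-value file loading, validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables of the extract/train/evaluate pipeline.

    Keys in config files use dotted names (``enhance.p_low`` etc.); flags
    override file values which override these defaults.
    """

    # image_prep
    enhance_p_low: float = 1.0
    enhance_p_high: float = 99.0
    enhance_equalize: bool = False
    enhance_upsample: int = 1
    binarize_method: str = "otsu"
    binarize_threshold: float | None = None
    pixel_spacing: float = 1.0
    # multifractal
    q_min: float = -5.0
    q_max: float = 5.0
    q_step: float = 0.25
    scales: list[int] | None = None  # None -> dyadic default per image
    fit_min_scale: float | None = None
    fit_max_scale: float | None = None
    fit_r2_warn: float = 0.98
    # classifier / evaluation
    scheme: str = "kaggle"
    knn_k: int = 5
    split_n_train: int = 100
    split_n_test: int = 40
    runs: int = 7
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_KEY_MAP = {
    "enhance.p_low": "enhance_p_low",
    "enhance.p_high": "enhance_p_high",
    "enhance.equalize": "enhance_equalize",
    "enhance.upsample": "enhance_upsample",
    "binarize.method": "binarize_method",
    "binarize.threshold": "binarize_threshold",
    "pixel_spacing": "pixel_spacing",
    "q.min": "q_min",
    "q.max": "q_max",
    "q.step": "q_step",
    "scales": "scales",
    "fit.min_scale": "fit_min_scale",
    "fit.max_scale": "fit_max_scale",
    "fit.r2_warn": "fit_r2_warn",
    "scheme": "scheme",
    "knn.k": "knn_k",
    "split.n_train": "split_n_train",
    "split.n_test": "split_n_test",
    "runs": "runs",
    "seed": "seed",
}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML/key-value file, and
    keyword overrides. Unknown keys are rejected."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        for key, val in raw.items():
            if key not in _KEY_MAP:
                raise ValueError(f"{path}: unknown config key {key!r}")
            values[_KEY_MAP[key]] = val
    for key, val in overrides.items():
        if val is None:
            continue
        if key not in PipelineConfig.__dataclass_fields__:
            raise ValueError(f"unknown config field {key!r}")
        values[key] = val
    cfg = PipelineConfig(**values)
    if cfg.binarize_method not in ("otsu", "fixed"):
        raise ValueError(f"binarize.method must be otsu or fixed, got {cfg.binarize_method!r}")
    if cfg.binarize_method == "fixed" and cfg.binarize_threshold is None:
        raise ValueError("binarize.method=fixed requires binarize.threshold")
    return cfg
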