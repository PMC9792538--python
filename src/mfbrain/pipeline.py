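"""End-to-end image -> feature-vector pipeline used by the CLI and examples."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import FeatureVector, extract_features
from .image_prep import EmptyMaskError, GrayImage, apparent_area, binarize, enhance, load_image
from .multifractal import analyze_measure, default_q_grid, measure_from_mask

__all__ = ["extract_features_from_image", "extract_features_from_paths"]

log = logging.getLogger("mfbrain")


def extract_features_from_image(
    img: GrayImage, cfg: PipelineConfig | None = None
) -> FeatureVector:
    """Enhance, binarize, analyze and reduce one loaded slice to 10 features."""
    cfg = cfg or PipelineConfig()
    if img.pixel_spacing == 1.0 and cfg.pixel_spacing != 1.0:
        img = GrayImage(img.pixels, pixel_spacing=cfg.pixel_spacing)
    img = enhance(
        img,
        p_low=cfg.enhance_p_low,
        p_high=cfg.enhance_p_high,
        equalize=cfg.enhance_equalize,
        upsample=cfg.enhance_upsample,
    )
    mask = binarize(img, method=cfg.binarize_method, threshold=cfg.binarize_threshold)
    if mask.is_empty:
        raise EmptyMaskError("binarization produced an empty mask")
    log.debug("binarize threshold=%.4g foreground=%d", mask.threshold, mask.foreground_count)
    q_grid = default_q_grid(cfg.q_min, cfg.q_max, cfg.q_step)
    fit_range = None
    if cfg.fit_min_scale is not None or cfg.fit_max_scale is not None:
        fit_range = (cfg.fit_min_scale or 0, cfg.fit_max_scale or np.inf)
    gen, sing = analyze_measure(
        measure_from_mask(mask),
        q_grid=q_grid,
        scales=cfg.scales,
        fit_range=fit_range,
        r2_warn=cfg.fit_r2_warn,
    )
    log.debug("fit R2 range [%.4f, %.4f]", gen.r_squared.min(), gen.r_squared.max())
    return extract_features(gen, sing, apparent_area(mask))


def extract_features_from_paths(
    paths: list[str | Path],
    cfg: PipelineConfig | None = None,
    label: str | None = None,
) -> pd.DataFrame:
    """Feature table for a list of image files; unreadable images are skipped
    with a logged error. Raises if every image fails."""
    cfg = cfg or PipelineConfig()
    records = []
    for path in paths:
        path = Path(path)
        try:
            fv = extract_features_from_image(load_image(path), cfg)
        except (OSError, ValueError, EmptyMaskError) as exc:
            log.error("skipping %s: %s", path, exc)
            continue
        rec = {"image_id": path.stem, **fv.__dict__}
        if label is not None:
            rec["stage"] = label
        records.append(rec)
    if not records:
        raise RuntimeError("no image could be processed")
    return pd.DataFrame.from_records(records)
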