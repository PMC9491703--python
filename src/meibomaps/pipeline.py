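"""End-to-end orchestration: image + mask + config -> maps, scores, features.

Deterministic given (inputs, config): re-running writes byte-identical
JSON and CSV.  Every stage failure is re-raised as a ``PipelineError``
naming the stage and the offending file.
"""

from __future__ import annotations

from pathlib import Path

from . import __version__
from .config import AnalysisConfig
from .estimators import DensityProductClassifier  # noqa: F401  (re-export convenience)
from .features import extract_features
from .io import (
    read_image,
    read_mask,
    write_features,
    write_json,
    write_maps,
    write_overlays,
)
from .maps import build_maps, meibo_scores
from .preprocess import binarize, enhance_contrast

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, path, message: str):
        self.stage = stage
        self.path = str(path)
        super().__init__(f"[{stage}] {path}: {message}")


def run_pipeline(image_path, mask_path, out_dir,
                 config: AnalysisConfig | None = None,
                 image_id: str | None = None,
                 write_overlay_pngs: bool = True) -> dict:
    """Run preprocess -> maps -> scores -> features and write everything.

    Returns a summary dict (scores, feature values, output paths).  The
    mask is mandatory: analyzing a full frame as if it were an eyelid
    silently corrupts the scores, so there is no fallback.
    """
    cfg = config or AnalysisConfig()
    out = Path(out_dir)
    image_path, mask_path = Path(image_path), Path(mask_path)
    if not image_path.exists():
        raise PipelineError("load-image", image_path, "file not found")
    if not mask_path.exists():
        raise PipelineError("load-mask", mask_path, "file not found")

    try:
        img = read_image(image_path)
    except Exception as e:  # malformed input
        raise PipelineError("load-image", image_path, str(e)) from e
    try:
        mask = read_mask(mask_path, shape=img.pixels.shape)
    except Exception as e:
        raise PipelineError("load-mask", mask_path, str(e)) from e
    if mask.pixels.shape != img.pixels.shape:
        raise PipelineError("load-mask", mask_path,
                            f"mask shape {mask.pixels.shape} != image {img.pixels.shape}")

    if not img.is_binary:
        try:
            img = enhance_contrast(img, clip_limit=cfg.preprocess.clip_limit,
                                   tile=cfg.preprocess.tile)
            img = binarize(img, method=cfg.preprocess.method,
                           block_size=cfg.preprocess.block_size)
        except Exception as e:
            raise PipelineError("preprocess", image_path, str(e)) from e

    try:
        maps = build_maps(img, mask, cfg.window, n_q=cfg.polar.n_q,
                          n_theta=cfg.polar.n_theta,
                          dc_exclusion_bins=cfg.fit.dc_exclusion_bins,
                          max_residual=cfg.fit.max_residual,
                          neighborhood=cfg.neighborhood)
    except Exception as e:
        raise PipelineError("maps", image_path, str(e)) from e

    scores = meibo_scores(maps, cfg.thresholds.g_q, cfg.thresholds.c_theta)
    iid = image_id or image_path.stem
    fv = extract_features(maps, n_bins=cfg.n_bins, image_id=iid)

    provenance = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "image": str(image_path),
        "mask": str(mask_path),
    }
    write_maps(out / "maps", maps, extra={"provenance": provenance})
    write_json(out / "scores.json", {
        "a_q_percent": scores.a_q,
        "a_theta_percent": scores.a_theta,
        "g_q_threshold": scores.g_q_threshold,
        "c_theta_threshold": scores.c_theta_threshold,
        "provenance": provenance,
    })
    write_features(out / "features.csv", [fv])
    if write_overlay_pngs:
        write_overlays(out / "overlays", maps, img)

    return {"scores": scores, "features": fv, "maps": maps, "out_dir": str(out)}
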