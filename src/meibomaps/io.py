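"""Readers and writers for the on-disk formats gluing the stages together.

Images come in as 8/16-bit grayscale PNG/TIFF; morphometric maps go out
as float32 single-channel TIFFs with a JSON sidecar carrying units,
window parameters, thresholds and scores (TIFF tags are unreliable for
units); features travel as CSV with the 30 named columns; classifier
models as JSON (loadings, scalers, density knots).  Colormapped PNG
overlays blend each map over the source image for visual inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .features import FEATURE_NAMES, FeatureVector
from .maps import MorphoMaps
from .preprocess import EyelidMask, GlandImage

__all__ = [
    "read_image",
    "read_mask",
    "write_image",
    "write_maps",
    "read_maps",
    "features_to_frame",
    "write_features",
    "read_features",
    "write_json",
    "read_json",
    "write_overlays",
]

MAP_UNITS = {
    "q0": "cycles/pixel",
    "sigma_q": "unitless (normalized broadening)",
    "g_q": "(cycles/pixel) per map pixel",
    "theta0": "degrees in [0, 180)",
    "sigma_theta": "unitless (normalized broadening)",
    "c_theta": "unitless in [0, 1]",
}


def read_image(path) -> GlandImage:
    px = np.asarray(iio.imread(path))
    if px.ndim == 3:  # collapse RGB(A) to luminance
        px = px[..., :3].mean(axis=2)
    vals = np.unique(px)
    binary = vals.size <= 2
    if binary:
        px = (px > px.min()).astype(np.uint8)
    return GlandImage(pixels=px, is_binary=binary, meta={"source": str(path)})


def read_mask(path, shape: tuple[int, int] | None = None) -> EyelidMask:
    """A mask is either a raster (any nonzero pixel = inside) or a JSON
    polygon ``[[row, col], ...]`` (requires ``shape``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        from .preprocess import rasterize_mask
        if shape is None:
            raise ValueError("polygon masks need the target image shape")
        return rasterize_mask(json.loads(path.read_text()), shape)
    px = np.asarray(iio.imread(path))
    if px.ndim == 3:
        px = px[..., :3].max(axis=2)
    return EyelidMask(pixels=px > 0, source="raster")


def write_image(path, img: GlandImage | np.ndarray) -> None:
    px = np.asarray(getattr(img, "pixels", img))
    if px.dtype != np.uint8:
        vmax = px.max()
        px = (px * (255.0 / vmax) if vmax > 0 else px).astype(np.uint8)
    elif getattr(img, "is_binary", False) or px.max() <= 1:
        px = px * np.uint8(255)
    iio.imwrite(path, px)


def write_maps(out_dir, maps: MorphoMaps, extra: dict | None = None) -> Path:
    """Six float32 TIFFs + validity mask + JSON sidecar; returns sidecar path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, raster in maps.as_dict().items():
        tifffile.imwrite(out / f"{name}.tif", raster.astype(np.float32))
    tifffile.imwrite(out / "valid_mask.tif", maps.valid_mask.astype(np.uint8))
    sidecar = {
        "units": MAP_UNITS,
        "grid_stride": int(maps.grid_stride),
        "window": {"sigma_r": maps.window_spec.sigma_r,
                   "support_radius": maps.window_spec.support_radius,
                   "stride": maps.window_spec.stride},
        "map_shape": list(maps.valid_mask.shape),
        "n_valid": int(maps.valid_mask.sum()),
    }
    if extra:
        sidecar.update(extra)
    write_json(out / "maps.json", sidecar)
    return out / "maps.json"


def read_maps(map_dir) -> tuple[dict[str, np.ndarray], np.ndarray, dict]:
    """Returns ({map name: raster}, valid_mask, sidecar dict)."""
    d = Path(map_dir)
    rasters = {name: tifffile.imread(d / f"{name}.tif") for name in MAP_UNITS}
    valid = tifffile.imread(d / "valid_mask.tif").astype(bool)
    sidecar = read_json(d / "maps.json")
    return rasters, valid, sidecar


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    rows = []
    for v in vectors:
        row = {"image_id": v.image_id, "label": v.label if v.label is not None else ""}
        row.update(v.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["image_id", "label", *FEATURE_NAMES])


def write_features(path, vectors: list[FeatureVector]) -> None:
    features_to_frame(vectors).to_csv(path, index=False)


def read_features(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (X, labels, image_ids); labels are '' where absent."""
    df = pd.read_csv(path, keep_default_na=False)
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].astype(str).to_numpy()
    ids = df["image_id"].astype(str).tolist()
    return X, y, ids


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_overlays(out_dir, maps: MorphoMaps, image, alpha: float = 0.55) -> None:
    """Nearest-neighbor upsampled, colormapped map blended over the image."""
    import matplotlib.cm as cm

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    px = np.asarray(getattr(image, "pixels", image), dtype=float)
    span = px.max() - px.min()
    base = (px - px.min()) / span if span > 0 else np.zeros_like(px)
    h, w = px.shape
    stride = maps.grid_stride
    for name, raster in maps.as_dict().items():
        vals = raster.copy()
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        lo, hi = vals[finite].min(), vals[finite].max()
        normed = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
        normed[~finite] = 0.0
        up = np.repeat(np.repeat(normed, stride, 0), stride, 1)[:h, :w]
        pad_r, pad_c = h - up.shape[0], w - up.shape[1]
        if pad_r or pad_c:
            up = np.pad(up, ((0, pad_r), (0, pad_c)), mode="edge")
        rgba = cm.viridis(up)[..., :3]
        blend = (1 - alpha) * base[..., None] + alpha * rgba
        iio.imwrite(out / f"overlay_{name}.png", (blend * 255).astype(np.uint8))
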