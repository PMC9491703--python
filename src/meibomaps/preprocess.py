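"""From a raw grayscale meibogram to a binarized, mask-limited input.

Clinically acquired meibograms are low-contrast infrared images; the
analysis operates on a binary silhouette of the glands restricted to a
manually (or synthetically) delineated eyelid region.  The operators
here standardize that preparation: contrast-limited adaptive histogram
equalization (CLAHE), global Otsu or local adaptive thresholding, and
polygon-to-raster conversion of the eyelid outline.

Conventions: 0-based (row, col) indexing with pixel centers on integer
coordinates; binary images take values {0, 1} with glands mapped to 1
(glands are bright in IR meibography); the mask never alters pixel
values, it only restricts where analysis windows are placed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure, filters

__all__ = ["GlandImage", "EyelidMask", "enhance_contrast", "binarize", "rasterize_mask"]


@dataclass
class GlandImage:
    """A 2D intensity raster with binarization state and provenance."""

    pixels: np.ndarray
    is_binary: bool = False
    pixel_size: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("GlandImage expects a 2D raster")
        if self.is_binary:
            vals = np.unique(self.pixels)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("binary image must contain only {0, 1}")


@dataclass
class EyelidMask:
    pixels: np.ndarray
    source: str = "raster"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if not self.pixels.any():
            raise ValueError("eyelid mask is empty")


def _looks_binary(px: np.ndarray) -> bool:
    vals = np.unique(px)
    return vals.size == 2 and np.isin(vals, (0, 1)).all()


def enhance_contrast(img: GlandImage, clip_limit: float = 0.01, tile: int = 64) -> GlandImage:
    """CLAHE contrast enhancement; output intensity span is [0, max(input)].

    Rejects binary {0, 1} input (nothing left to enhance); a constant
    image passes through unchanged.
    """
    if img.is_binary or _looks_binary(img.pixels):
        raise ValueError("enhance_contrast expects a grayscale (non-binary) image")
    px = np.asarray(img.pixels, dtype=np.float64)
    if np.ptp(px) == 0:  # constant image: nothing to enhance
        return GlandImage(pixels=px.copy(), is_binary=False, pixel_size=img.pixel_size,
                          meta=dict(img.meta))
    vmax = float(px.max())
    norm = (px - px.min()) / (vmax - px.min())
    out = exposure.equalize_adapthist(norm, kernel_size=int(tile), clip_limit=float(clip_limit))
    return GlandImage(pixels=out * vmax, is_binary=False, pixel_size=img.pixel_size,
                      meta={**img.meta, "contrast": "clahe"})


def binarize(img: GlandImage, method: str = "otsu", block_size: int = 51) -> GlandImage:
    """Threshold a grayscale image into a {0, 1} gland silhouette.

    ``otsu`` picks the global threshold minimizing intra-class variance;
    ``adaptive`` uses a local Gaussian-weighted mean over ``block_size``
    pixels (odd).  Applying ``binarize`` to an already binary-valued
    image is the identity up to threshold placement.
    """
    px = np.asarray(img.pixels, dtype=np.float64)
    if np.ptp(px) == 0:
        raise ValueError("degenerate histogram: constant image cannot be thresholded")
    if method == "otsu":
        thr = filters.threshold_otsu(px)
        binary = px > thr
    elif method == "adaptive":
        if block_size % 2 == 0:
            raise ValueError("block_size must be odd")
        thr = filters.threshold_local(px, block_size=block_size, method="gaussian")
        binary = px > thr
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return GlandImage(pixels=binary.astype(np.uint8), is_binary=True,
                      pixel_size=img.pixel_size, meta={**img.meta, "binarize": method})


def _segments(vertices: np.ndarray) -> np.ndarray:
    return np.stack([vertices, np.roll(vertices, -1, axis=0)], axis=1)


def _self_intersects(vertices: np.ndarray) -> bool:
    segs = _segments(vertices)
    n = len(segs)

    def ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # first and last share a vertex
            a, b = segs[i]
            c, d = segs[j]
            if (ccw(a, c, d) * ccw(b, c, d) < 0) and (ccw(c, a, b) * ccw(d, a, b) < 0):
                return True
    return False


def rasterize_mask(polygon, shape: tuple[int, int]) -> EyelidMask:
    """Even-odd fill of a (row, col) polygon at pixel centers.

    Pixel centers exactly on a polygon edge are counted inside, so an
    axis-aligned rectangle with corners (0,0)-(9,9) covers 100 pixels.
    Self-intersecting outlines trigger a warning but are still filled by
    the even-odd rule.  A polygon wholly outside the raster raises.
    """
    verts = np.asarray(polygon, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    if _self_intersects(verts):
        warnings.warn("self-intersecting polygon; even-odd fill applied", stacklevel=2)

    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    py = rr.ravel().astype(np.float64)
    px = cc.ravel().astype(np.float64)
    inside = np.zeros(py.shape, dtype=bool)
    on_edge = np.zeros(py.shape, dtype=bool)
    eps = 1e-9
    for (r1, c1), (r2, c2) in _segments(verts):
        crosses = (r1 > py) != (r2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (c2 - c1) * (py - r1) / (r2 - r1) + c1
        inside ^= crosses & (px < xint)
        # distance from pixel center to the segment
        dr, dc = r2 - r1, c2 - c1
        L2 = dr * dr + dc * dc
        if L2 == 0:
            d2 = (py - r1) ** 2 + (px - c1) ** 2
        else:
            t = np.clip(((py - r1) * dr + (px - c1) * dc) / L2, 0.0, 1.0)
            d2 = (py - (r1 + t * dr)) ** 2 + (px - (c1 + t * dc)) ** 2
        on_edge |= d2 <= eps
    m = (inside | on_edge).reshape(h, w)
    if not m.any():
        raise ValueError("polygon covers no pixel of the raster (mask outside image?)")
    return EyelidMask(pixels=m, source="polygon")
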