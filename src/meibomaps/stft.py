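"""Gaussian-windowed local power spectra and their polar probability form.

The elementary operation of the whole analysis: place a Gaussian window at
a grid position on the (binarized) gland image, Fourier-transform the
windowed patch, and re-express the power spectral density (PSD) over
spatial frequency ``q`` (cycles/pixel) and axial stripe orientation
``theta`` (degrees in ``[0, 180)``).  Normalized this way the polar PSD is
read as a probability map ``p(q, theta)`` of finding gland structure of a
given frequency and orientation inside the window; its two marginals
``p(q)`` and ``p(theta)`` are what the fitting stage consumes.

Coordinate conventions (used throughout the package):

* images are indexed ``(row, col)``, 0-based, pixel centers on integers;
* ``theta`` is the orientation of the stripe crests, measured from the
  +col axis toward the +row axis.  A vertical stripe pattern (period along
  the column direction) has ``theta = 90``; the wave vector of a pattern
  with stripe orientation ``theta`` points at ``theta - 90``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "WindowSpec",
    "CartesianPSD",
    "PolarPSD",
    "Marginals",
    "window_positions",
    "windowed_psd",
    "psd_to_polar",
    "marginals",
]


@dataclass(frozen=True)
class WindowSpec:
    """Gaussian analysis window and the sampling grid it is placed on.

    Parameters
    ----------
    sigma_r : float
        Standard deviation of the Gaussian window in pixels.  The window
        must span at least ~1.5 periods of the stripe pattern for the
        spectral peak to separate from DC; for meibography stripes of
        period ~10 px the default of 8 px satisfies that while keeping
        the orientation field resolvable on the analysis grid.
    support_radius : int
        Half-size of the extracted patch; the patch side is
        ``2 * support_radius + 1``.  Must be at least ``3 * sigma_r`` so
        the truncated Gaussian carries essentially all of its mass.
    stride : int
        Grid step in pixels between window positions (default 10: one
        window every 10th pixel).
    """

    sigma_r: float = 8.0
    support_radius: int = 24
    stride: int = 10

    def __post_init__(self) -> None:
        if self.sigma_r <= 0:
            raise ValueError("sigma_r must be positive")
        if self.support_radius < 3 * self.sigma_r:
            raise ValueError("support_radius must be >= 3 * sigma_r")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def patch_size(self) -> int:
        return 2 * int(self.support_radius) + 1


@dataclass
class CartesianPSD:
    """Squared-modulus 2D DFT of a windowed patch, DC at ``dc_index``."""

    values: np.ndarray
    dc_index: tuple[int, int]
    freq_step: float

    @property
    def is_degenerate(self) -> bool:
        """True when the patch carried no AC energy (e.g. constant input)."""
        return float(self.values.max(initial=0.0)) <= 1e-30


@dataclass
class PolarPSD:
    """Normalized p(q, theta): rows index q bins, columns theta bins."""

    values: np.ndarray
    q_axis: np.ndarray
    theta_axis: np.ndarray


@dataclass
class Marginals:
    p_q: np.ndarray
    p_theta: np.ndarray


def _as_pixels(img) -> np.ndarray:
    px = getattr(img, "pixels", img)
    return np.asarray(px, dtype=np.float64)


def _as_mask(mask) -> np.ndarray:
    px = getattr(mask, "pixels", mask)
    return np.asarray(px).astype(bool)


def window_positions(mask, spec: WindowSpec) -> np.ndarray:
    """All stride-lattice points whose pixel center lies inside the mask.

    Returns an ``(n, 2)`` integer array of (row, col) positions in
    row-major order.  Lattice points have both coordinates divisible by
    ``spec.stride``.
    """
    m = _as_mask(mask)
    if not m.any():
        raise ValueError("mask is empty")
    rows = np.arange(0, m.shape[0], spec.stride)
    cols = np.arange(0, m.shape[1], spec.stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = m[rr, cc]
    if not keep.any():
        raise ValueError("mask too small: no grid point falls inside it")
    return np.stack([rr[keep], cc[keep]], axis=1)


@lru_cache(maxsize=32)
def _gaussian_window(patch_size: int, sigma_r: float) -> np.ndarray:
    r = (patch_size - 1) // 2
    x = np.arange(patch_size, dtype=np.float64) - r
    g1 = np.exp(-0.5 * (x / sigma_r) ** 2)
    return np.outer(g1, g1)


def windowed_psd(img, center: tuple[int, int], spec: WindowSpec) -> CartesianPSD:
    """PSD of the mean-subtracted, Gaussian-windowed patch at ``center``.

    The patch (side ``2*support_radius + 1``) is zero-padded where it
    extends past the image border, its mean removed to suppress the DC
    term, multiplied by the Gaussian window, and the squared modulus of
    its 2D DFT returned with the zero-frequency bin shifted to the patch
    center index.
    """
    px = _as_pixels(img)
    r0, c0 = int(center[0]), int(center[1])
    if not (0 <= r0 < px.shape[0] and 0 <= c0 < px.shape[1]):
        raise ValueError(f"window center {center!r} outside image {px.shape}")
    ps = spec.patch_size
    rad = spec.support_radius
    patch = np.zeros((ps, ps), dtype=np.float64)
    rlo, rhi = max(0, r0 - rad), min(px.shape[0], r0 + rad + 1)
    clo, chi = max(0, c0 - rad), min(px.shape[1], c0 + rad + 1)
    patch[rlo - (r0 - rad):rhi - (r0 - rad), clo - (c0 - rad):chi - (c0 - rad)] = px[rlo:rhi, clo:chi]
    patch -= patch.mean()
    wp = patch * _gaussian_window(ps, float(spec.sigma_r))
    psd = np.abs(np.fft.fftshift(np.fft.fft2(wp))) ** 2
    return CartesianPSD(values=psd, dc_index=(rad, rad), freq_step=1.0 / ps)


@lru_cache(maxsize=32)
def _polar_coords(n: int, n_q: int, n_theta: int):
    """Bilinear sampling coordinates from an n-by-n centered PSD onto a
    uniform (q, theta) lattice.  q runs from one cartesian frequency step
    above DC to Nyquist; theta bin centers cover [0, 180)."""
    dc = (n - 1) // 2
    q_axis = np.linspace(1.0 / n, 0.5, n_q)
    theta_axis = (np.arange(n_theta) + 0.5) * (180.0 / n_theta)
    alpha = np.deg2rad(theta_axis - 90.0)  # wave-vector angle
    qx = np.outer(q_axis, np.cos(alpha))
    qy = np.outer(q_axis, np.sin(alpha))
    rows = dc + qy * n
    cols = dc + qx * n
    return q_axis, theta_axis, np.stack([rows, cols])


def psd_to_polar(psd: CartesianPSD, n_q: int = 64, n_theta: int = 90) -> PolarPSD:
    """Resample a centrosymmetric cartesian PSD onto a uniform (q, theta)
    grid and normalize it to unit total mass.

    Only the half-plane ``theta in [0, 180)`` is sampled (the other half
    is its mirror image by centrosymmetry of the PSD of a real image).
    The DC bin is excluded by construction: the q axis starts one
    cartesian frequency step above zero.
    """
    if psd.is_degenerate:
        raise ValueError("no spectral energy: degenerate (constant) patch")
    n = psd.values.shape[0]
    q_axis, theta_axis, coords = _polar_coords(n, int(n_q), int(n_theta))
    vals = map_coordinates(psd.values, coords, order=1, mode="constant", cval=0.0)
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("no spectral energy above DC")
    return PolarPSD(values=vals / total, q_axis=q_axis.copy(), theta_axis=theta_axis.copy())


def marginals(polar: PolarPSD) -> Marginals:
    """Project p(q, theta) onto each axis and renormalize to unit sum."""
    p_q = polar.values.sum(axis=1)
    p_t = polar.values.sum(axis=0)
    return Marginals(p_q=p_q / p_q.sum(), p_theta=p_t / p_t.sum())
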