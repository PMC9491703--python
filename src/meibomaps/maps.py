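"""Assembly of the six morphometric maps and the area meibo-scores.

For every window-grid position inside the eyelid mask the local spectral
fits provide four directly-extracted parameters: peak frequency ``q0``,
window-corrected frequency spread ``delta sigma_q``, peak orientation
``theta0`` and orientation spread ``delta sigma_theta``.  Two further
maps are derived from the first group: the frequency-gradient magnitude
``G_q`` (rate of change of q0 across the map) and the angular
incoherence ``C_theta`` (local spatial variability of the mean stripe
orientation).  Thresholding G_q and C_theta and counting the exceeding
fraction of the eyelid yields the two area scores A_q and A_theta.

Unit note: ``G_q`` is expressed in (cycles/pixel) change per *map pixel*
(i.e. per grid step of ``stride`` image pixels).  The maps are the
native rasters of the analysis, so their gradient is naturally taken per
map sample; the default threshold 0.007 assumes this convention and a
stride of 10 and is exposed in configuration because it is not
transferable to other unit choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import (
    DEFAULT_MAX_RESIDUAL,
    fit_q_marginal,
    fit_theta_marginal,
    ideal_widths,
    normalized_broadening,
)
from .stft import WindowSpec, marginals, psd_to_polar, windowed_psd, _as_mask, _as_pixels

__all__ = [
    "MorphoMaps",
    "MeiboScores",
    "build_maps",
    "frequency_gradient",
    "angular_incoherence",
    "area_fraction",
    "meibo_scores",
    "DEFAULT_GQ_THRESHOLD",
    "DEFAULT_CTHETA_THRESHOLD",
]

DEFAULT_GQ_THRESHOLD = 0.007
DEFAULT_CTHETA_THRESHOLD = 0.1

_MAP_NAMES = ("q0", "sigma_q", "g_q", "theta0", "sigma_theta", "c_theta")


@dataclass
class MorphoMaps:
    """Six co-registered rasters on the window grid plus a validity mask.

    Invalid grid points (outside the mask, or where a fit failed) hold
    NaN in every map and False in ``valid_mask``.
    """

    q0_map: np.ndarray
    sigma_q_map: np.ndarray
    g_q_map: np.ndarray
    theta0_map: np.ndarray
    sigma_theta_map: np.ndarray
    c_theta_map: np.ndarray
    valid_mask: np.ndarray
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    grid_stride: int
    window_spec: WindowSpec

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "q0": self.q0_map,
            "sigma_q": self.sigma_q_map,
            "g_q": self.g_q_map,
            "theta0": self.theta0_map,
            "sigma_theta": self.sigma_theta_map,
            "c_theta": self.c_theta_map,
        }


@dataclass
class MeiboScores:
    a_q: float
    a_theta: float
    g_q_threshold: float
    c_theta_threshold: float


def build_maps(
    img,
    mask,
    spec: WindowSpec | None = None,
    *,
    n_q: int = 64,
    n_theta: int = 90,
    dc_exclusion_bins: int = 2,
    max_residual: float = DEFAULT_MAX_RESIDUAL,
    neighborhood: int = 3,
) -> MorphoMaps:
    """Run the windowed spectral analysis on the full grid and assemble
    all six morphometric maps.

    Raises ``ValueError`` when fewer than 4 grid points yield valid fits
    (insufficient coverage for the derived maps).
    """
    spec = spec or WindowSpec()
    px = _as_pixels(img)
    m = _as_mask(mask)
    if px.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    rows = np.arange(0, px.shape[0], spec.stride)
    cols = np.arange(0, px.shape[1], spec.stride)
    shape = (len(rows), len(cols))
    q0m = np.full(shape, np.nan)
    sqm = np.full(shape, np.nan)
    t0m = np.full(shape, np.nan)
    stm = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            if not m[r, c]:
                continue
            psd = windowed_psd(px, (r, c), spec)
            if psd.is_degenerate:
                continue
            polar = psd_to_polar(psd, n_q=n_q, n_theta=n_theta)
            marg = marginals(polar)
            fq = fit_q_marginal(marg.p_q, polar.q_axis,
                                dc_exclusion_bins=dc_exclusion_bins,
                                max_residual=max_residual)
            ft = fit_theta_marginal(marg.p_theta, polar.theta_axis,
                                    max_residual=max_residual)
            if not (fq.fit_ok and ft.fit_ok):
                continue
            try:
                sq_id, st_id = ideal_widths(fq.q0, spec, n_q=n_q, n_theta=n_theta,
                                            dc_exclusion_bins=dc_exclusion_bins)
            except ValueError:
                continue
            q0m[i, j] = fq.q0
            t0m[i, j] = ft.theta0
            sqm[i, j] = normalized_broadening(fq.sigma_fit, sq_id)
            stm[i, j] = normalized_broadening(ft.sigma_fit, st_id)
            valid[i, j] = True

    if valid.sum() < 4:
        raise ValueError("insufficient coverage: fewer than 4 valid grid points")

    gqm = frequency_gradient(q0m, valid)
    ctm = angular_incoherence(t0m, valid, neighborhood=neighborhood)
    return MorphoMaps(
        q0_map=q0m, sigma_q_map=sqm, g_q_map=gqm, theta0_map=t0m,
        sigma_theta_map=stm, c_theta_map=ctm, valid_mask=valid,
        grid_rows=rows, grid_cols=cols, grid_stride=int(spec.stride),
        window_spec=spec,
    )


def _masked_derivative(a: np.ndarray, valid: np.ndarray, axis: int) -> np.ndarray:
    """Central differences where both neighbors are valid, one-sided at
    validity borders, 0 where no valid neighbor exists along the axis.
    Units: per map pixel."""
    fwd = np.roll(a, -1, axis=axis)
    bwd = np.roll(a, 1, axis=axis)
    vf = np.roll(valid, -1, axis=axis)
    vb = np.roll(valid, 1, axis=axis)
    # roll wraps around; kill the wrapped edge entries
    edge_hi = [slice(None)] * a.ndim
    edge_hi[axis] = slice(-1, None)
    edge_lo = [slice(None)] * a.ndim
    edge_lo[axis] = slice(0, 1)
    vf[tuple(edge_hi)] = False
    vb[tuple(edge_lo)] = False

    d = np.zeros_like(a)
    both = vf & vb
    d[both] = (fwd[both] - bwd[both]) / 2.0
    only_f = vf & ~vb
    d[only_f] = fwd[only_f] - a[only_f]
    only_b = vb & ~vf
    d[only_b] = a[only_b] - bwd[only_b]
    return d


def frequency_gradient(q0_map: np.ndarray, valid_mask: np.ndarray | None = None) -> np.ndarray:
    """Magnitude of the spatial gradient of the q0 map.

    Units are (cycles/pixel) per map pixel (one map pixel = one grid
    stride of the analysis).  Invalid grid points are NaN in the output
    and excluded as difference partners.
    """
    a = np.asarray(q0_map, dtype=float)
    valid = np.isfinite(a) if valid_mask is None else np.asarray(valid_mask, bool)
    a0 = np.where(valid, a, 0.0)
    dr = _masked_derivative(a0, valid, axis=0)
    dc = _masked_derivative(a0, valid, axis=1)
    g = np.hypot(dr, dc)
    g[~valid] = np.nan
    return g


def angular_incoherence(
    theta0_map: np.ndarray,
    valid_mask: np.ndarray | None = None,
    neighborhood: int = 3,
) -> np.ndarray:
    """1 - Rbar of the doubled orientation angles over a k-by-k
    neighborhood of valid grid points (k = ``neighborhood``, default 3).

    Rbar is the mean resultant length of the unit vectors
    ``exp(2i * theta0)``; doubling makes the statistic axial, so angles
    of 179 and 1 degree count as nearly identical orientations.  Range
    [0, 1]; 0 means a perfectly coherent orientation field.
    """
    t = np.asarray(theta0_map, dtype=float)
    valid = np.isfinite(t) if valid_mask is None else np.asarray(valid_mask, bool)
    k = int(neighborhood)
    if k < 1 or k % 2 == 0:
        raise ValueError("neighborhood must be a positive odd integer")
    h = k // 2
    z = np.exp(2j * np.deg2rad(np.where(valid, t, 0.0)))
    out = np.full(t.shape, np.nan)
    nr, nc = t.shape
    for i in range(nr):
        for j in range(nc):
            if not valid[i, j]:
                continue
            sl = (slice(max(0, i - h), min(nr, i + h + 1)),
                  slice(max(0, j - h), min(nc, j + h + 1)))
            v = valid[sl]
            out[i, j] = 1.0 - abs(z[sl][v].mean())
    return np.clip(out, 0.0, 1.0, out=out)


def area_fraction(map_values: np.ndarray, threshold: float,
                  valid_mask: np.ndarray | None = None) -> float:
    """Percentage of valid map pixels strictly exceeding ``threshold``."""
    a = np.asarray(map_values, dtype=float)
    valid = np.isfinite(a) if valid_mask is None else np.asarray(valid_mask, bool) & np.isfinite(a)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("empty valid mask")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return 100.0 * float((a[valid] > threshold).sum()) / n


def meibo_scores(
    maps: MorphoMaps,
    g_q_threshold: float = DEFAULT_GQ_THRESHOLD,
    c_theta_threshold: float = DEFAULT_CTHETA_THRESHOLD,
) -> MeiboScores:
    """Area scores: A_q from the G_q map, A_theta from the C_theta map."""
    return MeiboScores(
        a_q=area_fraction(maps.g_q_map, g_q_threshold, maps.valid_mask),
        a_theta=area_fraction(maps.c_theta_map, c_theta_threshold, maps.valid_mask),
        g_q_threshold=float(g_q_threshold),
        c_theta_threshold=float(c_theta_threshold),
    )
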