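"""Peak fits of the spectral marginals and window-broadening correction.

``p(q)`` is fitted with a Gaussian and ``p(theta)`` with a von Mises
density on the doubled angle (orientation is axial: period 180 deg, so
``2*theta`` lives on a full circle and a unimodal circular law applies
without spurious bimodality at the 0/180 seam).

A finite Gaussian window broadens both marginals even for a perfectly
regular stripe pattern.  The *ideal* widths ``sigma_id`` for a constant
pattern of the same frequency are obtained by running the identical
pipeline on a synthetic perfect pattern, and the normalized excess

    delta_sigma = (sigma_fit - sigma_id) / sigma_id   (clipped at 0)

is the window-corrected measure of true local frequency / orientation
spread.  Computing sigma_id with the pipeline itself (rather than a
closed form) makes delta_sigma exactly zero-calibrated by construction.

All "sigma" quantities are standard deviations; the field literature
sometimes labels them variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import i0e, i1e

from .stft import WindowSpec, marginals, psd_to_polar, windowed_psd

__all__ = [
    "MarginalFitQ",
    "MarginalFitTheta",
    "fit_q_marginal",
    "fit_theta_marginal",
    "ideal_widths",
    "normalized_broadening",
]

#: default rejection threshold on rms residual / peak height
DEFAULT_MAX_RESIDUAL = 0.35


@dataclass
class MarginalFitQ:
    q0: float
    sigma_fit: float
    sigma_id: float = float("nan")
    delta_sigma: float = float("nan")
    fit_ok: bool = False
    residual: float = float("nan")


@dataclass
class MarginalFitTheta:
    theta0: float
    sigma_fit: float
    sigma_id: float = float("nan")
    delta_sigma: float = float("nan")
    fit_ok: bool = False
    residual: float = float("nan")


def _gaussian(q, a, q0, sigma):
    return a * np.exp(-0.5 * ((q - q0) / sigma) ** 2)


def fit_q_marginal(
    p_q: np.ndarray,
    q_axis: np.ndarray,
    dc_exclusion_bins: int = 2,
    max_residual: float = DEFAULT_MAX_RESIDUAL,
) -> MarginalFitQ:
    """Least-squares Gaussian fit of the frequency marginal.

    The first ``dc_exclusion_bins`` bins are excluded: residual leakage
    of the (already suppressed) DC term piles up there and is not part of
    the stripe peak.  A flat marginal or a peak hugging the axis
    boundary yields ``fit_ok=False``, never an exception.
    """
    y = np.asarray(p_q, dtype=float)
    x = np.asarray(q_axis, dtype=float)
    if y.shape != x.shape or y.size < 8:
        raise ValueError("marginal and axis must match and have >= 8 bins")
    sl = slice(int(dc_exclusion_bins), None)
    x, y = x[sl], y[sl]
    dq = x[1] - x[0]

    ymax = float(y.max())
    if ymax <= 0 or ymax < 1.5 * float(y.mean()):
        # flat / featureless marginal
        return MarginalFitQ(q0=float(x[int(np.argmax(y))]), sigma_fit=float(x[-1] - x[0]),
                            fit_ok=False, residual=float("inf"))

    i0 = int(np.argmax(y))
    # moment-based initial width over a local neighborhood of the peak
    lo, hi = max(0, i0 - 6), min(len(x), i0 + 7)
    w = y[lo:hi]
    mu = float(np.sum(x[lo:hi] * w) / np.sum(w))
    var = float(np.sum((x[lo:hi] - mu) ** 2 * w) / np.sum(w))
    s0 = max(np.sqrt(var), dq / 2)
    p0 = (ymax, float(x[i0]), s0)
    bounds = ([0.0, x[0], dq / 10.0], [10.0 * ymax, x[-1], 0.5])
    try:
        popt, _ = curve_fit(_gaussian, x, y, p0=p0, bounds=bounds, maxfev=400)
    except RuntimeError:
        return MarginalFitQ(q0=float(x[i0]), sigma_fit=s0, fit_ok=False, residual=float("inf"))
    a, q0, sigma = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((y - _gaussian(x, *popt)) ** 2)) / ymax)
    ok = resid <= max_residual and (x[0] + dq) < q0 < (x[-1] - dq)
    return MarginalFitQ(q0=q0, sigma_fit=sigma, fit_ok=bool(ok), residual=resid)


def _axial_vonmises(theta_deg, a, theta0_deg, kappa):
    # exp(kappa*(cos-1)) parameterization avoids overflow at large kappa
    d = np.deg2rad(2.0 * (theta_deg - theta0_deg))
    return a * np.exp(kappa * (np.cos(d) - 1.0))


def _kappa_to_sigma_deg(kappa: float) -> float:
    """Circular std of the doubled-angle von Mises, halved, in degrees."""
    r = i1e(kappa) / i0e(kappa)
    r = min(max(float(r), 1e-12), 1.0 - 1e-12)
    return float(np.rad2deg(0.5 * np.sqrt(-2.0 * np.log(r))))


def fit_theta_marginal(
    p_theta: np.ndarray,
    theta_axis: np.ndarray,
    max_residual: float = DEFAULT_MAX_RESIDUAL,
) -> MarginalFitTheta:
    """Axial von Mises fit of the orientation marginal (doubled angles).

    ``theta0`` is half the fitted location of the doubled-angle peak,
    reduced modulo 180; ``sigma_fit`` is the equivalent circular standard
    deviation in degrees.  Isotropic (flat) marginals give
    ``fit_ok=False``.
    """
    y = np.asarray(p_theta, dtype=float)
    t = np.asarray(theta_axis, dtype=float)
    if y.shape != t.shape or y.size < 8:
        raise ValueError("marginal and axis must match and have >= 8 bins")
    tot = float(y.sum())
    if tot <= 0:
        return MarginalFitTheta(theta0=0.0, sigma_fit=90.0, fit_ok=False, residual=float("inf"))
    z = np.sum((y / tot) * np.exp(2j * np.deg2rad(t)))
    rbar = float(np.abs(z))
    theta0_init = float(np.rad2deg(np.angle(z) / 2.0) % 180.0)
    ymax = float(y.max())
    if rbar < 0.03 or ymax < 1.5 * float(y.mean()):
        return MarginalFitTheta(theta0=theta0_init, sigma_fit=90.0, fit_ok=False,
                                residual=float("inf"))
    # Fisher's approximation for the concentration of the doubled angle
    if rbar < 0.53:
        k0 = 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    elif rbar < 0.85:
        k0 = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k0 = 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)
    k0 = min(max(k0, 0.1), 1e4)
    p0 = (ymax, theta0_init, k0)
    bounds = ([0.0, theta0_init - 90.0, 1e-3], [10.0 * ymax, theta0_init + 90.0, 1e6])
    try:
        popt, _ = curve_fit(_axial_vonmises, t, y, p0=p0, bounds=bounds, maxfev=400)
    except RuntimeError:
        return MarginalFitTheta(theta0=theta0_init, sigma_fit=_kappa_to_sigma_deg(k0),
                                fit_ok=False, residual=float("inf"))
    a, theta0, kappa = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((y - _axial_vonmises(t, *popt)) ** 2)) / ymax)
    return MarginalFitTheta(theta0=theta0 % 180.0, sigma_fit=_kappa_to_sigma_deg(kappa),
                            fit_ok=bool(resid <= max_residual), residual=resid)


@lru_cache(maxsize=4096)
def _ideal_widths_cached(qkey: int, qstep: float, spec: WindowSpec, n_q: int,
                         n_theta: int, dc_exclusion_bins: int) -> tuple[float, float]:
    q0 = qkey * qstep
    ps = spec.patch_size
    rad = spec.support_radius
    x = np.arange(ps, dtype=float) - rad
    # perfect binarized stripe pattern, vertical (orientation 90 deg)
    row = (np.cos(2 * np.pi * q0 * x) >= 0).astype(np.float64)
    pattern = np.tile(row, (ps, 1))
    psd = windowed_psd(pattern, (rad, rad), spec)
    polar = psd_to_polar(psd, n_q=n_q, n_theta=n_theta)
    marg = marginals(polar)
    fq = fit_q_marginal(marg.p_q, polar.q_axis, dc_exclusion_bins=dc_exclusion_bins)
    ft = fit_theta_marginal(marg.p_theta, polar.theta_axis)
    return float(fq.sigma_fit), float(ft.sigma_fit)


def ideal_widths(
    q0: float,
    spec: WindowSpec,
    n_q: int = 64,
    n_theta: int = 90,
    dc_exclusion_bins: int = 2,
) -> tuple[float, float]:
    """Finite-window widths (sigma_q_id, sigma_theta_id) at frequency q0.

    Synthesizes a perfect constant-frequency binary stripe pattern, runs
    it through the identical windowed-PSD -> polar -> marginal -> fit
    pipeline, and returns the fitted widths.  Results are cached on a
    quarter-q-bin quantization of ``q0`` (the widths vary slowly with q0,
    so the quantization error is negligible while the cache makes map
    construction cheap).
    """
    ps = spec.patch_size
    q_axis_lo = 1.0 / ps
    dq = (0.5 - q_axis_lo) / (n_q - 1)
    floor = q_axis_lo + dc_exclusion_bins * dq
    if not (floor < q0 < 0.475):
        raise ValueError(f"q0={q0:.4g} at or beyond the fitted q-axis boundary")
    qstep = dq / 4.0
    return _ideal_widths_cached(int(round(q0 / qstep)), qstep, spec,
                                int(n_q), int(n_theta), int(dc_exclusion_bins))


def normalized_broadening(sigma_fit: float, sigma_id: float) -> float:
    """(sigma_fit - sigma_id) / sigma_id, clipped below at 0."""
    if not sigma_id > 0:
        raise ValueError("sigma_id must be positive")
    return max(0.0, (float(sigma_fit) - float(sigma_id)) / float(sigma_id))
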