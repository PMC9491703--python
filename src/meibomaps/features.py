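"""Reduction of the six morphometric maps to 30 histogram-statistic features.

For each map the distribution of its valid pixel values is summarized by
five measures — entropy, mean, variance, skewness and kurtosis — giving
6 x 5 = 30 descriptive features per image.  Healthy gland patterns yield
narrow, low-valued distributions for the homogeneity-sensitive maps
(sigma_q, G_q, sigma_theta, C_theta); distortion pushes mass to higher
values, which the five measures pick up.

Conventions: entropy is Shannon entropy of the normalized histogram
masses in nats; kurtosis follows the Pearson convention (a normal
distribution scores 3); skewness/kurtosis of a constant map are set to 0
and flagged.  The orientation map theta0 is axial, so its *mean* is the
circular mean of doubled angles (halved back, in [0, 180)); the
remaining theta0 measures operate on the linear degree values, which is
adequate because the per-image orientation spread is far from the
0/180 seam for upper-eyelid glands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import MorphoMaps

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "MAP_ORDER",
    "MEASURE_ORDER",
    "map_histogram",
    "distribution_measures",
    "extract_features",
]

MAP_ORDER = ("q0", "sigma_q", "g_q", "theta0", "sigma_theta", "c_theta")
MEASURE_ORDER = ("entropy", "mean", "variance", "skewness", "kurtosis")
FEATURE_NAMES = tuple(f"{m}_{s}" for m in MAP_ORDER for s in MEASURE_ORDER)


@dataclass
class FeatureVector:
    """30 named scalars in fixed order, plus identity and optional label."""

    values: np.ndarray
    image_id: str = ""
    label: str | None = None
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(f"expected {len(self.names)} feature values")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def map_histogram(map_values: np.ndarray, valid_mask: np.ndarray | None = None,
                  n_bins: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram of the valid map values.

    Returns ``(density, bin_edges)`` with the bins spanning
    [min, max] of the valid values.  A constant map occupies a single
    bin (numpy widens a zero-width range), which is legal and carries
    zero entropy.
    """
    a = np.asarray(map_values, dtype=float)
    valid = np.isfinite(a) if valid_mask is None else np.asarray(valid_mask, bool) & np.isfinite(a)
    vals = a[valid]
    if vals.size < 10:
        raise ValueError("need at least 10 valid values for a histogram")
    density, edges = np.histogram(vals, bins=int(n_bins), density=True)
    return density, edges


def distribution_measures(values: np.ndarray, n_bins: int = 64) -> dict[str, float]:
    """Entropy, mean, variance, skewness, kurtosis of a sample.

    Moments are computed from the raw values (population convention,
    standardized 3rd/4th moments, kurtosis of a normal = 3); entropy is
    ``-sum(p_i * ln(p_i))`` over the normalized masses of an
    ``n_bins``-bin histogram, so a uniform occupation of B bins scores
    exactly ``ln(B)``.  A zero-variance sample has undefined
    skewness/kurtosis; both are set to 0 and ``degenerate`` is flagged.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("empty sample")
    mean = float(v.mean())
    var = float(v.var())
    degenerate = var <= 0.0
    if degenerate:
        skew = kurt = 0.0
    else:
        z = (v - mean) / np.sqrt(var)
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))
    counts, _ = np.histogram(v, bins=int(n_bins))
    p = counts / counts.sum()
    p = p[p > 0]
    entropy = float(-np.sum(p * np.log(p)))
    return {"entropy": entropy, "mean": mean, "variance": var,
            "skewness": skew, "kurtosis": kurt, "degenerate": degenerate}


def _circular_mean_deg(theta_deg: np.ndarray) -> float:
    """Axial mean: circular mean of doubled angles, halved, in [0, 180)."""
    z = np.exp(2j * np.deg2rad(np.asarray(theta_deg, dtype=float)))
    return float(np.rad2deg(np.angle(z.mean()) / 2.0) % 180.0)


def extract_features(maps: MorphoMaps, n_bins: int = 64,
                     image_id: str = "", label: str | None = None) -> FeatureVector:
    """The 30-vector of (6 maps) x (5 distribution measures).

    Order is fixed by ``FEATURE_NAMES``.  Identical maps produce
    identical vectors (the computation is deterministic).
    """
    valid = maps.valid_mask
    out: list[float] = []
    for name, raster in maps.as_dict().items():
        vals = raster[valid & np.isfinite(raster)]
        meas = distribution_measures(vals, n_bins=n_bins)
        if name == "theta0":
            meas["mean"] = _circular_mean_deg(vals)
        out.extend(meas[k] for k in MEASURE_ORDER)
    return FeatureVector(values=np.asarray(out), image_id=image_id, label=label)
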