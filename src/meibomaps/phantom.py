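"""Synthetic meibography phantoms with analytically known ground truth.

Meibomian glands in an infrared meibogram appear as bright quasi-parallel
stripes inside the everted eyelid.  The phantoms here render binary
stripe patterns as thresholded cosines of a phase field whose gradient is
the local wave vector, so the spatial frequency and stripe orientation
are known in closed form at every pixel.  Two distortions mirror the
clinically graded ones: *bending* (a smooth sinusoidal perturbation of
the orientation field along the stripe direction) and *narrowing* (a
linear frequency ramp across the stripes).  Gland drop-out (erased
patches) and i.i.d. binarization pixel noise can be layered on top
without altering the analytic ground-truth fields.

``generate_labeled_dataset`` builds a three-class cohort following the
clinical counting rule: a *healthy* image has no distortion, an
*intermediate* one has 1-4 locally distorted stripe regions and an
*unhealthy* one at least 5, where a region counts as distorted when the
local orientation deviates from the eyelid's base orientation by more
than 45 degrees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EyelidMask, GlandImage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_labeled_dataset",
    "CLASS_LABELS",
]

CLASS_LABELS = ("healthy", "intermediate", "unhealthy")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one stripe phantom.

    ``base_frequency`` is in cycles/pixel (must stay below Nyquist also
    at the end of the narrowing ramp), ``base_orientation`` and
    ``bend_amplitude`` in degrees, ``bend_wavelength`` in pixels along
    the stripe direction, ``narrowing_slope`` in (cycles/pixel) per
    pixel across the stripes.  The elliptical eyelid mask defaults to a
    centered ellipse covering most of the frame.
    """

    height: int = 180
    width: int = 260
    base_frequency: float = 0.1
    base_orientation: float = 90.0
    bend_amplitude: float = 0.0
    bend_wavelength: float = 40.0
    narrowing_slope: float = 0.0
    dropout_fraction: float = 0.0
    noise_flip_prob: float = 0.0
    mask_center: tuple[float, float] | None = None
    mask_semiaxes: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("phantom dimensions must be positive")
        if not (0.0 < self.base_frequency < 0.5):
            raise ValueError("base_frequency must lie in (0, 0.5) cycles/pixel")
        for name in ("dropout_fraction", "noise_flip_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bend_wavelength <= 0:
            raise ValueError("bend_wavelength must be positive")
        if self.narrowing_slope < 0:
            raise ValueError("narrowing_slope must be non-negative")
        span = float(np.hypot(self.height, self.width))
        if self.base_frequency + self.narrowing_slope * span >= 0.5:
            raise ValueError("narrowing ramp reaches the Nyquist frequency")

    def resolved_mask(self) -> tuple[tuple[float, float], tuple[float, float]]:
        center = self.mask_center or ((self.height - 1) / 2.0, (self.width - 1) / 2.0)
        semi = self.mask_semiaxes or (0.44 * self.height, 0.46 * self.width)
        return center, semi


@dataclass
class GroundTruth:
    """Analytic per-pixel frequency/orientation fields of a phantom."""

    frequency_field: np.ndarray
    orientation_field: np.ndarray
    class_label: str | None = None
    distorted_regions: list[tuple[float, float, float]] = field(default_factory=list)


def _ellipse_mask(shape: tuple[int, int], center, semiaxes) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / semiaxes[0]) ** 2
            + ((cc - center[1]) / semiaxes[1]) ** 2) <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[GlandImage, EyelidMask, GroundTruth]:
    """Render a binary stripe phantom plus its mask and ground truth.

    The phase is the line integral of the local wave-vector field, so
    the returned analytic fields are exactly the gradient of the phase
    actually rendered.  Thresholding the cosine at zero gives a 50% duty
    cycle.  Identical spec (including seed) gives a bit-identical
    phantom.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    th0 = np.deg2rad(spec.base_orientation)
    # u runs along the wave vector (across stripes), v along the stripes
    u = xx * np.sin(th0) - yy * np.cos(th0)
    v = xx * np.cos(th0) + yy * np.sin(th0)
    u0 = u.min()

    q0, s = spec.base_frequency, spec.narrowing_slope
    b_rad = np.deg2rad(spec.bend_amplitude)
    lam = spec.bend_wavelength

    # transverse displacement T(v) with T'(v) = tan(delta(v)),
    # delta(v) = bend_amplitude * sin(2 pi v / lambda)
    v1 = np.arange(np.floor(v.min()) - 1.0, np.ceil(v.max()) + 2.0)
    slope1 = np.tan(b_rad * np.sin(2 * np.pi * v1 / lam))
    t1 = np.concatenate([[0.0], np.cumsum((slope1[1:] + slope1[:-1]) / 2.0)])
    t_of_v = np.interp(v, v1, t1)

    phase = 2 * np.pi * (q0 * (u - u0) + 0.5 * s * (u - u0) ** 2 + q0 * t_of_v)
    k_u = q0 + s * (u - u0)
    k_v = q0 * np.tan(b_rad * np.sin(2 * np.pi * v / lam))
    freq = np.hypot(k_u, k_v)
    if freq.max() >= 0.5:
        raise ValueError("local frequency reaches the Nyquist limit")
    orient = (spec.base_orientation + np.rad2deg(np.arctan2(k_v, k_u))) % 180.0

    img = (np.cos(phase) >= 0).astype(np.uint8)
    center, semi = spec.resolved_mask()
    mask = _ellipse_mask((h, w), center, semi)

    if spec.dropout_fraction > 0:
        target = spec.dropout_fraction * mask.sum()
        erased = np.zeros((h, w), dtype=bool)
        radius = max(6.0, 0.06 * min(h, w))
        for _ in range(200):
            if (erased & mask).sum() >= target:
                break
            cr = rng.uniform(0, h)
            cc_ = rng.uniform(0, w)
            rr, cc = np.mgrid[0:h, 0:w]
            erased |= (rr - cr) ** 2 + (cc - cc_) ** 2 <= radius ** 2
        img[erased] = 0

    if spec.noise_flip_prob > 0:
        flips = rng.random((h, w)) < spec.noise_flip_prob
        img[flips] = 1 - img[flips]

    gland = GlandImage(pixels=img, is_binary=True,
                       meta={"phantom_spec": dataclasses.asdict(spec)})
    truth = GroundTruth(frequency_field=freq, orientation_field=orient)
    return gland, EyelidMask(pixels=mask, source="raster"), truth


def _apply_distorted_regions(
    img: np.ndarray,
    truth: GroundTruth,
    mask: np.ndarray,
    base_orientation: float,
    base_frequency: float,
    n_regions: int,
    rng: np.random.Generator,
    radius: float = 22.0,
) -> None:
    """Re-render ``n_regions`` disjoint circular patches with a strongly
    deviated stripe orientation (always > 45 deg from base, the clinical
    distortion rule) and, half of the time, a narrowed (higher)
    frequency.  Image and ground-truth fields are updated in place."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    centers: list[tuple[float, float]] = []
    placed = 0
    attempts = 0
    while placed < n_regions and attempts < 500:
        attempts += 1
        cr = rng.uniform(radius, h - radius)
        cc = rng.uniform(radius, w - radius)
        if not mask[int(cr), int(cc)]:
            continue
        if any((cr - a) ** 2 + (cc - b) ** 2 < (2 * radius + 4) ** 2 for a, b in centers):
            continue
        centers.append((cr, cc))
        sign = 1 if rng.random() < 0.5 else -1
        dev = sign * rng.uniform(50.0, 70.0)
        theta = (base_orientation + dev) % 180.0
        q = base_frequency * (rng.uniform(1.6, 2.1) if rng.random() < 0.5 else 1.0)
        thr = np.deg2rad(theta)
        phase = 2 * np.pi * q * (xx * np.sin(thr) - yy * np.cos(thr))
        inside = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius ** 2
        img[inside] = (np.cos(phase[inside]) >= 0).astype(np.uint8)
        truth.orientation_field[inside] = theta
        truth.frequency_field[inside] = q
        truth.distorted_regions.append((cr, cc, radius))
        placed += 1
    if placed < n_regions:
        raise RuntimeError("could not place the requested distorted regions")


def generate_labeled_dataset(
    n_per_class: int,
    seed: int,
    *,
    height: int = 180,
    width: int = 260,
    noise_flip_prob: float = 0.02,
) -> list[tuple[GlandImage, EyelidMask, GroundTruth]]:
    """Three-class phantom cohort with the clinical counting rule.

    healthy: no distorted region; intermediate: 1-4; unhealthy: 5-8.
    Base frequency and orientation vary mildly between images.  The
    output order is healthy block, intermediate block, unhealthy block;
    deterministic under ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[GlandImage, EyelidMask, GroundTruth]] = []
    for label in CLASS_LABELS:
        for _ in range(n_per_class):
            spec = PhantomSpec(
                height=height,
                width=width,
                base_frequency=float(rng.uniform(0.09, 0.115)),
                base_orientation=float(rng.uniform(80.0, 100.0)),
                noise_flip_prob=0.0,  # noise applied after region painting
                seed=int(rng.integers(2**31)),
            )
            gland, mask, truth = generate_phantom(spec)
            if label == "healthy":
                k = 0
            elif label == "intermediate":
                k = int(rng.integers(1, 5))
            else:
                k = int(rng.integers(5, 9))
            if k:
                _apply_distorted_regions(gland.pixels, truth, mask.pixels,
                                         spec.base_orientation,
                                         spec.base_frequency, k, rng)
            if noise_flip_prob > 0:
                flips = rng.random(gland.pixels.shape) < noise_flip_prob
                gland.pixels[flips] = 1 - gland.pixels[flips]
            truth.class_label = label
            gland.meta["class_label"] = label
            gland.meta["n_distorted_regions"] = k
            out.append((gland, mask, truth))
    return out
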