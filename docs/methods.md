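# Methods

## The analysis in one paragraph

Healthy meibomian glands appear in an infrared meibogram as bright,
quasi-parallel stripes crossing the everted eyelid. Such a pattern has a
well-defined local spatial frequency `q` (the inverse of gland width /
separation, in cycles/pixel) and a local axial orientation `theta`
(degrees, period 180). `meibomaps` measures both fields by a 2D
short-time Fourier transform: a Gaussian window slides over a stride-10
grid of positions inside the eyelid mask, the power spectral density
(PSD) of each mean-subtracted, windowed patch is resampled to polar
coordinates `(q, theta)` and normalized into a probability map, and the
two marginals `p(q)` and `p(theta)` are fitted with a Gaussian and an
axial von Mises peak. The fitted peak positions give the `q0` and
`theta0` maps; the fitted widths, after subtracting the broadening that
a finite window imposes even on a perfect pattern, give the spread maps
`sigma_q` and `sigma_theta`; two derived maps, the frequency-gradient
magnitude `G_q` and the angular incoherence `C_theta`, localize where
gland width and gland direction change. Thresholding `G_q` and
`C_theta` yields the area meibo-scores `A_q` and `A_theta` (percent of
eyelid area affected). For classification, each of the six maps is
reduced to five distribution measures (entropy, mean, variance,
skewness, kurtosis), the resulting 30 features are embedded into two
PCA or LDA components, and an image is assigned to the class maximizing
the product of the per-class 1D densities of the two components.

## Model assumptions

* The gland pattern is locally a single oriented quasi-periodic texture:
  one dominant `(q, theta)` per window. Windows containing two
  interleaved orientations produce broad or bimodal marginals; the fits
  flag these (`fit_ok = False`) and the grid point is masked, not
  interpolated.
* Orientation is axial (stripe direction, not a signed vector). All
  circular statistics operate on doubled angles: the von Mises fit is
  performed on `2*theta`, the angular incoherence uses resultant vectors
  of `2*theta0`, and the circular mean feature halves the doubled-angle
  mean back into `[0, 180)`.
* The PSD of a real image is centrosymmetric, so only the half-plane
  `theta in [0, 180)` is resampled.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `sigma_r` | 8 | px | Gaussian window std. Must span >= ~1.5 stripe periods at the typical gland frequency (q ~ 0.1) so the spectral peak separates from DC, yet stay small enough that the window does not low-pass the orientation field it is supposed to map. 8 px resolves orientation modulations down to ~30 px wavelength; a much wider window (e.g. 15 px) attenuates the measured `theta0` modulation of any +/-30 deg bend below the `C_theta` detection threshold. |
| `support_radius` | 24 | px | Patch half-size; >= 3 sigma_r keeps the truncated Gaussian's mass. Patch side 49 px fixes the cartesian frequency step at 1/49 cycles/px. |
| `stride` | 10 | px | One window per 10th pixel: the native map resolution. |
| `n_q`, `n_theta` | 64, 90 | bins | Polar grid: ~0.0076 cycles/px and 2 deg per bin; finer bins destabilize the fits, coarser ones quantize the maps. |
| `dc_exclusion_bins` | 2 | bins | Residual DC leakage occupies the lowest q bins; the Gaussian fit of `p(q)` starts above them. |
| `max_residual` | 0.35 | — | Fit rejection: rms residual normalized by peak height. |
| `neighborhood` | 3 | map px | `C_theta` window (3x3 grid cells = 30x30 image px). |
| `g_q` threshold | 0.007 | (cycles/px)/map px | Area-score cut for `A_q`. |
| `c_theta` threshold | 0.1 | — | Area-score cut for `A_theta`. |

## Window-broadening correction (`delta sigma`)

A finite Gaussian window broadens `p(q)` and `p(theta)` even for a
perfect constant-frequency pattern (the PSD of a windowed cosine is a
Gaussian of std `1/(2*sqrt(2)*pi*sigma_r)` in q; the angular width
scales as the same spectral blur divided by the peak radius `q0`).
Rather than a closed form, the *ideal* widths are obtained by running
the identical pipeline — binarized perfect stripes, same window, same
polar grid, same fits — at the fitted `q0`, cached on a quarter-bin
quantization of `q0`. This choice makes the normalized excess
`delta_sigma = (sigma_fit - sigma_id)/sigma_id` exactly zero-calibrated:
on a distortion-free phantom it is 0 up to interpolation noise, and any
positive value reflects genuine pattern inhomogeneity, not the window.
Small negative excesses are clipped to 0.

## Derived maps and their units

`G_q` is the central-difference gradient magnitude of the `q0` map with
one-sided differences at validity borders and invalid neighbors
excluded. Units are (cycles/pixel) **per map pixel**, i.e. per grid
stride: the maps are the native rasters of the analysis, so their
gradient is naturally taken per map sample, and the default threshold
0.007 is calibrated to this convention (0.007 per 10-px step = 7e-4
cycles/px per image pixel, a realistic narrowing rate; expressed per
image pixel the same threshold would be unreachable by any physically
plausible gland pattern). The threshold is configuration-exposed and not
transferable to other unit conventions.

`C_theta = 1 - Rbar` where `Rbar` is the mean resultant length of the
doubled orientation angles over the 3x3 valid neighborhood. It is 0 for
a locally uniform orientation field and approaches 1 where orientations
within the neighborhood oppose each other (e.g. a 0/90 deg domain
wall); axially close angles like 179 and 1 deg are correctly coherent.

## The phantom generator

Phantoms are thresholded cosines of a phase field whose gradient is the
local wave vector, so the ground-truth frequency and orientation fields
are exact by construction (the analytic fields are derived from the very
phase that is rendered). Distortions:

* **bending** — a sinusoidal orientation perturbation of amplitude
  `bend_amplitude` (deg) and wavelength `bend_wavelength` (px, default
  40) along the stripe direction, realized through a transverse
  displacement whose slope is `tan(delta(v))` (numerically integrated,
  so the ground truth stays exact at large amplitudes);
* **narrowing** — a linear frequency ramp `q(u) = q0 + s*u` across the
  stripes, rejected if it reaches Nyquist anywhere in the frame;
* **drop-out** — erased circular patches (gland cut-off); leaves the
  analytic fields untouched;
* **binarization noise** — i.i.d. pixel flips.

The default bend wavelength of 40 px (= 4 grid strides) makes an
orientation modulation maximally visible to the stride-10 analysis grid
while staying above the window's resolution limit; much shorter
wavelengths are averaged away by the window, much longer ones produce
negligible orientation contrast between neighboring grid cells.

The labeled cohort mirrors the clinical counting rule: *healthy* images
have no distortion; *intermediate* ones carry 1–4 locally distorted
circular regions; *unhealthy* ones 5–8. Every distorted region deviates
the stripe orientation by 50–70 deg (beyond the clinical 45 deg rule)
and half of them also narrow the stripes by a factor 1.6–2.1. Base
frequency (0.09–0.115 cycles/px) and base orientation (80–100 deg) vary
mildly between images; 2% pixel-flip noise is applied everywhere.

What the phantoms do **not** emulate: acquisition optics, illumination
gradients, specular reflections, partial binarization failures, gland
duct texture, and eyelid curvature. Passing tests on phantoms therefore
demonstrate the correctness of the measurement chain (fields in,
fields out), not clinical performance on real meibograms; the cohort
classification result in particular shows that the 30 features carry
the injected class structure, not that real gland grading reaches the
same accuracy.

## Numerical choices

* Patch mean subtraction before windowing suppresses the DC term; the
  lowest two polar q bins are additionally excluded from the `p(q)` fit.
* Polar resampling uses bilinear interpolation onto the uniform
  `(q, theta)` lattice with no explicit Jacobian weight: the uniform
  resampling itself performs the area reweighting, and the subsequent
  normalization to unit mass absorbs global factors.
* Nonlinear fits start from the empirical peak bin and circular/linear
  moments, with bounded parameters; the axial von Mises uses an
  `exp(kappa*(cos - 1))` parameterization to avoid overflow at large
  concentration, and its width is reported as the halved circular std
  `0.5*sqrt(-2*ln(I1(kappa)/I0(kappa)))` in degrees.
* Degenerate inputs: constant patches are flagged and skipped; flat
  marginals set `fit_ok = False` rather than raising; maps with fewer
  than 4 valid grid points raise (`insufficient coverage`); constant
  maps have entropy 0 and flagged skewness/kurtosis 0.
* Tie-breaking in classification is severity-ordered (healthy <
  intermediate < unhealthy): among exactly equal density products the
  more severe class wins, so borderline cases are never under-called.
  A point with zero density under every class is `unclassifiable`.
* Kurtosis uses the Pearson convention (normal = 3); entropy uses
  natural logarithms.
* Evaluation defaults to leave-one-out cross-validation, with
  resubstitution available for comparison; confidence intervals are
  nonparametric bootstrap (2000 resamples, seeded) over the per-image
  correctness indicators within each class.

## Problem sizes used in the shipped checks

The reference recovery phantom is 600x400 px (about 1500 valid grid
points); the distortion series uses 280x200 px phantoms; the labeled
cohort is 90 images of 260x180 px (about 290 grid points each). These
sizes give stable statistics for every asserted property while keeping
a full test run in the minutes range on one CPU.

## Known limitations

* One dominant orientation per window: crossing gland bundles are
  flagged rather than decomposed (no mixture fits).
* `A_theta` responds to *spatial changes* of the mean orientation. A
  smooth sinusoidal bend of amplitude B can shift neighboring-window
  orientations by at most 2B before window averaging; for B = 15 deg
  the 3x3 doubled-angle incoherence is then mathematically capped near
  0.09, below the 0.1 threshold, so gentle low-amplitude bending is
  invisible to `A_theta` (while clearly visible to `sigma_theta`).
  Abrupt orientation changes — the clinically graded kind — exceed the
  threshold easily.
* The 0.007 and 0.1 thresholds are convention-bound (see units above)
  and should be recalibrated for imaging systems with a different pixel
  scale.
* Drop-out area (the classical atrophy score) is deliberately out of
  scope; the generator's drop-out knob exists to test robustness, not
  to measure atrophy.
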