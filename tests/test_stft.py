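"""Windowed PSD, polar resampling and marginals."""

import numpy as np
import pytest

from meibomaps import (
    EyelidMask,
    WindowSpec,
    marginals,
    psd_to_polar,
    window_positions,
    windowed_psd,
)
from meibomaps.stft import _gaussian_window

from conftest import stripe_patch


def naive_dft2_psd(a: np.ndarray) -> np.ndarray:
    """Squared modulus of the 2D DFT by explicit summation (no FFT),
    with the zero-frequency bin shifted to the center index."""
    m, n = a.shape
    j = np.arange(m)
    k = np.arange(n)
    Em = np.exp(-2j * np.pi * np.outer(j, j) / m)
    En = np.exp(-2j * np.pi * np.outer(k, k) / n)
    F = Em @ a.astype(complex) @ En
    return np.abs(np.roll(np.roll(F, (m - 1) // 2, axis=0), (n - 1) // 2, axis=1)) ** 2


class TestWindowPositions:
    def test_full_mask_lattice_count(self):
        spec = WindowSpec(stride=10)
        pos = window_positions(np.ones((100, 100), bool), spec)
        assert len(pos) == 100
        assert (pos % 10 == 0).all()

    def test_single_pixel_mask(self):
        m = np.zeros((40, 40), bool)
        m[10, 10] = True
        pos = window_positions(m, WindowSpec(stride=10))
        assert pos.tolist() == [[10, 10]]

    def test_elliptical_mask_positions_all_inside(self):
        yy, xx = np.mgrid[0:90, 0:120]
        m = ((yy - 45) / 40.0) ** 2 + ((xx - 60) / 55.0) ** 2 <= 1
        pos = window_positions(m, WindowSpec(stride=10))
        # brute-force lattice scan oracle
        expected = [(r, c) for r in range(0, 90, 10) for c in range(0, 120, 10) if m[r, c]]
        assert pos.tolist() == [list(t) for t in expected]

    def test_mask_missing_all_lattice_points_raises(self):
        m = np.zeros((40, 40), bool)
        m[5, 5] = True  # not on the stride-10 lattice
        with pytest.raises(ValueError, match="mask too small"):
            window_positions(m, WindowSpec(stride=10))


class TestWindowedPSD:
    def test_constant_image_degenerate(self):
        spec = WindowSpec()
        psd = windowed_psd(np.full((80, 80), 3.0), (40, 40), spec)
        assert psd.is_degenerate
        assert np.allclose(psd.values, 0.0)

    def test_cosine_peaks_at_carrier_frequency(self):
        spec = WindowSpec()
        img = stripe_patch(120, q=0.1, theta_deg=90.0, binary=False)
        psd = windowed_psd(img, (60, 60), spec)
        n = psd.values.shape[0]
        dc = psd.dc_index
        # two dominant symmetric maxima at (0, +/- q*n) offsets from DC
        flat = np.argsort(psd.values.ravel())[-2:]
        peaks = sorted([(p // n - dc[0], p % n - dc[1]) for p in flat])
        expected_off = round(0.1 * n)
        assert peaks == [(0, -expected_off), (0, expected_off)]

    def test_center_outside_image_raises(self):
        with pytest.raises(ValueError):
            windowed_psd(np.zeros((50, 50)), (60, 10), WindowSpec())

    def test_matches_naive_dft_oracle(self):
        """FFT path vs explicit O(N^4)-equivalent summation on a 32x32
        image patch, 1e-10 relative agreement."""
        rng = np.random.default_rng(5)
        img = (rng.random((32, 32)) > 0.5).astype(float)
        spec = WindowSpec(sigma_r=5.0, support_radius=15)
        psd = windowed_psd(img, (16, 16), spec)
        # reconstruct the exact windowed patch the implementation sees
        ps = spec.patch_size
        patch = img[1:1 + ps, 1:1 + ps].copy()
        patch -= patch.mean()
        wp = patch * _gaussian_window(ps, 5.0)
        oracle = naive_dft2_psd(wp)
        scale = oracle.max()
        assert np.abs(psd.values - oracle).max() <= 1e-10 * scale

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(6)
        img = rng.random((80, 80))
        spec = WindowSpec()
        psd = windowed_psd(img, (40, 40), spec)
        ps = spec.patch_size
        patch = img[40 - 24:40 + 25, 40 - 24:40 + 25].copy()
        patch -= patch.mean()
        wp = patch * _gaussian_window(ps, spec.sigma_r)
        # sum |F|^2 = N_total * sum |f|^2 for the numpy DFT convention
        assert psd.values.sum() == pytest.approx(ps * ps * (wp ** 2).sum(), rel=1e-8)


class TestPolar:
    def test_normalization(self):
        img = stripe_patch(100, 0.1, 30.0)
        polar = psd_to_polar(windowed_psd(img, (50, 50), WindowSpec()))
        assert polar.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert (polar.values >= 0).all()

    @pytest.mark.parametrize("theta", [30.0, 90.0, 120.0])
    def test_peak_at_stripe_orientation(self, theta):
        img = stripe_patch(100, 0.1, theta)
        polar = psd_to_polar(windowed_psd(img, (50, 50), WindowSpec()))
        iq, it = np.unravel_index(np.argmax(polar.values), polar.values.shape)
        assert polar.q_axis[iq] == pytest.approx(0.1, abs=polar.q_axis[1] - polar.q_axis[0])
        dt = polar.theta_axis[1] - polar.theta_axis[0]
        d = abs(polar.theta_axis[it] - theta) % 180
        assert min(d, 180 - d) <= dt

    def test_peak_bin_matches_direct_binning_oracle(self):
        """Nearest-neighbor binning of every cartesian PSD pixel must
        put its maximum in the same (q, theta) bin as the bilinear
        resampler."""
        img = stripe_patch(100, 0.12, 40.0)
        psd = windowed_psd(img, (50, 50), WindowSpec())
        polar = psd_to_polar(psd)
        n = psd.values.shape[0]
        dc = psd.dc_index
        q_axis, t_axis = polar.q_axis, polar.theta_axis
        dq = q_axis[1] - q_axis[0]
        dt = t_axis[1] - t_axis[0]
        acc = np.zeros_like(polar.values)
        for r in range(n):
            for c in range(n):
                qy, qx = (r - dc[0]) / n, (c - dc[1]) / n
                q = np.hypot(qx, qy)
                if q < q_axis[0] - dq / 2 or q > 0.5:
                    continue
                th = (np.rad2deg(np.arctan2(qy, qx)) + 90.0) % 180.0
                iq = int(np.clip(round((q - q_axis[0]) / dq), 0, len(q_axis) - 1))
                it = int(np.clip(round((th - t_axis[0]) / dt), 0, len(t_axis) - 1)) % len(t_axis)
                acc[iq, it] += psd.values[r, c]
        # the two discretizations (nearest binning vs bilinear sampling)
        # may quantize the argmax differently; require physical agreement
        # at the cartesian resolution of the PSD (1/n in q; the angular
        # pixel footprint at the peak radius in theta)
        iq_o, it_o = np.unravel_index(np.argmax(acc), acc.shape)
        iq_b, it_b = np.unravel_index(np.argmax(polar.values), polar.values.shape)
        assert abs(q_axis[iq_o] - q_axis[iq_b]) <= 1.5 / n
        ang_res = np.rad2deg(np.arctan2(1.5 / n, q_axis[iq_b]))
        d = abs(t_axis[it_o] - t_axis[it_b]) % 180.0
        assert min(d, 180.0 - d) <= ang_res
        assert acc.sum() / psd.values.sum() > 0.5  # oracle captured the energy

    def test_all_zero_psd_raises(self):
        with pytest.raises(ValueError, match="no spectral energy"):
            psd_to_polar(windowed_psd(np.zeros((80, 80)), (40, 40), WindowSpec()))


class TestMarginals:
    def test_sum_to_one(self):
        img = stripe_patch(100, 0.1, 60.0)
        marg = marginals(psd_to_polar(windowed_psd(img, (50, 50), WindowSpec())))
        assert marg.p_q.sum() == pytest.approx(1.0)
        assert marg.p_theta.sum() == pytest.approx(1.0)

    def test_separable_density_recovers_factors(self):
        from meibomaps.stft import PolarPSD

        q_axis = np.linspace(0.02, 0.5, 64)
        t_axis = np.linspace(1, 179, 90)
        f = np.exp(-0.5 * ((q_axis - 0.2) / 0.05) ** 2)
        g = np.exp(-0.5 * ((t_axis - 70) / 15.0) ** 2)
        joint = np.outer(f, g)
        joint /= joint.sum()
        marg = marginals(PolarPSD(values=joint, q_axis=q_axis, theta_axis=t_axis))
        assert np.allclose(marg.p_q, f / f.sum())
        assert np.allclose(marg.p_theta, g / g.sum())

    def test_phantom_marginal_peaks(self):
        img = stripe_patch(100, 0.1, 30.0)
        polar = psd_to_polar(windowed_psd(img, (50, 50), WindowSpec()))
        marg = marginals(polar)
        assert polar.q_axis[np.argmax(marg.p_q)] == pytest.approx(0.1, abs=0.01)
        assert polar.theta_axis[np.argmax(marg.p_theta)] == pytest.approx(30.0, abs=2.0)


class TestEquivariance:
    @pytest.mark.parametrize("phi", [15.0, 45.0, 90.0])
    def test_rotation_shifts_theta_peak(self, phi):
        from skimage.transform import rotate

        base = stripe_patch(140, 0.1, 30.0, binary=False)
        rot = rotate(base, -phi, order=3)  # skimage rotates CCW in (row,col) display
        spec = WindowSpec()
        m0 = marginals(psd_to_polar(windowed_psd(base, (70, 70), spec)))
        m1 = marginals(psd_to_polar(windowed_psd(rot, (70, 70), spec)))
        polar_axis = psd_to_polar(windowed_psd(base, (70, 70), spec)).theta_axis
        t0 = polar_axis[np.argmax(m0.p_theta)]
        t1 = polar_axis[np.argmax(m1.p_theta)]
        dt = polar_axis[1] - polar_axis[0]
        d = abs((t1 - (t0 + phi)) % 180.0)
        assert min(d, 180.0 - d) <= dt

    def test_upsampling_halves_frequency_peak(self):
        base = stripe_patch(80, 0.2, 90.0, binary=False)
        up = np.kron(base, np.ones((2, 2)))
        spec = WindowSpec()
        p0 = psd_to_polar(windowed_psd(base, (40, 40), spec))
        p1 = psd_to_polar(windowed_psd(up, (80, 80), spec))
        q0 = p0.q_axis[np.argmax(marginals(p0).p_q)]
        q1 = p1.q_axis[np.argmax(marginals(p1).p_q)]
        dq = p0.q_axis[1] - p0.q_axis[0]
        assert q1 == pytest.approx(q0 / 2, abs=dq)
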