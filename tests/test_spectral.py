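"""Power spectrum, angular/radial profiles, alignment and decay fit."""

import math
from dataclasses import replace

import numpy as np
import pytest

from fibertex.spectral import (
    alignment_index,
    angular_profile,
    fit_radial_decay,
    power_spectrum,
    radial_profile,
)


class TestPowerSpectrum:
    def test_sinusoid_power_at_expected_radius(self):
        n = 64
        x = np.cos(2 * np.pi * np.arange(n) / 8.0)  # horizontal period 8 px
        img = np.tile(x, (n, 1))
        spec = power_spectrum(img, window="rect")
        cr, cc = spec.center
        S = spec.S.copy()
        S[cr, cc] = 0.0
        # the two conjugate peaks sit at radius n/8 on the column axis
        peaks = np.argsort(S.ravel())[-2:]
        for p in peaks:
            r, c = divmod(p, n)
            assert math.hypot(r - cr, c - cc) == pytest.approx(n / 8, abs=0.51)
        assert S[peaks[0] // n, peaks[0] % n] > 100 * np.median(S[S > 0])

    def test_white_noise_azimuthally_flat(self):
        profs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = power_spectrum(rng.normal(0, 1, (64, 64)))
            profs.append(angular_profile(spec, n_bins=12))
        mean_prof = np.mean(profs, axis=0)
        assert mean_prof.max() / mean_prof.min() < 1.5

    def test_point_symmetry_for_real_input(self, rng):
        spec = power_spectrum(rng.normal(0, 1, (64, 64)))
        S = spec.S
        flipped = S[::-1, ::-1]
        # DC-centered grid of even size: symmetry partner shifts by one
        assert np.allclose(S[1:, 1:], flipped[:-1, :-1], rtol=1e-6)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            power_spectrum(np.zeros((8, 16)))


def _delta_spectrum(n, r, theta):
    """Spectrum with one conjugate point pair at radius r, angle theta."""
    S = np.zeros((n, n))
    cr = cc = n // 2
    dr = int(round(r * math.sin(theta)))
    dc = int(round(r * math.cos(theta)))
    S[cr + dr, cc + dc] = 1.0
    S[cr - dr, cc - dc] = 1.0
    from fibertex.spectral import PowerSpectrum

    return PowerSpectrum(S=S, freq_per_px=1.0)


class TestAngularProfile:
    def test_point_pair_lands_in_one_bin(self):
        theta0 = 0.7
        spec = _delta_spectrum(64, 10, theta0)
        prof = angular_profile(spec, n_bins=36)
        assert prof.sum() == pytest.approx(2.0)
        occupied = np.nonzero(prof)[0]
        assert len(occupied) == 1

    def test_isotropic_ring_uniform(self):
        n = 128
        cr = cc = n // 2
        rows = np.arange(n)[:, None] - cr
        cols = np.arange(n)[None, :] - cc
        r = np.hypot(rows, cols)
        from fibertex.spectral import PowerSpectrum

        spec = PowerSpectrum(S=((r > 15) & (r < 25)).astype(float), freq_per_px=1.0)
        prof = angular_profile(spec, n_bins=12)
        assert prof.std() / prof.mean() < 0.1

    def test_matches_bruteforce_binning(self, rng):
        from fibertex.spectral import PowerSpectrum

        n = 32
        S = rng.random((n, n))
        spec = PowerSpectrum(S=S, freq_per_px=1.0)
        n_bins, r_min, r_max = 18, 2.0, 16.0
        prof = angular_profile(spec, n_bins=n_bins, r_min=r_min, r_max=r_max)
        ref = np.zeros(n_bins)
        for i in range(n):
            for j in range(n):
                dr, dc = i - n // 2, j - n // 2
                rad = math.hypot(dr, dc)
                if r_min <= rad <= r_max:
                    th = math.atan2(dr, dc) % math.pi
                    if np.isclose(th, math.pi):
                        th = 0.0
                    ref[min(int(th / math.pi * n_bins), n_bins - 1)] += S[i, j]
        assert np.allclose(prof, ref, atol=1e-12)

    def test_power_conservation_over_annulus(self, rng):
        from fibertex.spectral import PowerSpectrum

        S = rng.random((64, 64))
        spec = PowerSpectrum(S=S, freq_per_px=1.0)
        prof = angular_profile(spec, n_bins=90, r_min=2, r_max=30)
        cr = cc = 32
        rows = np.arange(64)[:, None] - cr
        cols = np.arange(64)[None, :] - cc
        r = np.hypot(rows, cols)
        assert prof.sum() == pytest.approx(S[(r >= 2) & (r <= 30)].sum(), abs=1e-9)

    def test_empty_annulus_rejected(self):
        spec = _delta_spectrum(64, 10, 0.0)
        with pytest.raises(ValueError):
            angular_profile(spec, r_min=2.0, r_max=1.0)


class TestAlignmentIndex:
    def test_point_mass_fully_ordered(self):
        prof = np.zeros(90)
        prof[17] = 5.0
        assert alignment_index(prof) == pytest.approx(1.0)

    def test_uniform_fully_disordered(self):
        assert alignment_index(np.ones(90)) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_masses_cancel(self):
        # equal mass at theta and theta + pi/2: doubled phases are opposite
        prof = np.zeros(90)
        prof[10] = 3.0
        prof[55] = 3.0  # 45 bins later = pi/2
        assert alignment_index(prof) == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_profile_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(alignment_index(np.zeros(10)))

    def test_stripe_rotation_changes_alignment_slightly(self):
        from scipy.ndimage import rotate

        n = 96
        x = np.cos(2 * np.pi * np.arange(n) / 6.0)
        img = np.tile(x, (n, 1))
        big = np.tile(x, (2 * n, 2))[:2 * n, :2 * n]
        rot = rotate(big, 30.0, reshape=False, order=3)[n // 2 : n // 2 + n, n // 2 : n // 2 + n]

        def align(im):
            return alignment_index(angular_profile(power_spectrum(im), n_bins=90))

        assert abs(align(img) - align(rot)) < 0.05


class TestRadialProfile:
    def test_isotropic_gaussian_monotone(self):
        n = 64
        cr = cc = n // 2
        rows = np.arange(n)[:, None] - cr
        cols = np.arange(n)[None, :] - cc
        r2 = rows**2 + cols**2
        from fibertex.spectral import PowerSpectrum

        spec = PowerSpectrum(S=np.exp(-r2 / 50.0), freq_per_px=1.0)
        _, prof = radial_profile(spec, n_bins=16)
        assert np.all(np.diff(prof) < 0)

    def test_matches_bruteforce_binning(self, rng):
        from fibertex.spectral import PowerSpectrum

        n = 32
        S = rng.random((n, n))
        spec = PowerSpectrum(S=S, freq_per_px=1.0)
        n_bins = 15
        centers, prof = radial_profile(spec, n_bins=n_bins)
        edges = np.linspace(1.0, n // 2, n_bins + 1)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for i in range(n):
            for j in range(n):
                rad = math.hypot(i - n // 2, j - n // 2)
                if 1.0 <= rad <= n // 2:
                    k = min(int(np.digitize(rad, edges)) - 1, n_bins - 1)
                    if 0 <= k < n_bins:
                        sums[k] += S[i, j]
                        counts[k] += 1
        ref = sums[counts > 0] / counts[counts > 0]
        assert np.allclose(prof, ref, atol=1e-12)

    def test_ring_gives_single_dominant_bin(self):
        n = 128
        cr = cc = n // 2
        rows = np.arange(n)[:, None] - cr
        cols = np.arange(n)[None, :] - cc
        r = np.hypot(rows, cols)
        from fibertex.spectral import PowerSpectrum

        spec = PowerSpectrum(S=(np.abs(r - 20) < 1.2).astype(float), freq_per_px=1.0)
        _, prof = radial_profile(spec, n_bins=32)
        assert prof.max() > 10 * np.sort(prof)[-3]


class TestRadialDecayFit:
    def test_exact_model_recovery(self):
        r = np.arange(1.0, 41.0)
        profile = 100.0 * np.exp(-r / 5.0)
        a, tc, boundary = fit_radial_decay(r, profile, fit_range=(1.0, 40.0))
        assert a == pytest.approx(100.0, abs=1e-6)
        assert tc == pytest.approx(5.0, abs=1e-6)
        assert not boundary

    def test_constant_profile_hits_boundary(self):
        r = np.arange(1.0, 41.0)
        with pytest.warns(UserWarning, match="upper bound"):
            _, tc, boundary = fit_radial_decay(r, np.full(40, 7.0))
        assert boundary
        assert tc > 1000

    def test_thin_fibers_have_larger_time_constant(self):
        # thinner fibers put relatively more power at high spatial frequency
        from fibertex.synth import GeneratorParams, render_field

        wins = 0
        for seed in range(10):
            tcs = {}
            for w_px in (2.0, 8.0):
                p = GeneratorParams(
                    n_fibers=12, n_px=128, fov_um=128.0, width_mu=w_px,
                    width_sigma=0.05, length_mu=60.0, wiggle_sigma=0.1,
                    photon_budget_fwd=200.0, photon_budget_bwd=50.0,
                    background=2.0, seed=seed,
                )
                fwd, _, _ = render_field(p)
                spec = power_spectrum(fwd.pixels.astype(float))
                r, prof = radial_profile(spec)
                _, tc, _ = fit_radial_decay(r, prof)
                tcs[w_px] = tc
            wins += tcs[2.0] > tcs[8.0]
        assert wins >= 9

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_radial_decay(np.arange(1.0, 6.0), np.exp(-np.arange(1.0, 6.0)))
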