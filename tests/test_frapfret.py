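"""FRET estimators and FRAP diffusion + exchange decomposition tests."""

import numpy as np
import pytest

from slbkit.core import FretTrace, ImageSeries
from slbkit.frapfret import (extract_recovery_profile, fit_frap,
                             fret_efficiency_ap, fret_efficiency_spectral,
                             integrate_recovery, recovery_modes)
from slbkit.simgen import simulate_fret_trace, simulate_frap_profiles


def _trace(donor_pre, donor_post, n=20, bleach=10):
    donor = np.concatenate([np.full(bleach, float(donor_pre)),
                            np.full(n - bleach, float(donor_post))])
    acceptor = np.concatenate([np.full(bleach, 100.0),
                               np.full(n - bleach, 2.0)])
    return FretTrace(np.arange(n, dtype=float), donor, acceptor, bleach)


class TestFretAp:
    def test_donor_gain_80_to_100_gives_20_percent(self):
        assert fret_efficiency_ap(_trace(80, 100)) == pytest.approx(20.0)

    def test_unchanged_donor_gives_zero(self):
        assert fret_efficiency_ap(_trace(100, 100)) == pytest.approx(0.0)

    def test_generator_round_trip(self):
        tr = simulate_fret_trace(e_true=0.25, donor_pre_level=100.0,
                                 bleach_frame=20, n_frames=60,
                                 noise_sd=0.01, seed=2)
        assert fret_efficiency_ap(tr) == pytest.approx(25.0, abs=1.0)

    def test_unbleached_acceptor_refused(self):
        tr = _trace(80, 100)
        tr.acceptor[:] = 100.0
        with pytest.raises(ValueError, match="photobleach"):
            fret_efficiency_ap(tr)

    def test_literal_reading_available(self):
        # the printed-formula reading has a 50% baseline for no change
        assert fret_efficiency_ap(_trace(100, 100),
                                  literal=True) == pytest.approx(50.0)
        assert fret_efficiency_ap(_trace(80, 100),
                                  literal=True) == pytest.approx(
                                      100 * 100 / 180)


class TestFretSpectral:
    def test_symmetric_peaks_give_50(self):
        wl = np.arange(550.0, 701.0)
        inten = np.where((wl == 565) | (wl == 670), 200.0, 5.0)
        e = fret_efficiency_spectral(np.column_stack([wl, inten]))
        assert e == pytest.approx(50.0)

    def test_no_acceptor_emission_gives_zero(self):
        wl = np.arange(550.0, 701.0)
        inten = np.where(wl == 565, 300.0, 0.0)
        assert fret_efficiency_spectral(
            np.column_stack([wl, inten])) == pytest.approx(0.0)

    def test_fd_300_fa_100_gives_25(self):
        wl = np.arange(550.0, 701.0)
        inten = np.where(wl == 565, 300.0,
                         np.where(wl == 670, 100.0, 0.0))
        assert fret_efficiency_spectral(
            np.column_stack([wl, inten])) == pytest.approx(25.0)

    def test_missing_coverage_rejected(self):
        wl = np.arange(550.0, 600.0)
        with pytest.raises(ValueError, match="cover"):
            fret_efficiency_spectral(
                np.column_stack([wl, np.ones_like(wl)]))


class TestForwardModel:
    def test_fd_and_spectral_integrators_agree(self):
        # implicit finite differences vs exact cosine modes
        n = 120
        pos = (np.arange(n) + 0.5) * (12.0 / n)
        f0 = np.where((pos > 4) & (pos < 7), 0.2, 1.0)
        times = np.array([0.0, 2.0, 5.0, 10.0, 20.0])
        fd = integrate_recovery(f0, pos, times, 0.1, 0.05)
        sp = recovery_modes(f0, 12.0, times, 0.1, 0.05)
        assert np.max(np.abs(fd - sp)) < 5e-3

    def test_mass_conserved_without_exchange(self):
        n = 100
        pos = (np.arange(n) + 0.5) * 0.1
        f0 = np.where((pos > 3) & (pos < 6), 0.1, 1.0)
        out = integrate_recovery(f0, pos, np.linspace(0, 50, 6), 0.2, 0.0)
        deficit = (1.0 - out).sum(axis=1)
        np.testing.assert_allclose(deficit, deficit[0], rtol=1e-6)

    def test_free_diffusion_variance_grows_as_2dt(self):
        # narrow Gaussian bleach far from boundaries: the deficit spreads
        # with variance sigma^2 + 2 D t (heat kernel)
        n, L = 400, 40.0
        pos = (np.arange(n) + 0.5) * (L / n)
        sigma0 = 0.5
        f0 = 1.0 - 0.8 * np.exp(-(pos - L / 2) ** 2 / (2 * sigma0 ** 2))
        d = 0.2
        times = np.array([0.0, 5.0, 10.0, 20.0])
        out = recovery_modes(f0, L, times, d, 0.0)
        for t, prof in zip(times[1:], out[1:]):
            deficit = 1.0 - prof
            w = deficit / deficit.sum()
            mu = (pos * w).sum()
            var = ((pos - mu) ** 2 * w).sum()
            assert var == pytest.approx(sigma0 ** 2 + 2 * d * t, rel=0.05)


class TestExtractProfile:
    def test_uniform_movie_flat_profile(self):
        frames = np.full((6, 20, 30), 50.0)
        series = ImageSeries(frames, 0.1, 1.0)
        prof = extract_recovery_profile(series, (5, 5, 10, 8),
                                        n_prebleach=2)
        np.testing.assert_allclose(prof.intensities, 1.0)

    def test_round_trip_from_rendered_profiles(self):
        truth = simulate_frap_profiles(
            d_coeff=0.1, k_off=0.05, domain_length=20.0,
            bleach_window=(7.5, 12.5), bleach_depth=0.85,
            times=np.arange(0.0, 30.0, 2.0), n_positions=200)
        # render to a movie: replicate the profile across rows, prepend a
        # pre-bleach (all-ones) frame, scale to counts
        stack = np.repeat(truth.intensities[:, None, :], 16, axis=1) * 400
        pre = np.full((1, 16, 200), 400.0)
        series = ImageSeries(np.concatenate([pre, stack]),
                             pixel_size=0.1, frame_interval=2.0)
        prof = extract_recovery_profile(series, (75, 2, 50, 12),
                                        n_prebleach=1)
        rms = np.sqrt(np.mean((prof.intensities - truth.intensities) ** 2))
        assert rms <= 0.02

    def test_mirror_on_symmetric_profile_is_identity(self):
        x = np.arange(100) * 0.1
        prof_row = 1.0 - 0.8 * np.exp(-(x - 5.0) ** 2 / 2.0)
        frames = np.concatenate([
            np.full((1, 10, 100), 100.0),
            np.repeat((prof_row * 100)[None, None, :], 10, axis=1)
        ])
        series = ImageSeries(frames, 0.1, 1.0)
        a = extract_recovery_profile(series, (40, 2, 20, 6), n_prebleach=1)
        b = extract_recovery_profile(series, (40, 2, 20, 6), n_prebleach=1,
                                     mirror=True)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=5e-3)

    def test_roi_outside_image_rejected(self):
        series = ImageSeries(np.ones((3, 10, 10)), 0.1, 1.0)
        with pytest.raises(ValueError):
            extract_recovery_profile(series, (8, 8, 5, 5))


class TestFitFrap:
    def test_pure_exchange_limit(self):
        times = np.arange(0.0, 16.0, 1.0)
        prof = simulate_frap_profiles(
            d_coeff=0.0, k_off=0.37, domain_length=20.0,
            bleach_window=(7.5, 12.5), bleach_depth=0.9, times=times)
        fit = fit_frap(prof)
        assert fit.params["k_off"] == pytest.approx(0.37, rel=0.01)
        assert fit.params["D_coeff"] < 1e-4

    def test_both_parameters_recovered_at_2_percent_noise(self):
        times = np.arange(0.0, 61.0, 2.0)
        prof = simulate_frap_profiles(
            d_coeff=0.14, k_off=0.04, domain_length=20.0,
            bleach_window=(7.5, 12.5), bleach_depth=0.9, times=times,
            noise_sd=0.02, seed=5)
        fit = fit_frap(prof)
        assert fit.params["D_coeff"] == pytest.approx(0.14, rel=0.15)
        assert fit.params["k_off"] == pytest.approx(0.04, rel=0.15)

    def test_identifiability_pure_exchange_d_ci_includes_zero(self):
        times = np.arange(0.0, 31.0, 2.0)
        prof = simulate_frap_profiles(
            d_coeff=0.0, k_off=0.1, domain_length=20.0,
            bleach_window=(7.5, 12.5), bleach_depth=0.9, times=times,
            noise_sd=0.01, seed=3)
        fit = fit_frap(prof)
        d, sd = fit.params["D_coeff"], fit.stderr["D_coeff"]
        assert d - 1.96 * sd <= 0.0

    def test_flat_profile_rejected(self):
        from slbkit.core import RecoveryProfile
        pos = (np.arange(100) + 0.5) * 0.1
        prof = RecoveryProfile(pos, np.arange(8.0),
                               np.ones((8, 100)), (3.0, 6.0))
        with pytest.raises(ValueError, match="not bleached"):
            fit_frap(prof)

    def test_diffusion_dominated_profile(self):
        times = np.arange(0.0, 41.0, 2.0)
        prof = simulate_frap_profiles(
            d_coeff=0.2, k_off=0.0, domain_length=20.0,
            bleach_window=(8.0, 12.0), bleach_depth=0.9, times=times)
        fit = fit_frap(prof)
        assert fit.params["D_coeff"] == pytest.approx(0.2, rel=0.05)
        assert fit.params["k_off"] < 0.005
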