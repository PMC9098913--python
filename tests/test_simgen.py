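"""Tests of the synthetic-data generators: seed determinism, the statistical
structure each generator promises, and their documented degenerate cases."""

import numpy as np
import pytest
from scipy import stats

from slbkit import simgen
from slbkit.simgen import (DiskZone, DwellSimConfig, FilamentMovieConfig,
                           NoiseModel, TwoStateSimConfig,
                           simulate_dwell_tracks, simulate_filament_movie,
                           simulate_two_state_tracks)


class TestTwoStateTracks:
    def test_seed_determinism(self):
        cfg = TwoStateSimConfig(n_molecules=10, n_frames=50, seed=42)
        t1, e1 = simulate_two_state_tracks(cfg)
        t2, e2 = simulate_two_state_tracks(cfg)
        assert e1 == e2
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.x, b.x)
            np.testing.assert_array_equal(a.y, b.y)

    def test_no_trapping_when_binding_off(self):
        cfg = TwoStateSimConfig(d_free=0.2, d_trapped=0.2, k_bind=0.0,
                                n_molecules=20, n_frames=200, seed=1,
                                localization_noise_sd=0.0)
        tracks, events = simulate_two_state_tracks(cfg)
        assert events == []
        # per-axis displacement variance = 2 D dt (reflections negligible
        # over one step in a 10 um FOV)
        dx = np.concatenate([np.diff(t.x) for t in tracks])
        var = dx.var()
        assert var == pytest.approx(2 * 0.2 * cfg.frame_interval, rel=0.05)

    def test_free_step_variance_within_5_percent(self):
        cfg = TwoStateSimConfig(k_bind=0.0, n_molecules=30, n_frames=400,
                                localization_noise_sd=0.0, seed=7)
        tracks, _ = simulate_two_state_tracks(cfg)
        steps = np.concatenate([np.diff(t.x) for t in tracks] +
                               [np.diff(t.y) for t in tracks])
        assert steps.size >= 10_000
        assert steps.var() == pytest.approx(
            2 * cfg.d_free * cfg.frame_interval, rel=0.05)

    def test_event_durations_exponential_with_mean_1_over_k_unbind(self):
        k_unbind = 1.5
        cfg = TwoStateSimConfig(k_bind=0.5, k_unbind=k_unbind,
                                n_molecules=250, n_frames=1500, seed=3)
        _, events = simulate_two_state_tracks(cfg)
        horizon = cfg.n_frames * cfg.frame_interval
        durations = np.array([e.duration for e in events
                              if e.end_time < horizon])
        assert durations.size >= 1000
        assert durations.mean() == pytest.approx(1.0 / k_unbind, rel=0.1)
        # discrete-time (geometric) durations: compare against the matching
        # geometric law via KS on the frame counts
        dt = cfg.frame_interval
        frames = np.round(durations / dt).astype(int)
        q = 1.0 - np.exp(-k_unbind * dt)
        ref = stats.geom(q).rvs(size=len(frames) * 4,
                                random_state=np.random.RandomState(0))
        res = stats.ks_2samp(frames, ref)
        assert res.pvalue > 0.01

    def test_trapped_molecules_stay_near_anchor(self):
        cfg = TwoStateSimConfig(k_bind=2.0, k_unbind=0.2, n_molecules=40,
                                n_frames=400, localization_noise_sd=0.0,
                                seed=5)
        tracks, events = simulate_two_state_tracks(cfg)
        assert events
        dt = cfg.frame_interval
        for e in events[:50]:
            t = tracks[e.track_id]
            sel = (t.times >= e.start_time) & (t.times <= e.end_time)
            x, y = t.x[sel], t.y[sel]
            spread = np.hypot(x - x.mean(), y - y.mean()).max()
            assert spread <= 2 * cfg.trap_radius + 1e-9

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="d_trapped"):
            TwoStateSimConfig(d_trapped=-1.0)
        with pytest.raises(ValueError, match="crossing_probability"):
            TwoStateSimConfig(crossing_probability=1.5)
        with pytest.raises(ValueError):
            TwoStateSimConfig(d_free=0.1, d_trapped=0.2)

    def test_disk_zones_supported(self):
        zones = [DiskZone(5.0, 5.0, 1.0)]
        cfg = TwoStateSimConfig(trap_zones=zones, k_bind=5.0, k_unbind=0.5,
                                n_molecules=30, n_frames=300, seed=9)
        _, events = simulate_two_state_tracks(cfg)
        assert events and all(e.zone_id == 0 for e in events)


class TestDwellSim:
    def test_no_bleaching_mean_dwell_is_inverse_k_off(self):
        cfg = DwellSimConfig(k_off_true=0.05, bleach_rate=0.0,
                             lapse_intervals=(0.5, 1.0),
                             n_molecules_per_interval=20_000, seed=2)
        data = simulate_dwell_tracks(cfg)
        for tau, d in data.items():
            # discrete mean: tau / (1 - exp(-k tau)) ~ 1/k + tau/2
            expect = tau / (1 - np.exp(-0.05 * tau))
            assert d.mean() == pytest.approx(expect, rel=0.03)

    def test_apparent_rate_closed_form_at_1s(self):
        # k_off 0.05/s with bleach number 0.2 -> apparent rate 0.25/s at
        # a 1 s lapse interval (k_eff = k_off + k_b tau_int / tau_tl)
        cfg = DwellSimConfig(k_off_true=0.05, bleach_rate=4.0,
                             integration_time=0.05,
                             lapse_intervals=(0.125, 0.25, 0.5, 1.0, 2.0),
                             n_molecules_per_interval=50_000, seed=4)
        data = simulate_dwell_tracks(cfg)
        frames = np.round(data[1.0] / 1.0)
        x = -np.log1p(-1.0 / frames.mean())  # per-frame exponent
        assert x == pytest.approx(0.25, rel=0.03)

    def test_empty_and_invalid(self):
        cfg = DwellSimConfig(n_molecules_per_interval=0)
        assert all(len(v) == 0 for v in simulate_dwell_tracks(cfg).values())
        with pytest.raises(ValueError):
            DwellSimConfig(lapse_intervals=())
        with pytest.raises(ValueError):
            DwellSimConfig(lapse_intervals=(0.01,), integration_time=0.05)

    def test_determinism(self):
        cfg = DwellSimConfig(seed=11, n_molecules_per_interval=100)
        a = simulate_dwell_tracks(cfg)
        b = simulate_dwell_tracks(cfg)
        for tau in a:
            np.testing.assert_array_equal(a[tau], b[tau])


class TestFilamentMovie:
    def test_full_coupling_correlates_perfectly_without_noise(self):
        cfg = FilamentMovieConfig(channel2_coupling=1.0, seed=1, n_frames=3)
        a, b = simulate_filament_movie(cfg)
        for fa, fb in zip(a.frames, b.frames):
            r = np.corrcoef(fa.ravel(), fb.ravel())[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_coupling_uncorrelated(self):
        cfg = FilamentMovieConfig(
            channel2_coupling=0.0, seed=1, n_frames=3,
            noise_model=NoiseModel(read_noise_sd=0.05))
        a, b = simulate_filament_movie(cfg)
        r = np.corrcoef(a.frames[0].ravel(), b.frames[0].ravel())[0, 1]
        assert abs(r) < 0.05

    def test_static_movie_when_speed_zero(self):
        cfg = FilamentMovieConfig(treadmill_speed=0.0, seed=2, n_frames=4)
        a, _ = simulate_filament_movie(cfg)
        np.testing.assert_allclose(a.frames[0], a.frames[-1], atol=1e-12)

    def test_frame_count_validated(self):
        with pytest.raises(ValueError):
            FilamentMovieConfig(n_frames=1)


class TestFrapAndTraceGenerators:
    def test_pure_exchange_profiles_follow_exponential(self):
        times = np.arange(0.0, 10.0, 1.0)
        prof = simgen.simulate_frap_profiles(
            d_coeff=0.0, k_off=0.1, domain_length=10.0,
            bleach_window=(4.0, 6.0), bleach_depth=0.8, times=times)
        depth = 1.0 - prof.intensities[0]
        for i, t in enumerate(times):
            np.testing.assert_allclose(
                prof.intensities[i], 1.0 - depth * np.exp(-0.1 * t),
                atol=2e-3)

    def test_conservation_without_exchange(self):
        times = np.linspace(0.0, 30.0, 7)
        prof = simgen.simulate_frap_profiles(
            d_coeff=0.1, k_off=0.0, domain_length=10.0,
            bleach_window=(4.0, 6.0), bleach_depth=0.9, times=times)
        means = prof.intensities.mean(axis=1)
        np.testing.assert_allclose(means, means[0], rtol=1e-6)

    def test_frap_input_validation(self):
        with pytest.raises(ValueError):
            simgen.simulate_frap_profiles(0.1, 0.1, -1.0, (0.2, 0.5), 0.5,
                                          [0.0, 1.0])
        with pytest.raises(ValueError):
            simgen.simulate_frap_profiles(0.1, 0.1, 1.0, (0.5, 2.0), 0.5,
                                          [0.0, 1.0])

    def test_fret_trace_levels(self):
        tr = simgen.simulate_fret_trace(e_true=0.2, donor_pre_level=80.0,
                                        bleach_frame=5, n_frames=10)
        assert tr.donor[4] == pytest.approx(80.0)
        assert tr.donor[5] == pytest.approx(100.0)  # 80 / (1 - 0.2)
        flat = simgen.simulate_fret_trace(0.0, 80.0, 5, 10)
        np.testing.assert_allclose(flat.donor, 80.0)
        with pytest.raises(ValueError):
            simgen.simulate_fret_trace(1.0, 80.0, 5, 10)

    def test_binding_curve_half_max(self):
        series = simgen.simulate_binding_curve(
            "hill_qcmd", {"S": 0.0, "E": -30.0, "n": 1.0, "k": 0.21},
            np.array([0.05, 0.21, 1.0, 3.0]))
        # at c = k the response is halfway between S and E
        assert series.responses[1] == pytest.approx(-15.0)
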