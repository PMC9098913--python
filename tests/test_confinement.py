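"""Packing-coefficient and confinement-event detection tests, including the
brute-force oracle comparison and the simulation-validated detector
benchmarks."""

import numpy as np
import pytest

from conftest import brownian_track
from slbkit.confinement import (confinement_stats, default_window,
                                detect_confinement, detect_events,
                                filter_tracks, min_run_frames,
                                packing_coefficient, validate_against_truth)
from slbkit.core import ConfinementEvent, Track
from slbkit.simgen import TwoStateSimConfig, simulate_two_state_tracks
from slbkit.tracks_io import read_tracks, write_tracks


def oracle_packing(track, window_n):
    """Independent brute-force evaluation: shapely hull + explicit loop."""
    from shapely.geometry import MultiPoint

    x, y = track.x, track.y
    out = []
    for i in range(len(track) - window_n):
        if np.any(np.diff(track.frames[i:i + window_n + 1]) != 1):
            out.append(np.nan)
            continue
        s = 0.0
        for j in range(i, i + window_n):
            s += (x[j + 1] - x[j]) ** 2 + (y[j + 1] - y[j]) ** 2
        pts = MultiPoint(list(zip(x[i:i + window_n + 1],
                                  y[i:i + window_n + 1])))
        area = pts.convex_hull.area
        out.append(np.inf if area < 1e-12 else s / area ** 2)
    return np.array(out)


class TestPackingCoefficient:
    def test_square_path_hand_value(self):
        # 0.1 um square: four 0.1 um steps (sum sq 0.04 um^2), hull area
        # 0.01 um^2 -> p = 0.04 / 0.0001 = 400 um^-2
        t = Track(0, np.arange(5), [0, 0.1, 0.1, 0.0, 0.0],
                  [0, 0.0, 0.1, 0.1, 0.0], 0.05)
        prof = packing_coefficient(t, 4)
        assert prof.p_values == pytest.approx([400.0])

    def test_collinear_window_degenerate(self):
        t = Track(0, np.arange(5), np.linspace(0, 0.4, 5), np.zeros(5), 0.05)
        prof = packing_coefficient(t, 4)
        assert np.isinf(prof.p_values[0])

    def test_scaling_inverse_square(self, rng):
        t = brownian_track(0, 30, 0.1, 0.05, rng)
        t2 = Track(0, t.frames, 2 * t.x, 2 * t.y, t.frame_interval)
        p1 = packing_coefficient(t, 5).p_values
        p2 = packing_coefficient(t2, 5).p_values
        np.testing.assert_allclose(p2, p1 / 4.0, rtol=1e-12)

    def test_matches_bruteforce_oracle_on_random_tracks(self, rng):
        for i in range(100):
            n = int(rng.integers(10, 40))
            t = brownian_track(i, n, 0.2, 0.051, rng)
            window = int(rng.integers(3, 9))
            p = packing_coefficient(t, window).p_values
            expected = oracle_packing(t, window)
            np.testing.assert_allclose(p, expected, rtol=1e-10)

    def test_windows_spanning_gaps_are_nan(self):
        frames = np.array([0, 1, 2, 3, 5, 6, 7, 8, 9])
        t = Track(0, frames, np.random.default_rng(0).normal(0, 0.1, 9),
                  np.random.default_rng(1).normal(0, 0.1, 9), 0.05)
        p = packing_coefficient(t, 4).p_values
        # the gap is the step from index 3 to 4; windows 0..3 span it
        assert np.all(np.isnan(p[:4]))
        assert not np.isnan(p[4])

    def test_window_too_small_rejected(self, rng):
        t = brownian_track(0, 20, 0.2, 0.05, rng)
        with pytest.raises(ValueError):
            packing_coefficient(t, 2)

    def test_nonnegative(self, rng):
        t = brownian_track(0, 200, 0.2, 0.051, rng)
        p = packing_coefficient(t, 5).p_values
        assert np.all(p[np.isfinite(p)] >= 0)


class TestThresholds:
    def test_frame_conversion_at_51_and_32_ms(self):
        # 0.25 s minimum duration corresponds to five frames at 51 ms and
        # eight frames at 32 ms acquisition
        assert min_run_frames(0.25, 0.051) == 5
        assert min_run_frames(0.25, 0.032) == 8

    def test_default_window_tracks_min_run(self):
        assert default_window(0.25, 0.051) == 5
        assert default_window(0.25, 0.032) == 8


class TestDetection:
    def test_profile_below_threshold_no_events(self, rng):
        t = brownian_track(0, 50, 0.2, 0.051, rng)
        prof = packing_coefficient(t, 5)
        prof.p_values[:] = 10.0
        assert detect_confinement(prof, 1000.0, 0.25) == []

    def test_synthetic_high_p_run_detected(self):
        t = brownian_track(0, 60, 0.2, 0.051, np.random.default_rng(3))
        prof = packing_coefficient(t, 5)
        prof.p_values[:] = 10.0
        prof.p_values[20:35] = 5000.0
        events = detect_confinement(prof, 1000.0, 0.25)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration >= 0.25
        assert ev.mean_p >= 1000.0

    def test_false_event_rate_on_pure_brownian_below_5_percent(self, rng):
        # thresholds must suppress apparent confinement of plain diffusion
        n_tracks = 200
        hits = sum(
            bool(detect_events(brownian_track(i, 100, 0.2, 0.051, rng),
                               p_thresh=1000.0, t_thresh=0.25))
            for i in range(n_tracks))
        assert hits / n_tracks < 0.05


class TestFilterTracks:
    def test_short_and_still_tracks_removed(self, rng):
        short = brownian_track(0, 10, 0.2, 0.05, rng)  # 0.5 s
        ok = brownian_track(1, 40, 0.2, 0.05, rng)  # 2 s
        still = Track(2, np.arange(40), np.zeros(40), np.zeros(40), 0.05)
        kept = filter_tracks([short, ok, still], min_duration=1.0)
        assert [t.track_id for t in kept] == [1, 2]
        kept = filter_tracks([short, ok, still], min_duration=1.0,
                             min_net_displacement=0.05)
        assert [t.track_id for t in kept] == [1]

    def test_identity_with_zero_thresholds(self, rng):
        tracks = [brownian_track(i, 5, 0.2, 0.05, rng) for i in range(3)]
        assert filter_tracks(tracks, 0.0, 0.0) == tracks


class TestStats:
    def test_tau_recovered_from_exponential_durations(self, rng):
        durations = rng.exponential(0.35, 1000) + 0.25
        events = [ConfinementEvent(i, 0.0, d, (0, 0), 2000.0)
                  for i, d in enumerate(durations)]
        tracks = [brownian_track(i, 10, 0.2, 0.05, rng) for i in range(20)]
        st = confinement_stats(events, tracks, bin_width=0.1)
        # shifted exponential keeps the decay constant tau = 0.35 s
        assert st.mean_confinement_time == pytest.approx(0.35, abs=0.05)

    def test_few_events_flagged_fraction_still_reported(self, rng):
        tracks = [brownian_track(i, 10, 0.2, 0.05, rng) for i in range(4)]
        events = [ConfinementEvent(0, 0.0, 0.5, (0, 0), 2000.0)]
        st = confinement_stats(events, tracks)
        assert st.mean_confinement_time is None
        assert st.confined_fraction == pytest.approx(25.0)

    def test_all_tracks_confined_gives_100_percent(self, rng):
        tracks = [brownian_track(i, 10, 0.2, 0.05, rng) for i in range(3)]
        events = [ConfinementEvent(i, 0.0, 0.5, (0, 0), 2000.0)
                  for i in range(3)] * 4
        st = confinement_stats(events, tracks)
        assert st.confined_fraction == pytest.approx(100.0)


class TestValidation:
    def test_perfect_detection_scores_perfectly(self):
        events = [ConfinementEvent(0, 1.0, 2.0, (0, 0), 2000.0),
                  ConfinementEvent(1, 0.5, 1.25, (0, 0), 2000.0)]
        m = validate_against_truth(events, events)
        assert m.duration_error == 0.0
        assert m.recall == 1.0 and m.precision == 1.0

    def test_disjoint_track_ids_error(self):
        det = [ConfinementEvent(0, 1.0, 2.0, (0, 0), 2000.0)]
        tru = [ConfinementEvent(5, 1.0, 2.0, (0, 0), 2000.0)]
        with pytest.raises(ValueError):
            validate_against_truth(det, tru)


class TestDetectorBenchmark:
    """Simulation validation of the detector on the stated parameter grid."""

    @pytest.mark.parametrize("d_trapped,bound", [(0.002, 0.04),
                                                 (0.008, 0.10)])
    def test_duration_error_within_stated_bounds(self, d_trapped, bound):
        pairs = []
        for kb in (0.1, 0.5):
            for ku in (0.5, 3.0):
                cfg = TwoStateSimConfig(
                    d_trapped=d_trapped, k_bind=kb, k_unbind=ku,
                    n_frames=800, seed=int(kb * 10) * 7 + int(ku * 10))
                tracks, truth = simulate_two_state_tracks(cfg)
                detected = []
                for t in tracks:
                    detected.extend(detect_events(t))
                horizon = cfg.n_frames * cfg.frame_interval
                m = validate_against_truth(detected, truth,
                                           exclude_boundary=(0.0, horizon))
                pairs.append(m)
        n = sum(m.n_matched for m in pairs)
        assert n > 150
        pooled = sum(m.duration_error * m.n_matched for m in pairs) / n
        assert pooled <= bound

    def test_duration_error_nondecreasing_in_trapped_diffusivity(self):
        errs = []
        for d_trapped in (0.002, 0.005, 0.008):
            cfg = TwoStateSimConfig(d_trapped=d_trapped, k_bind=0.4,
                                    k_unbind=1.5, n_frames=800, seed=21)
            tracks, truth = simulate_two_state_tracks(cfg)
            detected = []
            for t in tracks:
                detected.extend(detect_events(t))
            horizon = cfg.n_frames * cfg.frame_interval
            m = validate_against_truth(detected, truth,
                                       exclude_boundary=(0.0, horizon))
            errs.append(m.duration_mae_matched)
        # per-event duration error degrades (weakly) with faster trapped
        # diffusion; allow small sampling slack on the ordering
        assert errs[0] <= errs[2] + 0.01


class TestTrackRoundTrip:
    def test_csv_round_trip(self, rng, tmp_path):
        tracks = [brownian_track(i, int(rng.integers(5, 15)), 0.2, 0.051,
                                 rng) for i in range(3)]
        path = tmp_path / "tracks.csv"
        write_tracks(tracks, path)
        back = read_tracks(path)
        assert len(back) == 3
        for a, b in zip(tracks, back):
            assert a.track_id == b.track_id
            np.testing.assert_array_equal(a.frames, b.frames)
            np.testing.assert_allclose(a.x, b.x, rtol=0, atol=0)
            assert b.frame_interval == pytest.approx(0.051)

    def test_xml_round_trip_preserves_gaps(self, tmp_path):
        frames = np.array([0, 1, 2, 4, 5, 6, 7])
        rng = np.random.default_rng(0)
        t = Track(0, frames, rng.normal(0, 1, 7), rng.normal(0, 1, 7), 0.05)
        path = tmp_path / "tracks.xml"
        write_tracks([t], path)
        back = read_tracks(path)
        np.testing.assert_array_equal(back[0].frames, frames)
        np.testing.assert_allclose(back[0].x, t.x)

    def test_csv_lengths_preserved(self, rng, tmp_path):
        lengths = [5, 8, 2]
        tracks = [brownian_track(i, n - 1, 0.2, 0.05, rng)
                  for i, n in enumerate(lengths)]
        path = tmp_path / "t.csv"
        write_tracks(tracks, path)
        assert [len(t) for t in read_tracks(path)] == lengths

    def test_missing_calibration_is_explicit_error(self, tmp_path):
        path = tmp_path / "bare.xml"
        path.write_text('<?xml version="1.0"?><Tracks nTracks="0"></Tracks>')
        with pytest.raises(ValueError, match="frameInterval"):
            read_tracks(path)

    def test_malformed_xml_reports_parse_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<Tracks><particle></Tracks>")
        with pytest.raises(ValueError, match="malformed"):
            read_tracks(path)
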