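"""Elongation-rate estimation, pause detection and nucleation counting."""

import numpy as np
import pytest

from plusend import (
    ConfigurationError,
    FilamentTrack,
    InsufficientDataError,
    SimConfig,
    count_nucleation,
    detect_pauses,
    estimate_elongation_rate,
    min_resolvable_pause,
    simulate_filament_population,
)
from conftest import make_track


class TestElongationRate:
    def test_exact_line_gives_rate_37(self, linear_track):
        est = estimate_elongation_rate(linear_track, actin_conc=1.0)
        assert est.slope == pytest.approx(0.1, abs=1e-12)
        assert est.rate == pytest.approx(37.0, abs=1e-9)
        assert est.fit_r2 == pytest.approx(1.0)
        assert est.n_points == 5

    def test_flat_track_zero_rate(self):
        est = estimate_elongation_rate(make_track([1.0] * 6), actin_conc=1.0)
        assert est.slope == pytest.approx(0.0, abs=1e-12)
        assert est.rate == pytest.approx(0.0, abs=1e-9)

    def test_rate_conversion_is_linear_in_length(self, linear_track):
        doubled = FilamentTrack(
            filament_id=1, fov_id=0,
            times=linear_track.times, lengths=2 * linear_track.lengths,
        )
        e1 = estimate_elongation_rate(linear_track, 1.0)
        e2 = estimate_elongation_rate(doubled, 1.0)
        assert e2.slope == pytest.approx(2 * e1.slope)
        assert e2.rate == pytest.approx(2 * e1.rate)

    def test_requires_four_samples_and_positive_conc(self, linear_track):
        with pytest.raises(InsufficientDataError):
            estimate_elongation_rate(make_track([0.0, 0.1, 0.2]), 1.0)
        with pytest.raises(ConfigurationError):
            estimate_elongation_rate(linear_track, 0.0)

    def test_noise_free_simulation_recovers_free_end_rate(self, quiet_config):
        tracks, _ = simulate_filament_population(quiet_config, 20)
        rates = [estimate_elongation_rate(tr, 1.0).rate for tr in tracks]
        np.testing.assert_allclose(rates, 10.2, atol=0.01)
        assert all(
            estimate_elongation_rate(tr, 1.0).fit_r2 == pytest.approx(1.0)
            for tr in tracks
        )


class TestPauseDetection:
    def test_three_stalled_increments_mid_movie_is_one_15s_pause(self):
        # grows 0.15 um/frame, stalls frames 4..7, grows again
        lengths = [0.0, 0.15, 0.3, 0.45, 0.45, 0.45, 0.45, 0.6, 0.75, 0.9]
        events = detect_pauses(make_track(lengths), stall_epsilon=0.1)
        assert len(events) == 1
        ev = events[0]
        assert ev.duration == pytest.approx(15.0)
        assert ev.start == pytest.approx(15.0)
        assert ev.end == pytest.approx(30.0)
        assert not ev.truncated_by_movie_end

    def test_strictly_linear_track_has_no_pauses(self, linear_track):
        assert detect_pauses(linear_track) == []

    def test_two_stalls_split_by_growth_are_distinct(self):
        lengths = [0.0, 0.0, 0.0, 0.0, 0.2, 0.2, 0.2, 0.2, 0.4]
        events = detect_pauses(make_track(lengths), stall_epsilon=0.1)
        assert len(events) == 2

    def test_run_reaching_final_frame_is_flagged_truncated(self):
        lengths = [0.0, 0.15, 0.3, 0.3, 0.3, 0.3]
        (ev,) = detect_pauses(make_track(lengths), stall_epsilon=0.1)
        assert ev.truncated_by_movie_end

    def test_no_event_shorter_than_min_frames_and_no_overlap(self):
        cfg = SimConfig(seed=9, length_noise_sd=0.02)
        tracks, _ = simulate_filament_population(cfg, 50)
        for tr in tracks:
            evs = detect_pauses(tr, 0.1, 3)
            for ev in evs:
                assert ev.duration >= 3 * cfg.frame_interval
            for a, b in zip(evs[:-1], evs[1:]):
                assert a.end <= b.start

    def test_detection_independent_of_track_order(self):
        cfg = SimConfig(seed=10, length_noise_sd=0.02)
        tracks, _ = simulate_filament_population(cfg, 20)
        fwd = [detect_pauses(tr) for tr in tracks]
        rev = [detect_pauses(tr) for tr in reversed(tracks)]
        assert fwd == rev[::-1]

    def test_recall_of_ground_truth_pauses_at_low_noise(self):
        cfg = SimConfig(seed=12, length_noise_sd=0.02)
        tracks, events = simulate_filament_population(cfg, 300)
        detected = {tr.filament_id: detect_pauses(tr, 0.1, 3) for tr in tracks}
        truth = [
            e for e in events
            if e.state == "iqgap1_paused"
            and e.duration >= 15.0
            and e.end < cfg.movie_duration
            and e.start > tracks[e.filament_id].times[0]
        ]
        assert len(truth) > 100
        hits = sum(
            any(d.start < e.end and d.end > e.start for d in detected[e.filament_id])
            for e in truth
        )
        assert hits / len(truth) >= 0.95

    def test_growth_phase_rate_recovers_free_rate_whole_track_is_lower(self):
        cfg = SimConfig(seed=13, length_noise_sd=0.02)
        tracks, _ = simulate_filament_population(cfg, 500, nucleation="start")
        growth, whole = [], []
        for tr in tracks:
            whole.append(estimate_elongation_rate(tr, 1.0).rate)
            try:
                growth.append(
                    estimate_elongation_rate(tr, 1.0, exclude_pauses=True).rate
                )
            except InsufficientDataError:
                continue
        assert np.mean(growth) == pytest.approx(10.2, rel=0.02)
        assert np.mean(whole) < np.mean(growth)


@pytest.mark.parametrize(
    "dt, frames, expected", [(5.0, 3, 15.0), (1.0, 2, 2.0), (3.2, 3, 9.6)]
)
def test_min_resolvable_pause_is_the_product(dt, frames, expected):
    assert min_resolvable_pause(dt, frames) == pytest.approx(expected)


class TestNucleationCount:
    def test_all_present_from_start(self):
        tracks = [make_track(np.linspace(0, 1, 50), filament_id=i) for i in range(3)]
        assert count_nucleation(tracks, 200.0) == {0: 3}

    def test_only_filaments_nucleated_by_query_time_count(self):
        tracks = []
        for i, t0 in enumerate([50.0, 150.0, 250.0]):
            times = np.arange(t0, 300.0, 5.0)
            lengths = 0.03 * (times - t0)
            tracks.append(
                FilamentTrack(filament_id=i, fov_id=0, times=times, lengths=lengths)
            )
        assert count_nucleation(tracks, 200.0) == {0: 2}

    def test_uniform_appearance_gives_proportional_count_at_200s(self):
        cfg = SimConfig(seed=14, length_noise_sd=0.0)
        tracks, _ = simulate_filament_population(cfg, 300)
        count = count_nucleation(tracks, 200.0)[0]
        # nucleation uniform over [0, movie_duration - 3 dt] = [0, 585]
        expected = 300 * 200.0 / 585.0
        assert abs(count - expected) < 4 * np.sqrt(expected)

    def test_counts_grouped_by_fov(self):
        tracks = [
            make_track(np.linspace(0, 1, 50), filament_id=i, fov_id=i % 2)
            for i in range(5)
        ]
        assert count_nucleation(tracks, 100.0) == {0: 3, 1: 2}
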