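"""Generator correctness: deterministic limits, calibration recovery, seeding."""

import numpy as np
import pytest

from plusend import (
    ConfigurationError,
    SimConfig,
    SUBUNITS_PER_MICRON,
    intensity_skewness,
    simulate_bundle_field,
    simulate_dwell_events,
    simulate_filament_population,
    simulate_photobleach_traces,
    simulate_spot_sets,
)


class TestFilamentPopulation:
    def test_no_transitions_no_noise_tracks_are_exactly_linear(self, quiet_config):
        tracks, _ = simulate_filament_population(quiet_config, 5)
        v = 10.2 * quiet_config.actin_conc / SUBUNITS_PER_MICRON
        for tr in tracks:
            slopes = np.diff(tr.lengths) / np.diff(tr.times)
            np.testing.assert_allclose(slopes, v, rtol=1e-12, atol=1e-12)

    def test_zero_growth_rates_tracks_stay_flat(self):
        cfg = SimConfig(
            length_noise_sd=0.0,
            transition_rates={},
            state_growth_rates={"free": 0.0},
            movie_duration=100.0,
        )
        tracks, _ = simulate_filament_population(cfg, 4)
        for tr in tracks:
            np.testing.assert_array_equal(tr.lengths, tr.lengths[0])

    def test_ground_truth_pause_durations_match_configured_gaussian(self):
        cfg = SimConfig(seed=42)
        _, events = simulate_filament_population(cfg, 500)
        durs = [
            e.duration
            for e in events
            if e.state == "iqgap1_paused" and e.end < cfg.movie_duration
        ]
        assert len(durs) > 100
        assert abs(np.mean(durs) - 20.6) < 0.5

    def test_events_tile_filament_lifetime_without_overlap(self):
        cfg = SimConfig(seed=3)
        tracks, events = simulate_filament_population(cfg, 20)
        for tr in tracks:
            evs = sorted(
                (e for e in events if e.filament_id == tr.filament_id),
                key=lambda e: e.start,
            )
            assert evs[-1].end == cfg.movie_duration
            for a, b in zip(evs[:-1], evs[1:]):
                assert a.end == b.start

    def test_same_seed_same_output(self):
        cfg = SimConfig(seed=7)
        t1, e1 = simulate_filament_population(cfg, 10)
        t2, e2 = simulate_filament_population(cfg, 10)
        assert e1 == e2
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.lengths, b.lengths)
            np.testing.assert_array_equal(a.times, b.times)

    @pytest.mark.parametrize(
        "field, value, match",
        [
            ("frame_interval", 0.0, "frame_interval"),
            ("movie_duration", 10.0, "movie_duration"),
            ("length_noise_sd", -0.1, "length_noise_sd"),
            ("state_growth_rates", {"free": -1.0}, "free"),
            ("state_growth_rates", {"free": 1.0, "cp_capped": 2.0}, "cp_capped"),
            ("transition_rates", {("free", "formin"): -0.1}, "transition_rates"),
        ],
    )
    def test_invalid_config_names_the_offending_field(self, field, value, match):
        with pytest.raises(ConfigurationError, match=match):
            SimConfig(**{field: value})

    def test_n_filaments_must_be_positive(self, quiet_config):
        with pytest.raises(ConfigurationError):
            simulate_filament_population(quiet_config, 0)


class TestPhotobleachTraces:
    def test_full_labeling_every_dimer_has_two_steps(self):
        traces = simulate_photobleach_traces(2, 1.0, 50, 0.1, 0.05, seed=1)
        assert len(traces) == 50
        assert all(tr.true_step_count == 2 for tr in traces)

    def test_visible_step_histogram_matches_conditional_binomial(self):
        traces = simulate_photobleach_traces(2, 0.7, 10000, 0.1, 0.0, seed=2)
        ks = np.array([tr.true_step_count for tr in traces])
        frac1 = np.mean(ks == 1)
        # conditional on visibility: 0.42/0.91 and 0.49/0.91
        assert abs(100 * frac1 - 46.2) < 2.0
        assert abs(100 * np.mean(ks == 2) - 53.8) < 2.0

    def test_noise_free_plateaus_are_integer_multiples_of_unit_step(self):
        traces = simulate_photobleach_traces(
            3, 0.8, 30, 0.1, 0.0, seed=3, unit_step=2.5
        )
        for tr in traces:
            levels = np.unique(tr.intensities)
            np.testing.assert_allclose(levels % 2.5, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    @pytest.mark.parametrize("p", [0.3, 0.5, 0.7, 1.0])
    def test_step_counts_converge_to_conditional_binomial_on_grid(self, n, p):
        from plusend import predict_step_pmf

        traces = simulate_photobleach_traces(n, p, 3000, 0.1, 0.0, seed=100 * n + int(10 * p))
        ks = np.array([tr.true_step_count for tr in traces])
        pmf = predict_step_pmf(n, p, conditional_on_visible=True)
        for k, expected in pmf.items():
            assert abs(np.mean(ks == k) - expected) < 0.035

    def test_invalid_label_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_photobleach_traces(2, 0.0, 10, 0.1, 0.0, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_photobleach_traces(2, 1.2, 10, 0.1, 0.0, seed=0)


class TestDwellEvents:
    def test_exponential_mean_recovery(self):
        recs = simulate_dwell_events({"mDia1": 100.0}, 0.0, 10000.0, 5000, seed=3)
        durs = [r.duration for r in recs if not r.censored]
        assert abs(np.mean(durs) - 100.0) < 5.0

    def test_tiny_movie_censors_everything(self):
        recs = simulate_dwell_events({"CP": 100.0}, 0.0, 0.01, 50, seed=4)
        assert all(r.censored for r in recs)
        assert all(r.release_time == 0.01 for r in recs)

    def test_displacement_hazard_competes_exponentially(self):
        # intrinsic rate 0.01 + hazard 0.05 -> mean 1/0.06 ~ 16.7 s
        recs = simulate_dwell_events({"mDia1": 100.0}, 0.05, 10000.0, 8000, seed=5)
        durs = [r.duration for r in recs if not r.censored]
        assert abs(np.mean(durs) - 1 / 0.06) < 0.05 / 0.06

    def test_non_positive_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_dwell_events({"CP": 0.0}, 0.0, 100.0, 10, seed=0)


class TestSpotSets:
    def test_full_colocalization_no_jitter_sets_identical(self):
        a, b = simulate_spot_sets(0.05, 1.0, 0.0, (50.0, 50.0), seed=6)
        np.testing.assert_array_equal(np.sort(a.points, axis=0), np.sort(b.points, axis=0))

    def test_points_stay_inside_fov(self):
        a, b = simulate_spot_sets(0.1, 0.5, 0.2, (30.0, 20.0), seed=7)
        for s in (a, b):
            assert np.all(s.points >= 0)
            assert np.all(s.points[:, 0] <= 30.0)
            assert np.all(s.points[:, 1] <= 20.0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_spot_sets(0.1, 1.5, 0.0, (10.0, 10.0), seed=0)


class TestBundleField:
    def test_pure_fields_are_symmetric_and_mixture_is_right_skewed(self):
        none = simulate_bundle_field(30000, 0.0, 4.0, 0.2, seed=8)
        some = simulate_bundle_field(30000, 0.2, 4.0, 0.2, seed=8)
        all_b = simulate_bundle_field(30000, 1.0, 4.0, 0.2, seed=8)
        assert abs(intensity_skewness(none)) < 0.05
        assert abs(intensity_skewness(all_b)) < 0.05
        assert intensity_skewness(some) > intensity_skewness(none) + 0.5

    def test_multiplier_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_bundle_field(100, 0.2, 1.5, 0.1, seed=0)
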