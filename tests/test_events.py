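"""Log amplitude, percentile envelopes, dip detection, REI."""

import math

import numpy as np
import pytest

from piezosleep import (
    ConfigurationError,
    DetectionParams,
    DomainError,
    EnvelopePair,
    EnvelopeParams,
    MicromotionRecord,
    compute_envelopes,
    compute_rei,
    detect_events,
    log_amplitude,
    run_detection,
)
from conftest import oracle_envelope_point, oracle_percentile


class TestLogAmplitude:
    def test_constant_maps_through_log(self):
        x = np.full(10, math.e - 1.0)
        assert np.allclose(log_amplitude(x), 1.0)

    def test_rectification_symmetry(self):
        out = log_amplitude(np.array([-5.0, 5.0]))
        assert np.allclose(out, math.log(6.0))

    def test_unit_sinusoid_95th_percentile(self):
        t = np.arange(400) / 100.0  # one 0.25 Hz period at 100 Hz
        out = log_amplitude(np.sin(2 * np.pi * 0.25 * t))
        p95 = oracle_percentile(out, 0.95)
        assert p95 == pytest.approx(math.log(2.0), abs=0.01)


class TestComputeEnvelopes:
    def test_constant_signal_constant_envelopes(self):
        rate = 10.0
        n = int(400 * rate)
        env = compute_envelopes(np.full(n, -2.5), None, rate)
        assert np.allclose(env.fast[env.valid], -2.5)
        assert np.allclose(env.slow[env.valid], -2.5)
        assert env.valid.any()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        rate = 10.0
        params = EnvelopeParams(fast_window_s=7.0, slow_window_s=60.0)
        logamp = rng.normal(0, 1, int(300 * rate))
        mask = rng.random(logamp.size) < 0.1
        env = compute_envelopes(logamp, mask, rate, params)
        for g in range(0, len(env.times), 7):
            if not env.valid[g]:
                continue
            for window, out in ((params.fast_window_s, env.fast), (params.slow_window_s, env.slow)):
                expected = oracle_envelope_point(
                    logamp, mask, rate, env.times[g], window, params.percentile
                )
                assert out[g] == expected

    def test_step_response_transition_widths(self):
        rate = 10.0
        logamp = np.concatenate([np.zeros(int(600 * rate)), -np.ones(int(600 * rate))])
        mask = np.zeros(logamp.size, dtype=bool)
        params = EnvelopeParams(fast_window_s=10.0, slow_window_s=120.0)
        env = compute_envelopes(logamp, mask, rate, params)

        def at(t, arr):
            return arr[int(round(t / env.grid_step_s))]

        assert at(300, env.fast) == 0.0 and at(300, env.slow) == 0.0
        assert at(900, env.fast) == -1.0 and at(900, env.slow) == -1.0
        # fast envelope completes its transition within ~10 s of the step,
        # the slow envelope within ~120 s (nearest-rank 95th percentile
        # holds the high value until <5% of the window remains high)
        assert at(598, env.fast) == 0.0 and at(612, env.fast) == -1.0
        assert at(545, env.slow) == 0.0 and at(665, env.slow) == -1.0
        # oracle agreement through the transition
        for t in range(540, 670, 5):
            expected = oracle_envelope_point(logamp, mask, rate, float(t), 120.0, 0.95)
            assert at(t, env.slow) == expected

    def test_too_short_recording_rejected(self):
        from piezosleep import LengthError

        with pytest.raises(LengthError):
            compute_envelopes(np.zeros(100), None, 10.0)


def _flat_envelope(duration_s=900, step=1.0):
    n = int(duration_s / step)
    times = np.arange(n) * step
    return EnvelopePair(
        times=times,
        fast=np.zeros(n),
        slow=np.zeros(n),
        valid=np.ones(n, dtype=bool),
        grid_step_s=step,
        trt_seconds=duration_s,
    )


class TestDetectEvents:
    def test_no_separation_no_events(self):
        assert detect_events(_flat_envelope()) == []

    def test_single_dip_with_default_params(self):
        env = _flat_envelope()
        env.fast[100:145] = -0.5  # 45-s dip, deeper than ln(1.43)
        events = detect_events(env)
        assert len(events) == 1
        (e,) = events
        assert e.duration_s == pytest.approx(45.0, abs=env.grid_step_s)
        assert e.max_depth_log == pytest.approx(0.5)
        assert e.max_depth_log >= DetectionParams().log_threshold

    def test_duration_criteria_reject_short_and_long(self):
        env = _flat_envelope()
        env.fast[100:108] = -0.5  # 8 s: too short
        env.fast[300:380] = -0.5  # 80 s: too long, rejected whole
        assert detect_events(env) == []

    def test_invalid_points_split_runs(self):
        env = _flat_envelope()
        env.fast[100:140] = -0.5
        env.valid[119] = False  # movement-masked point splits the run
        events = detect_events(env)
        assert len(events) == 2
        assert events[0].end_s <= 119 < events[1].start_s

    def test_shallow_dip_below_threshold_ignored(self):
        env = _flat_envelope()
        env.fast[100:140] = -0.3  # 26% reduction < 30% threshold
        assert detect_events(env) == []

    def test_coarse_grid_rejected(self):
        env = _flat_envelope(step=4.0)
        with pytest.raises(ConfigurationError):
            detect_events(env, DetectionParams(min_duration_s=10.0))

    def test_empty_envelope_empty_result(self):
        env = _flat_envelope(duration_s=0)
        assert detect_events(env) == []


class TestComputeRei:
    @pytest.mark.parametrize(
        "n_events, hours, expected",
        [(0, 8.0, 0.0), (56, 8.0, 7.0), (14, 7.5, 14 / 7.5)],
    )
    def test_rate_arithmetic(self, n_events, hours, expected):
        events = detect_events(_make_env_with_dips(n_events))
        assert len(events) == n_events
        assert compute_rei(events, hours).rei == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_trt_rejected(self):
        with pytest.raises(DomainError):
            compute_rei([], 0.0)


def _make_env_with_dips(n_dips):
    env = _flat_envelope(duration_s=max(900, 100 * n_dips + 200))
    for k in range(n_dips):
        start = 100 + 100 * k
        env.fast[start : start + 30] = -1.0
    return env


class TestFullPipeline:
    def test_all_zero_record_rei_zero(self):
        rec = MicromotionRecord(np.zeros(int(3600 * 100), dtype=np.int32))
        assert run_detection(rec).rei == 0.0

    def test_detected_events_respect_invariants(self, small_subject):
        record, _ = small_subject
        result = run_detection(record)
        params = DetectionParams()
        prev_end = -1.0
        for e in result.events:
            assert params.min_duration_s <= e.duration_s <= params.max_duration_s
            assert e.max_depth_log >= params.log_threshold
            assert e.start_s >= prev_end  # ordered, non-overlapping
            prev_end = e.end_s

    def test_event_count_monotone_in_depth(self, small_subject):
        record, _ = small_subject
        counts = []
        for depth in (10.0, 30.0, 50.0, 70.0, 90.0):
            res = run_detection(record, det_params=DetectionParams(depth_percent=depth))
            counts.append(len(res.events))
        assert counts == sorted(counts, reverse=True)

    def test_shallow_planted_dips_do_not_fire(self):
        from piezosleep import SimulationConfig, simulate_subject

        cfg = SimulationConfig(
            duration_s=3600.0,
            event_rate_per_h=12.0,
            event_depth_percent=10.0,  # below the 30% threshold
            shallow_spell_base_per_h=0.0,
            shallow_spell_per_event=0.0,
            posture_shift_every_s=0.0,
            seed=3,
        )
        record, truth = simulate_subject(cfg)
        assert truth.true_ahi >= 8.0
        assert run_detection(record).rei <= 1.0
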