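"""Transition detection, tanh fitting, and kinetics summaries."""

import numpy as np
import pytest

from wormdyn import (TANH_5_95, DetectionParams, TransitionEvent,
                     average_aligned_transitions, detect_transitions,
                     extract_transitions, fit_transition_tanh,
                     generate_ava_trace, summarize_kinetics)
from wormdyn.errors import EmptyResultError, OrderingError


def _tanh_step(t, t0, tau, direction, baseline=0.0, amplitude=1.0):
    s = 1.0 if direction == "on" else -1.0
    return baseline + amplitude / 2 * (1 + s * np.tanh((t - t0) / tau))


class TestDetect:
    def test_square_wave_candidates_at_steps(self):
        trace = np.zeros(200)
        trace[80:140] = 1.0
        cands = detect_transitions(trace, 2.0,
                                   DetectionParams(smooth_s=0.0))
        assert [c["direction"] for c in cands] == ["on", "off"]
        assert cands[0]["cross_frame"] == 80
        assert cands[1]["cross_frame"] == 140

    def test_constant_trace_yields_nothing(self):
        assert detect_transitions(np.full(200, 0.4), 2.0) == []

    def test_synthetic_trace_recovers_planted_bouts(self):
        trace, truth = generate_ava_trace(n_bouts=5, noise_sd=0.03, seed=3)
        events = extract_transitions(trace, 4.0)
        ons = [e for e in events if e.direction == "on"]
        offs = [e for e in events if e.direction == "off"]
        assert len(ons) == 5 and len(offs) == 5
        truth_on = sorted(e.onset_frame for e in truth
                          if e.direction == "on")
        got_on = sorted(e.onset_frame for e in ons)
        assert all(abs(a - b) <= 2 for a, b in zip(got_on, truth_on))


class TestFit:
    @pytest.mark.parametrize("tau", [0.25, 0.5, 1.0, 2.0, 4.0])
    def test_noiseless_transition_time_is_analytic(self, tau):
        fs = 4.0
        t = np.arange(0, 60, 1 / fs)
        trace = _tanh_step(t, 30.0, tau, "on")
        ev = fit_transition_tanh(trace, (0, t.size), "on", fs)
        assert ev.ok
        expected = 2 * tau * np.arctanh(0.9)
        assert ev.transition_time == pytest.approx(expected, rel=1e-6)

    def test_transition_time_scales_with_dilation(self):
        fs = 4.0
        t = np.arange(0, 80, 1 / fs)
        a = fit_transition_tanh(_tanh_step(t, 40, 1.0, "off"),
                                (0, t.size), "off", fs)
        b = fit_transition_tanh(_tanh_step(t, 40, 3.0, "off"),
                                (0, t.size), "off", fs)
        assert b.transition_time / a.transition_time == pytest.approx(
            3.0, rel=1e-5)

    def test_noisy_recovery_near_information_bound(self):
        """At sigma = 0.1*amplitude, 4 Hz, tau = 1 s, the Cramer-Rao bound
        for the four-parameter fit puts the best attainable median relative
        error in the 5-95% time at ~0.105; the least-squares fit must land
        within ~20% of that bound."""
        rng = np.random.default_rng(21)
        fs, tau = 4.0, 1.0
        t = np.arange(0, 60, 1 / fs)
        truth = TANH_5_95 * tau
        errs = []
        for _ in range(200):
            trace = _tanh_step(t, 30.0, tau, "on") \
                + rng.normal(0, 0.1, t.size)
            ev = fit_transition_tanh(trace, (0, t.size), "on", fs)
            errs.append(abs(ev.transition_time - truth) / truth)
        assert np.median(errs) < 1.2 * 0.105


class TestSummarize:
    def _ev(self, direction, frame):
        return TransitionEvent(direction=direction, t0=frame / 2.0, tau=1.0,
                               baseline=0.0, amplitude=1.0,
                               onset_frame=frame,
                               transition_time=TANH_5_95, fit_rmse=0.0)

    def test_single_bout_duty_ratio(self):
        events = [self._ev("on", 100), self._ev("off", 300)]
        s = summarize_kinetics(events, trace_length=300.0, sampling_rate=2.0)
        assert s.bouts[0].duration == pytest.approx(100.0)
        assert s.duty_ratio == pytest.approx(1 / 3)

    def test_no_events(self):
        s = summarize_kinetics([], trace_length=600.0, sampling_rate=2.0)
        assert s.duty_ratio == 0.0
        assert s.transient_frequency == 0.0

    def test_three_bouts_hand_arithmetic(self):
        events = []
        for k in range(3):
            events += [self._ev("on", 200 * k), self._ev("off", 200 * k + 60)]
        s = summarize_kinetics(events, trace_length=600.0, sampling_rate=2.0)
        assert s.duty_ratio == pytest.approx(0.15)
        assert s.transient_frequency == pytest.approx(0.3)

    def test_off_before_on_is_error(self):
        with pytest.raises(OrderingError):
            summarize_kinetics([self._ev("off", 10), self._ev("on", 50)],
                               600.0, 2.0)

    def test_square_wave_duty_cycle_exact(self):
        # periodic square wave: duty ratio equals its duty cycle
        fs = 4.0
        period, high = 100.0, 40.0
        trace = np.zeros(int(600 * fs))
        for k in range(6):
            start = int((k * period + 30.0) * fs)
            trace[start:start + int(high * fs)] = 1.0
        events = extract_transitions(trace, fs,
                                     DetectionParams(smooth_s=0.0))
        s = summarize_kinetics(events, 600.0, fs)
        assert s.duty_ratio == pytest.approx(high / period, abs=0.02)


class TestAlignedAverage:
    def test_identical_events_average_to_event(self):
        fs = 4.0
        t = np.arange(0, 40, 1 / fs)
        step = _tanh_step(t, 20.0, 1.0, "on")
        trace = np.concatenate([step, step])
        onset5 = int(np.ceil((20.0 - np.arctanh(0.9)) * fs))
        events = [TransitionEvent(direction="on", t0=20.0, tau=1.0,
                                  baseline=0.0, amplitude=1.0,
                                  onset_frame=onset5 + k * t.size,
                                  transition_time=TANH_5_95, fit_rmse=0.0)
                  for k in range(2)]
        mean, sem = average_aligned_transitions(events, trace, "on",
                                                pre_s=5, post_s=5,
                                                sampling_rate=fs)
        assert mean.shape == sem.shape == (41,)
        np.testing.assert_allclose(
            mean, trace[onset5 - 20: onset5 + 21], atol=1e-12)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)

    def test_single_event_is_identity(self):
        trace, truth = generate_ava_trace(n_bouts=2, noise_sd=0.0, seed=0)
        ev = [e for e in truth if e.direction == "on"][0]
        mean, _ = average_aligned_transitions([ev], trace, "on", 2, 2, 4.0)
        lo = ev.onset_frame - 8
        np.testing.assert_allclose(mean, trace[lo:lo + 17])

    def test_noisy_mean_near_clean_curve(self):
        rng = np.random.default_rng(9)
        fs = 4.0
        t = np.arange(0, 20, 1 / fs)
        clean = _tanh_step(t, 10.0, 1.0, "on")
        sigma = 0.1
        events = []
        stack = np.empty((50, t.size))
        for i in range(50):
            stack[i] = clean + rng.normal(0, sigma, t.size)
        trace = stack.ravel()
        onset5 = int(np.ceil((10.0 - np.arctanh(0.9)) * fs))
        for i in range(50):
            events.append(TransitionEvent(
                direction="on", t0=10.0, tau=1.0, baseline=0.0,
                amplitude=1.0, onset_frame=i * t.size + onset5,
                transition_time=TANH_5_95, fit_rmse=0.0))
        mean, _ = average_aligned_transitions(events, trace, "on",
                                              pre_s=2, post_s=2,
                                              sampling_rate=fs)
        expect = clean[onset5 - 8: onset5 + 9]
        assert np.all(np.abs(mean - expect) < 3 * sigma / np.sqrt(50) + 1e-9)

    def test_no_events_error(self):
        with pytest.raises(EmptyResultError):
            average_aligned_transitions([], np.zeros(100), "on", 1, 1, 2.0)
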