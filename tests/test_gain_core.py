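import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qvor.errors import EstimationError
from qvor.gain_core import (
    DesaccadeParams,
    Direction,
    analyze_paradigm,
    detect_saccades,
    estimate_frequency,
    estimate_slope_gain,
    split_by_direction,
)
from qvor.preprocess import select_analysis_window
from qvor.synthetic import TraceSimConfig, generate_trace

from conftest import make_trace


def closed_form_gain(head, eye):
    """Independent oracle: zero-intercept least-squares slope magnitude."""
    return abs(float(np.dot(head, eye) / np.dot(head, head)))


NO_REJECT = DesaccadeParams(max_iter=1, residual_k=np.inf)


class TestDetectSaccades:
    def test_pure_sinusoid_has_no_saccades(self):
        win = select_analysis_window(make_trace())
        mask, intervals = detect_saccades(win)
        assert intervals == []
        assert mask.all()

    def test_zero_eye_velocity_has_no_saccades(self):
        trace = make_trace(gain=0.0)
        mask, intervals = detect_saccades(select_analysis_window(trace))
        assert intervals == []

    def test_injected_pulse_is_localized(self):
        """A 50 ms, 300 deg/s pulse centred at 9.0 s yields one covering interval."""
        trace = make_trace()
        eye = trace.eye_velocity.copy()
        t = trace.time
        start, dur = 8.975, 0.05
        in_pulse = (t >= start) & (t <= start + dur)
        s = (t[in_pulse] - start) / dur
        eye[in_pulse] += 300.0 * 0.5 * (1 - np.cos(2 * np.pi * s))
        win = select_analysis_window(
            trace.replace_samples(t, trace.head_velocity, eye)
        )
        mask, intervals = detect_saccades(win)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert lo <= 8.975 and hi >= 9.025
        assert not mask[(win.time >= lo) & (win.time <= hi)].any()


class TestSplitByDirection:
    def test_sinusoid_rightward_fraction(self):
        """Analytic fraction above a 10 deg/s deadband for a 100 deg/s sinusoid.

        The window holds a whole number of periods (3 periods of 0.75 Hz in
        [8, 12) s) so the per-period analytic fraction applies exactly.
        """
        from qvor.preprocess import AnalysisWindow

        trace = make_trace(head_peak=100.0)
        win = select_analysis_window(trace, AnalysisWindow(8.0, 12.0))
        labels = split_by_direction(win, deadband=10.0)
        expected = (np.pi - 2 * np.arcsin(0.1)) / (2 * np.pi)  # 0.468127
        frac_right = np.mean(labels == Direction.RIGHT)
        frac_left = np.mean(labels == Direction.LEFT)
        assert frac_right == pytest.approx(expected, abs=0.01)
        assert frac_left == pytest.approx(expected, abs=0.01)

    def test_constant_positive_velocity_all_rightward(self):
        trace = make_trace(duration_s=2.0)
        flat = trace.replace_samples(
            trace.time, np.full(trace.n_samples, 50.0), trace.eye_velocity
        )
        labels = split_by_direction(flat, deadband=10.0)
        assert (labels == Direction.RIGHT).all()

    def test_subthreshold_velocity_all_excluded(self):
        trace = make_trace(duration_s=2.0, head_peak=5.0)
        labels = split_by_direction(trace, deadband=10.0)
        assert (labels == Direction.EXCLUDED).all()


class TestSlopeGain:
    def _fit(self, trace, params=NO_REJECT, direction=Direction.RIGHT):
        win = select_analysis_window(trace)
        mask, _ = detect_saccades(win, params)
        labels = split_by_direction(win)
        return estimate_slope_gain(win, mask, labels, direction, params)

    def test_perfect_compensation_gain_one(self):
        gain, diag = self._fit(make_trace(gain=1.0))
        assert gain == pytest.approx(1.0, abs=1e-12)
        assert diag["slope"] < 0  # compensatory sign convention

    def test_noisy_low_gain_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        trace = make_trace(gain=0.35)
        eye = trace.eye_velocity + rng.normal(0, 1.0, trace.n_samples)
        noisy = trace.replace_samples(trace.time, trace.head_velocity, eye)
        win = select_analysis_window(noisy)
        mask, _ = detect_saccades(win, NO_REJECT)
        labels = split_by_direction(win)
        sel = mask & (labels == Direction.RIGHT)
        expected = closed_form_gain(win.head_velocity[sel], win.eye_velocity[sel])
        gain, _ = estimate_slope_gain(win, mask, labels, Direction.RIGHT, NO_REJECT)
        assert gain == pytest.approx(expected, abs=1e-12)
        assert gain == pytest.approx(0.35, abs=0.01)

    def test_zero_eye_velocity_gain_zero(self):
        gain, _ = self._fit(make_trace(gain=0.0))
        assert gain == 0.0

    def test_degenerate_head_velocity_rejected(self):
        trace = make_trace(duration_s=2.0)
        flat = trace.replace_samples(
            trace.time, np.full(trace.n_samples, 50.0), trace.eye_velocity
        )
        labels = split_by_direction(flat)
        # constant head has signal but direction split leaves leftward empty
        with pytest.raises(EstimationError):
            estimate_slope_gain(
                flat, np.ones(flat.n_samples, bool), labels, Direction.LEFT
            )

    def test_oracle_equivalence_on_random_traces(self):
        """Robust iteration disabled: pipeline slope == closed form to 1e-9."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            gain_true = rng.uniform(0.1, 1.2)
            noise = rng.uniform(0.0, 5.0)
            trace = make_trace(gain=gain_true, head_peak=rng.uniform(40, 120))
            eye = trace.eye_velocity + rng.normal(0, noise, trace.n_samples)
            noisy = trace.replace_samples(trace.time, trace.head_velocity, eye)
            win = select_analysis_window(noisy)
            mask, _ = detect_saccades(win, NO_REJECT)
            labels = split_by_direction(win)
            for direction in (Direction.RIGHT, Direction.LEFT):
                sel = mask & (labels == direction)
                expected = closed_form_gain(
                    win.head_velocity[sel], win.eye_velocity[sel]
                )
                got, _ = estimate_slope_gain(win, mask, labels, direction, NO_REJECT)
                assert got == pytest.approx(expected, abs=1e-9)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, c):
        """Scaling eye by c scales gain by c; scaling both leaves it fixed."""
        trace = make_trace(gain=0.5, duration_s=17.0)
        win = select_analysis_window(trace)
        mask = np.ones(win.n_samples, bool)
        labels = split_by_direction(win)
        base, _ = estimate_slope_gain(win, mask, labels, Direction.RIGHT, NO_REJECT)
        eye_scaled = win.replace_samples(
            win.time, win.head_velocity, c * win.eye_velocity
        )
        both_scaled = win.replace_samples(
            win.time, c * win.head_velocity, c * win.eye_velocity
        )
        g_eye, _ = estimate_slope_gain(eye_scaled, mask, labels, Direction.RIGHT, NO_REJECT)
        g_both, _ = estimate_slope_gain(both_scaled, mask, labels, Direction.RIGHT, NO_REJECT)
        assert g_eye == pytest.approx(c * base, rel=1e-9)
        assert g_both == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize("rate", [1.0, 3.0, 5.0])
    def test_saccade_robustness(self, rate):
        """Up to 5 pulses/s on a noiseless trace moves the gain < 0.02."""
        cfg = TraceSimConfig(true_gain=0.35, paradigm="VORS",
                             saccade_rate=rate, seed=3)
        trace, _ = generate_trace(cfg)
        result = analyze_paradigm(trace)
        assert abs(result.gain_right - 0.35) < 0.02
        assert abs(result.gain_left - 0.35) < 0.02


class TestFrequency:
    def test_pure_tone(self):
        win = select_analysis_window(make_trace(freq=0.75))
        assert estimate_frequency(win) == pytest.approx(0.75, abs=0.005)

    def test_shifted_tone_with_noise(self):
        rng = np.random.default_rng(1)
        trace = make_trace(freq=0.85)
        head = trace.head_velocity + rng.normal(0, 5.0, trace.n_samples)
        noisy = trace.replace_samples(trace.time, head, trace.eye_velocity)
        win = select_analysis_window(noisy)
        assert estimate_frequency(win) == pytest.approx(0.85, abs=0.02)

    def test_zero_head_velocity_rejected(self):
        trace = make_trace(head_peak=1e-12)
        with pytest.raises(EstimationError):
            estimate_frequency(select_analysis_window(trace))

    def test_invariant_to_amplitude_and_gain(self):
        f1 = estimate_frequency(select_analysis_window(make_trace(head_peak=40)))
        f2 = estimate_frequency(select_analysis_window(make_trace(head_peak=120, gain=0.2)))
        assert f1 == pytest.approx(f2, abs=1e-6)


class TestAnalyzeParadigm:
    def test_noiseless_recovery(self):
        trace, _ = generate_trace(TraceSimConfig(true_gain=1.0, seed=0))
        res = analyze_paradigm(trace)
        assert res.gain_right == pytest.approx(1.0, abs=1e-3)
        assert res.gain_left == pytest.approx(1.0, abs=1e-3)
        assert res.frequency_hz == pytest.approx(0.75, abs=5e-3)

    def test_determinism(self):
        trace, _ = generate_trace(
            TraceSimConfig(true_gain=0.35, noise_sd=3.0, saccade_rate=2.0,
                           paradigm="VORS", seed=9)
        )
        r1 = analyze_paradigm(trace)
        r2 = analyze_paradigm(trace)
        assert r1 == r2

    @pytest.mark.parametrize("gain", [0.2, 0.35, 0.5, 1.0])
    @pytest.mark.parametrize("freq", [0.6, 0.75, 0.9])
    def test_parameter_recovery_grid(self, gain, freq):
        """Median absolute gain error < 0.02 under protocol noise."""
        errors = []
        for seed in range(20):
            cfg = TraceSimConfig(
                true_gain=gain, nominal_frequency=freq, noise_sd=3.0,
                saccade_rate=2.0, paradigm="VORS", seed=seed,
            )
            trace, _ = generate_trace(cfg)
            res = analyze_paradigm(trace)
            errors.append(abs(res.gain_right - gain))
            errors.append(abs(res.gain_left - gain))
            assert res.frequency_hz == pytest.approx(freq, abs=0.02)
        assert np.median(errors) < 0.02
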