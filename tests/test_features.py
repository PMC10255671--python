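import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from strokemetrics.config import FilterConfig, PipelineConfig
from strokemetrics.features import (compute_shock_metrics, emg_envelope,
                                    mvc_reference, normalize_to_mvc,
                                    peak_after_impact, shock_bandlimit,
                                    shock_transmission_pct)
from strokemetrics.recording import detect_impacts, extract_stroke_windows
from strokemetrics.segmentation import segment_phases
from strokemetrics.synthgen import (MvcParams, StrokeParams,
                                    generate_mvc_trials, generate_stroke)

FS = 8333.0


class TestEmgEnvelope:
    def test_zero_input_zero_output(self):
        assert np.all(emg_envelope(np.zeros(5000), FS) == 0.0)

    def test_dc_rejected(self):
        env = emg_envelope(np.full(16666, 7.0), FS)
        central = env[4000:-4000]
        assert np.abs(central).max() < 1e-6 * 7.0

    def test_rectified_sinusoid_mean(self):
        """A unit 50 Hz sinusoid rectifies to mean 2/π; the 10 Hz low-pass
        recovers that steady-state level in the central half."""
        t = np.arange(int(2 * FS)) / FS
        env = emg_envelope(np.sin(2 * np.pi * 50.0 * t), FS)
        central = env[len(env) // 4: 3 * len(env) // 4]
        np.testing.assert_allclose(central, 2 / np.pi, rtol=0.02)

    def test_shift_equivariance(self):
        """Zero-phase filtering: delaying the input delays the envelope."""
        rng = np.random.default_rng(0)
        n, k = 8000, 400
        burst = np.zeros(n)
        burst[2000:3000] = rng.standard_normal(1000)
        shifted = np.roll(burst, k)
        e0 = emg_envelope(burst, FS)
        e1 = emg_envelope(shifted, FS)
        np.testing.assert_allclose(e1[2000 + k:3000 + k], e0[2000:3000],
                                   atol=1e-4 * np.abs(e0).max())

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(6000)
        e1 = emg_envelope(x, FS)
        e3 = emg_envelope(3.0 * x, FS)
        np.testing.assert_allclose(e3, 3.0 * e1, atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            emg_envelope(np.zeros(50), FS)


class TestShockBandlimit:
    def test_low_frequency_rejected(self):
        t = np.arange(int(2 * FS)) / FS
        out = shock_bandlimit(np.sin(2 * np.pi * 5.0 * t), FS)
        assert np.abs(out[2000:-2000]).max() < 0.1

    def test_high_frequency_rejected(self):
        t = np.arange(int(2 * FS)) / FS
        out = shock_bandlimit(np.sin(2 * np.pi * 1000.0 * t), FS)
        assert np.abs(out[2000:-2000]).max() < 0.1

    def test_passband_frequency_preserved(self):
        t = np.arange(int(2 * FS)) / FS
        out = shock_bandlimit(np.sin(2 * np.pi * 100.0 * t), FS)
        amp = np.abs(out[2000:-2000]).max()
        # within 1 dB of unity (tiny passband ripple overshoot allowed)
        assert 0.89 <= amp <= 1.001

    def test_zero_in_zero_out(self):
        assert np.allclose(shock_bandlimit(np.zeros(4000), FS), 0.0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            shock_bandlimit(np.zeros(4000), 700.0)


class TestPeakAfterImpact:
    def setup_method(self):
        self.rate = 2000.0
        n = 2 * int(self.rate) + 1
        self.time = (np.arange(n) - n // 2) / self.rate

    def test_post_impact_impulse_found(self):
        x = np.zeros_like(self.time)
        x[np.argmin(np.abs(self.time - 0.01))] = 12.0
        assert peak_after_impact(x, self.time) == 12.0

    def test_pre_impact_excursion_ignored(self):
        x = np.zeros_like(self.time)
        x[np.argmin(np.abs(self.time + 0.2))] = 50.0
        x[np.argmin(np.abs(self.time - 0.1))] = 8.0
        assert peak_after_impact(x, self.time) == 8.0

    def test_all_zero_gives_zero(self):
        assert peak_after_impact(np.zeros_like(self.time), self.time) == 0.0

    def test_empty_interval_raises(self):
        t = self.time[: len(self.time) // 2]   # entirely pre-impact
        with pytest.raises(ValueError, match="empty"):
            peak_after_impact(np.zeros_like(t), t)


class TestShockTransmissionPct:
    @pytest.mark.parametrize("a_x, a_racket, expected", [
        (49.8, 49.8, 100.0),
        (0.0, 49.8, 0.0),
        (11.0, 49.8, 22.088353413654617),
    ])
    def test_values(self, a_x, a_racket, expected):
        assert shock_transmission_pct(a_x, a_racket) == pytest.approx(expected)

    def test_nonpositive_racket_peak_rejected(self):
        with pytest.raises(ValueError):
            shock_transmission_pct(1.0, 0.0)
        with pytest.raises(ValueError):
            shock_transmission_pct(-1.0, 10.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a_x=st_h.floats(0.0, 1e3), a_racket=st_h.floats(1e-6, 1e3))
    def test_two_step_formula_identity(self, a_x, a_racket):
        """The published two-step percentage formula reduces to the simple
        ratio 100·a_x/a_racket."""
        two_step = 100.0 - (-((a_x - a_racket) / a_racket) * 100.0)
        assert shock_transmission_pct(a_x, a_racket) == pytest.approx(
            two_step, rel=1e-12, abs=1e-9)
        assert shock_transmission_pct(a_x, a_racket) == pytest.approx(
            100.0 * a_x / a_racket, rel=1e-9, abs=1e-9)


class TestMvcReference:
    def test_wrong_trial_count_rejected(self):
        trials = generate_mvc_trials(MvcParams(sample_rate=2000.0), seed=0)
        with pytest.raises(ValueError, match="three"):
            mvc_reference(trials[:2])

    def test_short_trial_rejected(self):
        trials = generate_mvc_trials(MvcParams(sample_rate=2000.0), seed=0)
        short = dataclasses.replace(
            trials[0], time=trials[0].time[:8000],
            channels={k: v[:8000] for k, v in trials[0].channels.items()})
        with pytest.raises(ValueError, match="5 s"):
            mvc_reference([short, trials[1], trials[2]])


class TestNormalizeToMvc:
    def _window_with_emg(self, scale):
        rate = 2000.0
        params = StrokeParams(sample_rate=rate)
        rec, _ = generate_stroke(params, seed=0)
        cfg = PipelineConfig(target_rate=rate)
        [w] = extract_stroke_windows(rec, detect_impacts(rec, cfg))
        return w

    def test_envelope_equal_to_reference_is_100_pct(self):
        from strokemetrics.features import MvcReference
        w = self._window_with_emg(1.0)
        # synthesise a window whose grip equals the reference everywhere
        w.channels["grip_raw"] = np.full_like(w.time, 2.5)
        ref = MvcReference(grip_max=2.5, ecr_mvc=1.0, fcr_mvc=1.0, selected_trial=0)
        stroke = normalize_to_mvc(w, ref)
        np.testing.assert_allclose(stroke.grip_pct, 100.0)

    def test_peak_scale_in_percent(self):
        """An envelope reaching 4.127× its reference reads 412.7 %MVC."""
        from strokemetrics.features import MvcReference
        w = self._window_with_emg(1.0)
        env = emg_envelope(w.channels["emg_fcr_raw"], w.sample_rate)
        ref = MvcReference(grip_max=1.0, ecr_mvc=1.0,
                           fcr_mvc=float(env.max()) / 4.127, selected_trial=0)
        stroke = normalize_to_mvc(w, ref)
        assert stroke.fcr_pct.max() == pytest.approx(412.7, rel=1e-9)

    def test_zero_envelope_is_zero_percent(self):
        from strokemetrics.features import MvcReference
        w = self._window_with_emg(1.0)
        w.channels["emg_ecr_raw"] = np.zeros_like(w.time)
        ref = MvcReference(grip_max=1.0, ecr_mvc=1.0, fcr_mvc=1.0, selected_trial=0)
        stroke = normalize_to_mvc(w, ref)
        np.testing.assert_allclose(stroke.ecr_pct, 0.0)


class TestShockMetrics:
    def _stroke_window(self, **overrides):
        params = dataclasses.replace(StrokeParams().noiseless(), **overrides)
        rec, truth = generate_stroke(params, seed=4)
        [w] = extract_stroke_windows(rec, detect_impacts(rec))
        return w, segment_phases(w), truth

    def test_programmed_attenuations_recovered(self):
        w, bounds, truth = self._stroke_window(attenuation_wrist=0.2,
                                               attenuation_elbow=0.05)
        m = compute_shock_metrics(w, bounds)
        assert m.pct_wrist == pytest.approx(20.0, rel=0.05)
        assert m.pct_elbow == pytest.approx(5.0, rel=0.05)
        assert m.pct_elbow < m.pct_wrist

    def test_monotone_in_programmed_attenuation(self):
        measured = []
        for r in (0.05, 0.1, 0.2, 0.3):
            w, bounds, _ = self._stroke_window(attenuation_wrist=r,
                                               attenuation_elbow=r / 10)
            measured.append(compute_shock_metrics(w, bounds).pct_wrist)
        assert measured == sorted(measured)

    def test_missing_elbow_flagged_absent(self):
        w, bounds, _ = self._stroke_window(include_elbow=False)
        m = compute_shock_metrics(w, bounds)
        assert m.elbow_available is False
        assert m.peak_elbow is None and m.pct_elbow is None
        assert m.wrist_available is True and m.pct_wrist is not None
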