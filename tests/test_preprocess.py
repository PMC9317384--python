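"""Epoching, baseline correction, filtering and trial averaging."""

import numpy as np
import pytest
from scipy import signal

from ocadx.containers import EpochedRecording
from ocadx.preprocess import (
    average_trials,
    baseline_correct,
    design_highpass_fir,
    epoch,
    highpass_filter,
    lowpass_filter,
    preprocess_epochs,
)


def make_epochs(data, fs=500.0, window=(-0.2, 0.4), eye="OS"):
    return EpochedRecording(
        subject_id="T",
        eye=eye,
        sample_rate=fs,
        window=window,
        data=data,
        channel_labels=tuple(f"C{i}" for i in range(data.shape[1])),
    )


class TestEpoch:
    def test_stated_window_gives_300_samples_at_500hz(self):
        sig = np.zeros((2, 5000))
        rec = epoch(sig, 500.0, [1.0, 2.0], window=(-0.2, 0.4))
        assert rec.data.shape == (2, 2, 300)
        # t = 0 sample belongs to the epoch (half-open [start, end))
        assert rec.times[0] == pytest.approx(-0.2)
        assert 0.0 in np.round(rec.times, 9)
        assert rec.times[-1] == pytest.approx(0.4 - 1 / 500.0)

    def test_constant_signal_yields_constant_epochs(self):
        sig = np.ones((1, 2000))
        rec = epoch(sig, 500.0, [1.0, 2.0])
        assert np.all(rec.data == 1.0)

    def test_onsets_too_close_to_edges_are_dropped(self, caplog):
        fs = 500.0
        sig = np.zeros((1, int(10 * fs)))
        onsets = [0.05, 0.15] + list(np.arange(1.0, 9.0))  # 2 bad + 8 good
        with caplog.at_level("WARNING"):
            rec = epoch(sig, fs, onsets)
        assert rec.n_trials == 8
        assert "dropped 2" in caplog.text

    def test_zero_usable_trials_is_an_error(self):
        with pytest.raises(ValueError, match="no onset"):
            epoch(np.zeros((1, 100)), 500.0, [0.01])

    def test_trial_alignment_puts_onset_at_t0(self):
        fs = 500.0
        sig = np.zeros((1, 2000))
        sig[0, 750] = 1.0  # impulse at t = 1.5 s
        rec = epoch(sig, fs, [1.5])
        i0 = int(np.argmin(np.abs(rec.times)))
        assert rec.data[0, 0, i0] == 1.0


class TestBaseline:
    def test_constant_becomes_zero(self):
        rec = make_epochs(np.full((3, 2, 300), 4.2))
        out = baseline_correct(rec)
        assert np.allclose(out.data, 0.0)

    def test_causal_kernel_unchanged(self, noiseless_misrouted_subject):
        _, subj = noiseless_misrouted_subject
        rec = subj.recordings["OS"]
        out = baseline_correct(rec)
        assert np.allclose(out.data, rec.data, atol=1e-12)

    def test_ramp_closed_form(self):
        rec = make_epochs(np.zeros((1, 1, 300)))
        t = rec.times
        a = 3.0
        rec.data[0, 0] = a * t
        out = baseline_correct(rec, baseline=(-0.05, 0.0))
        mask = (t >= -0.05 - 1e-9) & (t <= 1e-9)
        expected = a * t - a * t[mask].mean()
        assert np.allclose(out.data[0, 0], expected, atol=1e-12)
        assert abs(out.data[0, 0][mask].mean()) < 1e-12

    def test_empty_baseline_window_rejected(self):
        rec = make_epochs(np.zeros((1, 1, 300)))
        with pytest.raises(ValueError):
            baseline_correct(rec, baseline=(0.01, -0.01))  # reversed
        with pytest.raises(ValueError):
            baseline_correct(rec, baseline=(0.5, 0.6))  # outside the epoch


class TestHighpass:
    fs = 100.0

    def test_dc_removed(self):
        x = np.full(8000, 5.0)
        y = highpass_filter(x, self.fs)
        mid = y[3000:5000]
        assert np.max(np.abs(mid)) < 0.05

    def test_passband_10hz_preserved(self):
        t = np.arange(8000) / self.fs
        x = np.sin(2 * np.pi * 10 * t)
        y = highpass_filter(x, self.fs)
        mid = slice(3000, 5000)
        amplitude = np.sqrt(2) * np.std(y[mid])  # rms-based, sampling-proof
        assert amplitude == pytest.approx(1.0, rel=0.01)

    def test_stopband_0p01hz_attenuated_per_design(self):
        taps = design_highpass_fir(self.fs)
        w, h = signal.freqz(taps, worN=[0.01], fs=self.fs)
        gain = np.abs(h[0])
        assert gain < 0.1  # > 90 % attenuation at 0.01 Hz
        t = np.arange(60000) / self.fs
        x = np.sin(2 * np.pi * 0.01 * t)
        y = highpass_filter(x, self.fs)
        mid = slice(20000, 40000)
        assert np.max(np.abs(y[mid])) < max(0.1, 1.5 * gain)

    def test_record_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            highpass_filter(np.zeros(100), self.fs)


class TestLowpass:
    def vep(self, data, fs=500.0):
        from ocadx.containers import VEPWaveform

        return VEPWaveform(
            subject_id="T",
            eye="OS",
            sample_rate=fs,
            window=(0.0, data.shape[-1] / fs),
            data=data,
            channel_labels=("C0",),
        )

    def test_passband_5hz_preserved(self):
        fs = 500.0
        t = np.arange(2000) / fs
        v = self.vep(np.sin(2 * np.pi * 5 * t)[None, :])
        out = lowpass_filter(v, 35.0)
        mid = slice(500, 1500)
        assert np.max(np.abs(out.data[0, mid])) == pytest.approx(1.0, rel=0.01)

    def test_60hz_attenuated_per_designed_response(self):
        fs = 500.0
        sos = signal.butter(4, 35.0, btype="low", fs=fs, output="sos")
        w, h = signal.sosfreqz(sos, worN=[60.0], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # forward-backward squares |H|
        t = np.arange(4000) / fs
        v = self.vep(np.sin(2 * np.pi * 60 * t)[None, :])
        out = lowpass_filter(v, 35.0)
        measured = np.max(np.abs(out.data[0, 1000:3000]))
        assert measured == pytest.approx(expected_gain, rel=0.05)

    def test_zero_phase_impulse_response_is_symmetric(self):
        data = np.zeros((1, 601))
        data[0, 300] = 1.0
        out = lowpass_filter(self.vep(data), 35.0)
        resp = out.data[0]
        assert np.allclose(resp, resp[::-1], atol=1e-10)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(self.vep(np.zeros((1, 100))), 250.0)


class TestAverage:
    def test_identical_trials_average_to_any_trial(self):
        trial = np.random.default_rng(0).normal(size=(2, 300))
        rec = make_epochs(np.repeat(trial[None], 5, axis=0))
        assert np.allclose(average_trials(rec).data, trial)

    def test_single_trial_is_identity(self):
        rec = make_epochs(np.random.default_rng(1).normal(size=(1, 2, 300)))
        assert np.allclose(average_trials(rec).data, rec.data[0])

    def test_average_converges_to_kernel_at_clt_rate(self):
        from conftest import reference_kernel

        rng = np.random.default_rng(42)
        n, sd = 400, 1.0
        rec = make_epochs(np.zeros((n, 1, 300)))
        truth = reference_kernel(rec.times)
        rec.data[:] = truth[None, None, :] + sd * rng.standard_normal((n, 1, 300))
        avg = average_trials(rec).data[0]
        resid = avg - truth
        # grand-mean deviation at the CLT rate; per-sample within ~5 sigma
        assert abs(resid.mean()) < 3 * sd / np.sqrt(n * 300)
        assert np.max(np.abs(resid)) < 5 * sd / np.sqrt(n)


class TestPipelineProperties:
    def test_preprocessing_is_linear(self):
        rng = np.random.default_rng(3)
        x = make_epochs(rng.normal(size=(4, 2, 300)))
        y = make_epochs(rng.normal(size=(4, 2, 300)))
        a, b = 2.5, -1.25
        combo = make_epochs(a * x.data + b * y.data)
        out_combo = preprocess_epochs(combo)
        out_lin = a * preprocess_epochs(x).data + b * preprocess_epochs(y).data
        assert np.allclose(out_combo.data, out_lin, atol=1e-9)

    def test_baseline_correction_is_idempotent(self):
        rec = make_epochs(np.random.default_rng(4).normal(size=(3, 2, 300)))
        once = baseline_correct(rec)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)
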