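"""VEP preprocessing: epoching, baseline correction, filtering, averaging.

The chain mirrors routine transient-VEP practice: a 0.1 Hz Blackman-sinc
FIR high-pass on the continuous record, epoching from -0.2 to 0.4 s around
each pattern onset, baseline correction over [-0.05, 0] s, trial averaging,
and a zero-phase 35 Hz Butterworth low-pass on the average.  Every stage is
linear, so the order of averaging and (zero-phase) filtering is
interchangeable; the low-pass is applied after averaging by default.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal

from .containers import EpochedRecording, VEPWaveform, n_epoch_samples, window_mask

log = logging.getLogger(__name__)

DEFAULT_EPOCH_WINDOW = (-0.2, 0.4)
DEFAULT_BASELINE = (-0.05, 0.0)


def epoch(
    data: np.ndarray,
    sample_rate: float,
    onsets: np.ndarray,
    *,
    subject_id: str = "",
    eye: str = "OS",
    channel_labels=None,
    window: tuple[float, float] = DEFAULT_EPOCH_WINDOW,
) -> EpochedRecording:
    """Cut a continuous record (channels x samples) into stimulus-locked epochs.

    Trial *i* is aligned so that t = 0 falls on ``onsets[i]`` (seconds from
    record start); sampling is half-open ``[start, end)``.  Onsets whose
    epoch would run off either edge of the record are dropped with a logged
    warning; an error is raised only if no usable trial remains.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_total = data.shape
    if channel_labels is None:
        channel_labels = tuple(f"CH{i + 1}" for i in range(n_ch))
    n_samp = n_epoch_samples(window, sample_rate)
    trials, dropped = [], 0
    for onset in np.asarray(onsets, dtype=float):
        i0 = int(round((onset + window[0]) * sample_rate))
        if i0 < 0 or i0 + n_samp > n_total:
            dropped += 1
            continue
        trials.append(data[:, i0 : i0 + n_samp])
    if dropped:
        log.warning("dropped %d/%d onsets too close to record edge", dropped, len(onsets))
    if not trials:
        raise ValueError("no onset leaves room for a full epoch window")
    return EpochedRecording(
        subject_id=subject_id,
        eye=eye,
        sample_rate=sample_rate,
        window=window,
        data=np.stack(trials),
        channel_labels=channel_labels,
    )


def baseline_correct(
    epochs: EpochedRecording, baseline: tuple[float, float] = DEFAULT_BASELINE
) -> EpochedRecording:
    """Subtract the per-trial, per-channel mean over the baseline window.

    After correction the mean of every trial/channel over the baseline
    window is zero to numerical precision.
    """
    mask = window_mask(epochs.times, baseline)
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def design_highpass_fir(
    sample_rate: float, cutoff: float = 0.1, transition: float = 0.2
) -> np.ndarray:
    """Blackman-windowed sinc high-pass FIR taps.

    Kernel length follows the Blackman-window rule numtaps ~= 5.5 * fs /
    transition_bandwidth (forced odd so the linear-phase filter is type I
    and can be applied with zero net delay).
    """
    numtaps = int(np.ceil(5.5 * sample_rate / transition))
    numtaps += 1 - numtaps % 2
    return signal.firwin(
        numtaps, cutoff, window="blackman", pass_zero=False, fs=sample_rate
    )


def highpass_filter(
    data: np.ndarray,
    sample_rate: float,
    cutoff: float = 0.1,
    transition: float = 0.2,
) -> np.ndarray:
    """Zero-phase 0.1 Hz high-pass of a continuous record (last axis = time).

    The symmetric FIR is applied by 'same'-mode convolution, which cancels
    the group delay; edge regions shorter than half the kernel are
    transient and should be discarded by subsequent epoching.
    """
    data = np.asarray(data, dtype=float)
    taps = design_highpass_fir(sample_rate, cutoff, transition)
    if data.shape[-1] < taps.size:
        raise ValueError(
            f"record ({data.shape[-1]} samples) shorter than filter kernel ({taps.size})"
        )
    out = np.apply_along_axis(
        lambda x: signal.oaconvolve(x, taps, mode="same"), -1, data
    )
    return out


def lowpass_filter(vep: VEPWaveform, cutoff: float = 35.0, order: int = 4) -> VEPWaveform:
    """Zero-phase Butterworth low-pass of an averaged VEP waveform."""
    nyq = vep.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=vep.sample_rate, output="sos")
    return replace(vep, data=signal.sosfiltfilt(sos, vep.data, axis=-1))


def average_trials(epochs: EpochedRecording) -> VEPWaveform:
    """Arithmetic mean across trials -> the VEP waveform."""
    return VEPWaveform(
        subject_id=epochs.subject_id,
        eye=epochs.eye,
        sample_rate=epochs.sample_rate,
        window=epochs.window,
        data=epochs.data.mean(axis=0),
        channel_labels=epochs.channel_labels,
    )


def rereference(data: np.ndarray, channel_labels, mode: str = "none") -> np.ndarray:
    """Optional re-referencing: 'none', 'average' or a channel label (e.g. 'CZ').

    The downstream differential activity (left-mean minus right-mean) is
    invariant to any common reference, so this is a convenience for
    inspecting single-channel waveforms, not a required stage.
    """
    data = np.asarray(data, dtype=float)
    if mode == "none":
        return data
    if mode == "average":
        return data - data.mean(axis=-2, keepdims=True)
    labels = list(channel_labels)
    if mode in labels:
        ref = data[..., labels.index(mode), :]
        return data - ref[..., None, :]
    raise ValueError(f"unknown reference {mode!r}")


def preprocess_epochs(
    epochs: EpochedRecording,
    *,
    baseline: tuple[float, float] | None = DEFAULT_BASELINE,
    lowpass: float | None = 35.0,
) -> VEPWaveform:
    """Baseline-correct, average, and (optionally) low-pass an epoch stack."""
    if baseline is not None:
        epochs = baseline_correct(epochs, baseline)
    vep = average_trials(epochs)
    if lowpass is not None:
        vep = lowpass_filter(vep, lowpass)
    return vep
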