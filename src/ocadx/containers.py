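"""In-memory containers for epoched EEG and trial-averaged VEP waveforms.

Data are stored in microvolts throughout.  Epochs follow the half-open
sampling convention: an epoch over ``[start, end)`` at sampling rate ``fs``
holds ``round((end - start) * fs)`` samples at times ``start + i / fs``;
the sample at t = 0 (stimulus onset) belongs to the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Eye labels: OS = oculus sinister (left eye), OD = oculus dexter (right).
EYES = ("OS", "OD")


def n_epoch_samples(window: tuple[float, float], sample_rate: float) -> int:
    """Number of samples in a half-open epoch window ``[start, end)``."""
    start, end = window
    if end <= start:
        raise ValueError(f"empty epoch window {window!r}")
    return int(round((end - start) * sample_rate))


def epoch_times(window: tuple[float, float], sample_rate: float) -> np.ndarray:
    """Sample times (s, relative to stimulus onset) of an epoch window."""
    n = n_epoch_samples(window, sample_rate)
    return window[0] + np.arange(n) / sample_rate


def window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples inside a *closed* analysis window.

    A half-sample tolerance absorbs floating-point jitter so that a sample
    nominally at a window edge (e.g. t = 0.07 s) is always included.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError(f"window {window!r} has hi < lo")
    dt = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    eps = 0.499 * dt
    mask = (times >= lo - eps) & (times <= hi + eps)
    if not mask.any():
        raise ValueError(f"window {window!r} contains no samples")
    return mask


@dataclass
class EpochedRecording:
    """Per-eye stack of stimulus-locked EEG epochs (trials x channels x samples)."""

    subject_id: str
    eye: str
    sample_rate: float
    window: tuple[float, float]
    data: np.ndarray
    channel_labels: tuple[str, ...]
    #: trials averaged into each row of ``data`` (1 unless pre-averaged)
    trials_per_row: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.window = (float(self.window[0]), float(self.window[1]))
        self.channel_labels = tuple(self.channel_labels)
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_s = self.data.shape
        if n_tr < 1:
            raise ValueError("at least one trial required")
        if n_ch != len(self.channel_labels):
            raise ValueError("channel_labels length does not match data")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        expected = n_epoch_samples(self.window, self.sample_rate)
        if n_s != expected:
            raise ValueError(
                f"window {self.window} at {self.sample_rate} Hz implies "
                f"{expected} samples, data has {n_s}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return epoch_times(self.window, self.sample_rate)


@dataclass
class VEPWaveform:
    """Trial-averaged visual evoked potential (channels x samples, microvolts)."""

    subject_id: str
    eye: str
    sample_rate: float
    window: tuple[float, float]
    data: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.window = (float(self.window[0]), float(self.window[1]))
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length does not match data")
        expected = n_epoch_samples(self.window, self.sample_rate)
        if self.data.shape[1] != expected:
            raise ValueError("sample count inconsistent with window/sample_rate")

    @property
    def times(self) -> np.ndarray:
        return epoch_times(self.window, self.sample_rate)

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in waveform") from None
        return self.data[idx]
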