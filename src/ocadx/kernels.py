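"""Evoked-response kernel and EEG noise models used by the simulator.

The evoked kernel is a difference of two gamma-shaped lobes, the standard
parametric morphology for transient evoked responses: a positive lobe
peaking at the pattern-onset latency (default 100 ms) followed by a smaller
negative undershoot.  Each lobe ``g(t; tau, p) = (t/tau)^p * exp(p*(1 - t/tau))``
is normalised to peak value 1 at ``t = tau`` and vanishes for t <= 0, so the
kernel is causal and identically zero over any pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KernelShape:
    """Shape parameters of the difference-of-gammas evoked kernel.

    ``peak_latency`` is the latency (s) of the positive lobe; the undershoot
    peaks at ``undershoot_latency_factor * peak_latency`` with relative
    amplitude ``undershoot_ratio``.  Sharpness exponents control lobe width.
    """

    peak_latency: float = 0.10
    sharpness: float = 8.0
    undershoot_ratio: float = 0.35
    undershoot_latency_factor: float = 1.85
    undershoot_sharpness: float = 10.0


def _gamma_lobe(t: np.ndarray, tau: float, p: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    x = t[pos] / tau
    out[pos] = x**p * np.exp(p * (1.0 - x))
    return out


def evoked_kernel(t: np.ndarray, shape: KernelShape = KernelShape()) -> np.ndarray:
    """Evaluate the unit-amplitude evoked kernel k(t) at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    tau2 = shape.undershoot_latency_factor * shape.peak_latency
    return _gamma_lobe(t, shape.peak_latency, shape.sharpness) - (
        shape.undershoot_ratio * _gamma_lobe(t, tau2, shape.undershoot_sharpness)
    )


def white_noise(rng: np.random.Generator, size: tuple[int, ...]) -> np.ndarray:
    """Unit-variance Gaussian white noise."""
    return rng.standard_normal(size)


def pink_noise(rng: np.random.Generator, size: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f (power) noise along the last axis.

    Generated by spectrally shaping Gaussian white noise with amplitude
    1/sqrt(f); phases are therefore independent across channels/trials.
    The analytic variance of the shaped process is divided out, so the
    scaling does not depend on the realisation.
    """
    n = size[-1]
    if n < 2:
        return rng.standard_normal(size)
    w = rng.standard_normal(size)
    spec = np.fft.rfft(w, axis=-1)
    freqs = np.fft.rfftfreq(n)  # cycles/sample; absolute rate irrelevant
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * amp, n=n, axis=-1)
    # Var of irfft(W * a) for unit-variance white w: (a0^2 + 2*sum(mid^2) + any^2)/n
    a2 = amp**2
    interior = a2[1:-1] if n % 2 == 0 else a2[1:]
    var = (a2[0] + 2.0 * interior.sum() + (a2[-1] if n % 2 == 0 else 0.0)) / n
    return shaped / np.sqrt(var)


def eeg_noise(
    rng: np.random.Generator,
    size: tuple[int, ...],
    noise_sd: float,
    model: str = "one_over_f_plus_white",
    pink_fraction: float = 0.5,
) -> np.ndarray:
    """Additive EEG noise with total standard deviation ``noise_sd`` (uV).

    ``one_over_f_plus_white`` mixes independent pink and white components so
    that ``pink_fraction`` of the total variance is 1/f-distributed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return np.zeros(size)
    if model == "white":
        return noise_sd * white_noise(rng, size)
    if model == "one_over_f_plus_white":
        w = white_noise(rng, size)
        p = pink_noise(rng, size)
        return noise_sd * (
            np.sqrt(1.0 - pink_fraction) * w + np.sqrt(pink_fraction) * p
        )
    raise ValueError(f"unknown noise model {model!r}")
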