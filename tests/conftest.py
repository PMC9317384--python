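import numpy as np
import pytest

from ocadx.kernels import KernelShape
from ocadx.misrouting import default_montage
from ocadx.preprocess import preprocess_epochs
from ocadx.simulate import VepSimConfig, simulate_vep_cohort


def reference_kernel(t, shape: KernelShape = KernelShape()):
    """Independent re-statement of the documented evoked-kernel formula.

    Used as the oracle against the simulator: each gamma lobe is
    (t/tau)^p * exp(p*(1 - t/tau)) for t > 0, peak value 1 at t = tau;
    the kernel is lobe(peak) - ratio * lobe(undershoot).
    """
    t = np.asarray(t, dtype=float)

    def lobe(tau, p):
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = (t[pos] / tau) ** p * np.exp(p * (1 - t[pos] / tau))
        return out

    return lobe(shape.peak_latency, shape.sharpness) - shape.undershoot_ratio * lobe(
        shape.undershoot_latency_factor * shape.peak_latency,
        shape.undershoot_sharpness,
    )


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def noiseless_misrouted_subject():
    cfg = VepSimConfig(
        n_subjects=1, asymmetry=0.5, evoked_amplitude=5.0, noise_sd=0.0, seed=7
    )
    return cfg, simulate_vep_cohort(cfg)[0]


@pytest.fixture(scope="session")
def noiseless_veps(noiseless_misrouted_subject):
    """Averaged OS/OD waveforms of the noiseless misrouted subject (no filtering)."""
    _, subj = noiseless_misrouted_subject
    return {
        eye: preprocess_epochs(rec, lowpass=None)
        for eye, rec in subj.recordings.items()
    }
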