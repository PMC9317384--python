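"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_vep_cohort` — lateralised monocular pattern-onset VEP
  epochs.  For eye *e* and hemisphere *h* the mean response is
  ``evoked_amplitude * w(e, h) * k(t)`` with the difference-of-gammas
  kernel ``k``; under misrouting the contralateral hemisphere gets weight
  ``(1 + asymmetry)/2`` and the ipsilateral ``(1 - asymmetry)/2`` (the
  laterality flips between eyes), under normal routing both weights are
  1/2.  Additive per-trial noise is white or 1/f+white.
* :func:`simulate_trio` — trio genotype configurations over the two common
  TYR polymorphisms and pathogenic variants, validated for Mendelian
  consistency.
* :func:`simulate_str_pedigree` — Mendelian transmission of microsatellite
  haplotypes across a non-recombining marker block to two siblings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EpochedRecording, window_mask, epoch_times
from .kernels import KernelShape, eeg_noise, evoked_kernel
from .variants import GT_STATES, TrioGenotype, check_mendelian

# ---------------------------------------------------------------------------
# VEP cohort simulation
# ---------------------------------------------------------------------------

#: analysis windows that any epoch window must contain
_REQUIRED_WINDOWS = ((-0.05, 0.0), (0.07, 0.1), (0.07, 0.3))


@dataclass(frozen=True)
class VepSimConfig:
    """Conditions of a simulated monocular-VEP cohort.

    Defaults reproduce the acquisition of the study population this
    package targets: 500 Hz sampling, epochs from -0.2 to 0.4 s, about
    498 +/- 51 pattern onsets per eye, evoked peak at 100 ms.
    """

    n_subjects: int = 8
    routing: str = "misrouted"  # or "normal"
    asymmetry: float = 0.5  # lateralisation index in [0, 1]
    evoked_amplitude: float = 5.0  # uV at the kernel peak
    noise_sd: float = 20.0  # uV per trial and channel
    noise_model: str = "one_over_f_plus_white"
    n_trials_mean: float = 498.0
    n_trials_sd: float = 51.0
    sample_rate: float = 500.0
    epoch_window: tuple[float, float] = (-0.2, 0.4)
    peak_latency: float = 0.10
    n_channels_per_side: int = 9
    kernel: KernelShape | None = None
    trial_mode: str = "trials"  # or "average": draw the trial mean directly
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.routing not in ("misrouted", "normal"):
            raise ValueError("routing must be 'misrouted' or 'normal'")
        if self.trial_mode not in ("trials", "average"):
            raise ValueError("trial_mode must be 'trials' or 'average'")
        lo, hi = self.epoch_window
        for wlo, whi in _REQUIRED_WINDOWS:
            if wlo < lo or whi > hi:
                raise ValueError(
                    f"epoch window {self.epoch_window} does not contain the "
                    f"required analysis window ({wlo}, {whi})"
                )

    @property
    def kernel_shape(self) -> KernelShape:
        if self.kernel is not None:
            return self.kernel
        return KernelShape(peak_latency=self.peak_latency)

    @property
    def channel_labels(self) -> tuple[str, ...]:
        n = self.n_channels_per_side
        return tuple(f"OL{i + 1}" for i in range(n)) + tuple(
            f"OR{i + 1}" for i in range(n)
        )


@dataclass
class SimulatedSubject:
    """One subject's OS/OD epoch stacks plus the generating ground truth."""

    subject_id: str
    routing: str
    asymmetry: float
    recordings: dict = field(default_factory=dict)  # eye -> EpochedRecording


def hemisphere_weight(routing: str, asymmetry: float, eye: str, side: str) -> float:
    """Mean-response weight w(e, h) for eye in {OS, OD}, side in {left, right}.

    Misrouted: the hemisphere contralateral to the stimulated eye receives
    (1 + a)/2, the ipsilateral (1 - a)/2.  OS (left eye) is contralateral
    to the right hemisphere.  Normal routing: 1/2 everywhere.
    """
    if routing == "normal":
        return 0.5
    contra = "right" if eye == "OS" else "left"
    return (1.0 + asymmetry) / 2.0 if side == contra else (1.0 - asymmetry) / 2.0


def _draw_n_trials(rng: np.random.Generator, cfg: VepSimConfig) -> int:
    n = int(round(rng.normal(cfg.n_trials_mean, cfg.n_trials_sd)))
    return max(n, 1)


def simulate_vep_cohort(cfg: VepSimConfig) -> list[SimulatedSubject]:
    """Simulate one epoched recording per subject and eye.

    Bit-reproducible for a given config: a single seed sequence is split
    into per-subject substreams.  In ``trial_mode='average'`` the trial
    count n is drawn exactly as in ``'trials'`` mode but the stack holds a
    single row: the trial average, whose noise is drawn with sd/sqrt(n) —
    the exact sampling distribution of the mean under either noise model,
    at a fraction of the cost.
    """
    times = epoch_times(cfg.epoch_window, cfg.sample_rate)
    k = evoked_kernel(times, cfg.kernel_shape)
    labels = cfg.channel_labels
    sides = ["left"] * cfg.n_channels_per_side + ["right"] * cfg.n_channels_per_side
    subjects = []
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    for s_idx, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        subj = SimulatedSubject(
            subject_id=f"S{s_idx + 1:03d}", routing=cfg.routing, asymmetry=cfg.asymmetry
        )
        for eye in ("OS", "OD"):
            n_trials = _draw_n_trials(rng, cfg)
            mean = np.stack(
                [
                    cfg.evoked_amplitude
                    * hemisphere_weight(cfg.routing, cfg.asymmetry, eye, side)
                    * k
                    for side in sides
                ]
            )  # channels x samples
            if cfg.trial_mode == "average":
                noise = eeg_noise(
                    rng,
                    (1, len(labels), times.size),
                    cfg.noise_sd / np.sqrt(n_trials),
                    cfg.noise_model,
                )
                data = mean[None, :, :] + noise
                rows = 1
            else:
                noise = eeg_noise(
                    rng, (n_trials, len(labels), times.size), cfg.noise_sd, cfg.noise_model
                )
                data = mean[None, :, :] + noise
                rows = n_trials
            subj.recordings[eye] = EpochedRecording(
                subject_id=subj.subject_id,
                eye=eye,
                sample_rate=cfg.sample_rate,
                window=cfg.epoch_window,
                data=data,
                channel_labels=labels,
                trials_per_row=n_trials if cfg.trial_mode == "average" else 1,
            )
        subjects.append(subj)
    return subjects


def expected_chiasm_coefficient(
    cfg: VepSimConfig, window: tuple[float, float] = (0.07, 0.1)
) -> float:
    """Noise-free chiasm coefficient implied by the simulator contract.

    D_OS(t) = -a*A*k(t) and D_OD(t) = +a*A*k(t), so
    CC = -2 * a * A * mean of k(t) over the window (0 for normal routing).
    """
    if cfg.routing == "normal":
        return 0.0
    times = epoch_times(cfg.epoch_window, cfg.sample_rate)
    k = evoked_kernel(times, cfg.kernel_shape)
    kbar = float(k[window_mask(times, window)].mean())
    return -2.0 * cfg.asymmetry * cfg.evoked_amplitude * kbar


def continuous_from_epochs(
    cfg: VepSimConfig, subject: SimulatedSubject, eye: str, isi: float = 0.48
) -> tuple[np.ndarray, np.ndarray]:
    """Render one eye's epochs as a continuous record plus onset times.

    Stimulus onsets are spaced ``isi`` seconds apart (the 40 ms ON / 440 ms
    OFF presentation cycle), wide enough that consecutive evoked responses
    do not overlap within the analysis windows.  Returns (channels x
    samples array, onset seconds).  Useful for exercising the epoching and
    high-pass stages on synthetic data.
    """
    rec = subject.recordings[eye]
    fs = rec.sample_rate
    n_ep = rec.data.shape[2]
    pre = int(round(-rec.window[0] * fs))
    step = int(round(isi * fs))
    n_total = pre + step * rec.n_trials + n_ep
    out = np.zeros((len(rec.channel_labels), n_total))
    onsets = []
    for i in range(rec.n_trials):
        i0 = i * step
        out[:, i0 : i0 + n_ep] = rec.data[i]
        onsets.append((i0 + pre) / fs)
    return out, np.asarray(onsets)


# ---------------------------------------------------------------------------
# Trio genotype simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrioConfig:
    """A family's genotype configuration over named variants.

    ``genotypes`` maps variant name -> {role -> state} with roles proband/
    father/mother and states WT/Het/Hom.  ``true_phase`` optionally maps a
    variant name to 'paternal'/'maternal' (ground truth for Het variants).
    """

    family_id: str
    genotypes: dict
    true_phase: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, roles in self.genotypes.items():
            for role, state in roles.items():
                if role not in ("proband", "father", "mother"):
                    raise ValueError(f"unknown role {role!r} for {var}")
                if state not in GT_STATES:
                    raise ValueError(f"unknown genotype state {state!r} for {var}")


def simulate_trio(cfg: TrioConfig) -> list[TrioGenotype]:
    """Emit the configured trio genotypes after Mendelian validation.

    Raises ValueError naming the first variant whose configuration is not
    producible by one paternal plus one maternal transmitted allele, and
    checks any declared true phase against the genotypes.
    """
    trios = []
    for var, roles in cfg.genotypes.items():
        trio = TrioGenotype(
            variant=var,
            proband=roles.get("proband", "WT"),
            father=roles.get("father", "WT"),
            mother=roles.get("mother", "WT"),
        )
        if check_mendelian(trio) != "consistent":
            raise ValueError(
                f"family {cfg.family_id}: variant {var} configuration "
                f"({trio.proband}/{trio.father}/{trio.mother}) violates "
                "Mendelian inheritance"
            )
        phase = cfg.true_phase.get(var)
        if phase is not None:
            carrier = {"paternal": trio.father, "maternal": trio.mother}[phase]
            if trio.proband != "Het" or carrier == "WT":
                raise ValueError(
                    f"family {cfg.family_id}: declared phase of {var} is "
                    "inconsistent with the genotypes"
                )
        trios.append(trio)
    return trios


# ---------------------------------------------------------------------------
# STR pedigree simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrPedigreeConfig:
    """Parental STR haplotypes and the per-sibling transmission pattern.

    ``paternal``/``maternal``: two equal-length integer allele vectors
    (repeat sizes), one per parental haplotype, across the marker block.
    ``transmission``: per sibling, the (paternal_index, maternal_index)
    haplotype transmitted — e.g. ``{"sib1": (0, 0), "sib2": (0, 0)}``.
    The interval is treated as a single non-recombinant linkage block.
    """

    paternal: tuple[tuple[int, ...], tuple[int, ...]]
    maternal: tuple[tuple[int, ...], tuple[int, ...]]
    transmission: dict = field(
        default_factory=lambda: {"sib1": (0, 0), "sib2": (0, 0)}
    )
    marker_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        lens = {len(h) for h in (*self.paternal, *self.maternal)}
        if len(lens) != 1:
            raise ValueError("all parental haplotypes must cover the same markers")
        (n,) = lens
        if self.marker_names is not None and len(self.marker_names) != n:
            raise ValueError("marker_names length mismatch")
        for sib, (pi, mi) in self.transmission.items():
            if pi not in (0, 1) or mi not in (0, 1):
                raise ValueError(f"transmission indices for {sib} must be 0 or 1")
        for hap in (*self.paternal, *self.maternal):
            if any(a <= 0 for a in hap):
                raise ValueError("allele repeat sizes must be positive integers")

    @property
    def n_markers(self) -> int:
        return len(self.paternal[0])

    @property
    def markers(self) -> tuple[str, ...]:
        if self.marker_names is not None:
            return self.marker_names
        return tuple(f"M{i + 1}" for i in range(self.n_markers))


def default_str_config(seed: int = 0, n_markers: int = 9) -> StrPedigreeConfig:
    """Random fully-heterozygous parental haplotypes over ``n_markers`` markers."""
    rng = np.random.default_rng(seed)
    base = rng.integers(120, 200, size=n_markers)
    haps = [tuple(int(b + 2 * k) for b in base) for k in range(4)]
    return StrPedigreeConfig(
        paternal=(haps[0], haps[1]), maternal=(haps[2], haps[3])
    )


def simulate_str_pedigree(cfg: StrPedigreeConfig) -> dict:
    """Genotypes for father, mother and each configured sibling.

    Returns {individual -> {marker -> (allele1, allele2)}} with parental
    genotypes being the union of their two haplotypes and each sibling the
    union of the transmitted paternal and maternal haplotype, marker by
    marker (unordered pairs, stored sorted).
    """
    markers = cfg.markers
    out = {
        "father": {
            m: tuple(sorted((cfg.paternal[0][i], cfg.paternal[1][i])))
            for i, m in enumerate(markers)
        },
        "mother": {
            m: tuple(sorted((cfg.maternal[0][i], cfg.maternal[1][i])))
            for i, m in enumerate(markers)
        },
    }
    for sib, (pi, mi) in cfg.transmission.items():
        out[sib] = {
            m: tuple(sorted((cfg.paternal[pi][i], cfg.maternal[mi][i])))
            for i, m in enumerate(markers)
        }
    return out
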