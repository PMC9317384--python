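"""Optic-pathway misrouting indexes from monocular pattern-onset VEPs.

In albinism, retinal fibres decussate excessively at the chiasm, so
monocular stimulation drives the *contralateral* occipital cortex more than
the ipsilateral one.  With a left (OL) and right (OR) set of occipital
electrodes, the differential activity D(t) = mean(OL) - mean(OR) therefore
has opposite sign for left-eye (OS) and right-eye (OD) stimulation:

* chiasm coefficient  CC = mean_[70,100 ms] D_OS - mean_[70,100 ms] D_OD,
  negative when the contralateral hemisphere dominates;
* interocular Pearson correlation r between D_OS(t) and D_OD(t) over
  [70, 300] ms, negative under misrouting.

A subject is classified misrouted when both indexes are negative and the
correlation is significant (two-tailed p <= alpha).  Analysis windows are
closed intervals sampled at the native rate; the sample at exactly 0.07 s
belongs to both windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import VEPWaveform, window_mask

CHIASM_WINDOW = (0.07, 0.10)
CORRELATION_WINDOW = (0.07, 0.30)


@dataclass(frozen=True)
class Montage:
    """Left/right occipital electrode sets (disjoint, equal size)."""

    left: tuple[str, ...]
    right: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", tuple(self.left))
        object.__setattr__(self, "right", tuple(self.right))
        if len(self.left) != len(self.right):
            raise ValueError("left and right electrode sets must have equal size")
        if set(self.left) & set(self.right):
            raise ValueError("left and right electrode sets must be disjoint")

    def swapped(self) -> "Montage":
        return Montage(left=self.right, right=self.left)


def default_montage(n: int = 9) -> Montage:
    """Synthetic occipital montage OL1..OLn / OR1..ORn."""
    return Montage(
        left=tuple(f"OL{i + 1}" for i in range(n)),
        right=tuple(f"OR{i + 1}" for i in range(n)),
    )


@dataclass
class DifferentialActivity:
    """D(t) = mean over left set - mean over right set, one eye."""

    subject_id: str
    eye: str
    times: np.ndarray
    values: np.ndarray


@dataclass
class MisroutingResult:
    """Per-subject misrouting indexes and classification.

    ``misrouted`` is None (status 'indeterminate') when the correlation is
    undefined because one differential trace has zero variance.
    """

    subject_id: str
    chiasm_coefficient: float
    pearson_r: float
    p_value: float
    misrouted: bool | None
    mean_D_OS: float
    mean_D_OD: float
    status: str = "ok"


@dataclass
class GroupMisroutingStats:
    """Paired two-tailed t-test of mean_D_OS vs mean_D_OD across subjects."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    coefficients: np.ndarray = field(default_factory=lambda: np.array([]))


def differential_activity(vep: VEPWaveform, montage: Montage) -> DifferentialActivity:
    """Mean left-set signal minus mean right-set signal, per sample."""
    missing = [c for c in (*montage.left, *montage.right) if c not in vep.channel_labels]
    if missing:
        raise KeyError(f"montage channels missing from waveform: {missing}")
    idx_l = [vep.channel_labels.index(c) for c in montage.left]
    idx_r = [vep.channel_labels.index(c) for c in montage.right]
    d = vep.data[idx_l].mean(axis=0) - vep.data[idx_r].mean(axis=0)
    return DifferentialActivity(
        subject_id=vep.subject_id, eye=vep.eye, times=vep.times, values=d
    )


def _check_aligned(d_os: DifferentialActivity, d_od: DifferentialActivity) -> None:
    if d_os.times.shape != d_od.times.shape or not np.allclose(d_os.times, d_od.times):
        raise ValueError("OS and OD differential activities must share a time axis")


def mean_in_window(d: DifferentialActivity, window: tuple[float, float]) -> float:
    return float(d.values[window_mask(d.times, window)].mean())


def chiasm_coefficient(
    d_os: DifferentialActivity,
    d_od: DifferentialActivity,
    window: tuple[float, float] = CHIASM_WINDOW,
) -> float:
    """Difference of windowed mean differential activity between eyes (uV).

    Negative values indicate contralateral dominance, i.e. misrouting;
    swapping eye labels changes the sign exactly.
    """
    _check_aligned(d_os, d_od)
    return mean_in_window(d_os, window) - mean_in_window(d_od, window)


def _effective_n(x: np.ndarray, y: np.ndarray) -> float:
    """Bartlett effective sample size for the correlation of two series.

    Var(r) of two independent autocorrelated series is approximately
    (1/n) * sum_k rho_x(k) * rho_y(k); the equivalent number of
    independent samples is n / (1 + 2 * sum_{k>0} (1 - k/n) rho_x rho_y),
    estimated from the sample autocorrelations up to lag n/3.
    """
    n = x.size
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    k_max = n // 3
    lags = np.arange(1, k_max + 1)
    rho_x = np.array([(xc[:-k] @ xc[k:]) / n for k in lags])
    rho_y = np.array([(yc[:-k] @ yc[k:]) / n for k in lags])
    factor = 1.0 + 2.0 * np.sum((1.0 - lags / n) * rho_x * rho_y)
    factor = max(factor, 1.0 / n)  # guard against negative estimates
    return float(np.clip(n / factor, 3.0, n))


def interocular_correlation(
    d_os: DifferentialActivity,
    d_od: DifferentialActivity,
    window: tuple[float, float] = CORRELATION_WINDOW,
    *,
    autocorr_correction: bool = True,
) -> tuple[float, float]:
    """Pearson r between D_OS(t) and D_OD(t) across samples in the window.

    The two-tailed p-value comes from the t distribution.  By default the
    degrees of freedom use the Bartlett effective sample size, because
    band-limited EEG samples are strongly autocorrelated and the naive
    sample count makes the test anti-conservative; pass
    ``autocorr_correction=False`` for the textbook n - 2 df.  Returns
    (nan, nan) when either series has zero variance in the window — the
    correlation is undefined, not zero.
    """
    _check_aligned(d_os, d_od)
    mask = window_mask(d_os.times, window)
    x, y = d_os.values[mask], d_od.values[mask]
    if x.size < 3:
        raise ValueError("correlation window must contain at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if autocorr_correction:
        n_eff = _effective_n(x, y)
        df = n_eff - 2.0
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt(df / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def classify_misrouting(
    chiasm: float, pearson_r: float, p_value: float, alpha: float = 0.05
) -> bool | None:
    """Misrouted iff r < 0 and p <= alpha and the chiasm coefficient < 0.

    Returns None (indeterminate) when the correlation is undefined.
    """
    if math.isnan(pearson_r) or math.isnan(p_value):
        return None
    return bool(pearson_r < 0 and p_value <= alpha and chiasm < 0)


def evaluate_waveform_pair(
    vep_os: VEPWaveform,
    vep_od: VEPWaveform,
    montage: Montage,
    *,
    alpha: float = 0.05,
    chiasm_window: tuple[float, float] = CHIASM_WINDOW,
    correlation_window: tuple[float, float] = CORRELATION_WINDOW,
) -> MisroutingResult:
    """Full per-subject misrouting assessment from averaged OS/OD waveforms."""
    if {vep_os.eye, vep_od.eye} != {"OS", "OD"}:
        raise ValueError("need one OS and one OD waveform")
    if vep_os.eye == "OD":
        vep_os, vep_od = vep_od, vep_os
    d_os = differential_activity(vep_os, montage)
    d_od = differential_activity(vep_od, montage)
    cc = chiasm_coefficient(d_os, d_od, chiasm_window)
    r, p = interocular_correlation(d_os, d_od, correlation_window)
    verdict = classify_misrouting(cc, r, p, alpha)
    return MisroutingResult(
        subject_id=vep_os.subject_id,
        chiasm_coefficient=cc,
        pearson_r=r,
        p_value=p,
        misrouted=verdict,
        mean_D_OS=mean_in_window(d_os, chiasm_window),
        mean_D_OD=mean_in_window(d_od, chiasm_window),
        status="ok" if verdict is not None else "indeterminate",
    )


def group_chiasm_ttest(
    mean_d_os: np.ndarray, mean_d_od: np.ndarray
) -> GroupMisroutingStats:
    """Two-tailed paired t-test of the per-subject windowed means.

    Equivalent to a one-sample t-test of the chiasm coefficients against
    zero; df = n_subjects - 1 (n = 8 patients gives t(7)).
    """
    a = np.asarray(mean_d_os, dtype=float)
    b = np.asarray(mean_d_od, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired per-subject values required")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 subjects for a paired t-test")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff, 0.0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(a, b)
    return GroupMisroutingStats(
        t_statistic=float(t_stat),
        degrees_of_freedom=n - 1,
        p_value=float(p),
        coefficients=diff,
    )
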