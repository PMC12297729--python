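"""Current-clamp analysis: activity coding, passive properties, spike morphometry.

Induced activity is coded on the five-level scale used for step-evoked
firing in immature human neurons:

* ``Quiet`` — no significant excursion from baseline during the step;
* ``AttemptingSingle`` — excursions present but none overshoots 0 mV;
* ``Single`` — exactly one excursion and it overshoots 0 mV;
* ``AttemptingTrain`` — several excursions, exactly one overshooting;
* ``Train`` — several excursions, at least two overshooting.

A neuron's class over a step family is the maximum sweep class under the
ordering Quiet < AttemptingSingle < Single < AttemptingTrain < Train.
Non-induced (stimulus-free) activity is coded Quiet vs Spontaneous.  The
0-mV overshoot criterion is absolute (a voltage, not a baseline-relative
offset).

Spike threshold is operationalized as the voltage at the peak of the
third time-derivative of voltage during the upstroke, computed on a
polynomial-smoothed trace; amplitude, overshoot, half-width and maximal
depolarization rate follow from it.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import MorphologyError, ProtocolError, ValidationError
from .io import StimulusStep, SweepSet, TimeSeriesTrace

__all__ = [
    "ActivityClass",
    "Excursion",
    "SpikeFeatures",
    "PassiveProperties",
    "detect_excursions",
    "classify_sweep",
    "classify_induced",
    "classify_spontaneous",
    "resting_vm",
    "input_resistance",
    "extract_spike_features",
    "cohort_feature_table",
    "DEFAULT_MIN_RISE",
    "DEFAULT_SMOOTH_WINDOW_MS",
]

#: minimum rise above the within-step baseline (mV) for a "significant excursion"
DEFAULT_MIN_RISE = 15.0
#: polynomial smoothing window (ms) applied before differentiation
DEFAULT_SMOOTH_WINDOW_MS = 1.0
#: settling time (s) skipped before the within-step baseline window
_BASELINE_SETTLE_S = 2e-3
#: within-step baseline window length (s)
_BASELINE_WINDOW_S = 10e-3


class ActivityClass(enum.Enum):
    """Activity category; induced classes are ordered by maturity."""

    QUIET = "Quiet"
    ATTEMPTING_SINGLE = "AttemptingSingle"
    SINGLE = "Single"
    ATTEMPTING_TRAIN = "AttemptingTrain"
    TRAIN = "Train"
    SPONTANEOUS = "Spontaneous"

    @property
    def rank(self) -> int:
        return _INDUCED_ORDER.index(self) if self in _INDUCED_ORDER else -1

    def __lt__(self, other):
        if not isinstance(other, ActivityClass):
            return NotImplemented
        return self.rank < other.rank


_INDUCED_ORDER = [
    ActivityClass.QUIET,
    ActivityClass.ATTEMPTING_SINGLE,
    ActivityClass.SINGLE,
    ActivityClass.ATTEMPTING_TRAIN,
    ActivityClass.TRAIN,
]
INDUCED_CLASSES = tuple(_INDUCED_ORDER)
NONINDUCED_CLASSES = (ActivityClass.QUIET, ActivityClass.SPONTANEOUS)


@dataclass(frozen=True)
class Excursion:
    """One depolarizing deflection from the within-step baseline."""

    onset_index: int
    peak_index: int
    peak_v: float
    overshoots: bool

    def __post_init__(self):
        if self.onset_index > self.peak_index:
            raise ValidationError("onset_index must not exceed peak_index")
        if self.overshoots != (self.peak_v > 0.0):
            raise ValidationError("overshoots flag must equal (peak_v > 0 mV)")


@dataclass
class SpikeFeatures:
    """Morphometry of one action potential.

    ``overshoot`` equals ``peak_v`` (amount above 0 mV by convention);
    ``amplitude`` is threshold-to-peak; ``half_width`` is measured at
    threshold + amplitude/2; ``depol_rate`` is the maximal dV/dt between
    threshold and peak, in V/s.
    """

    threshold_v: float
    peak_v: float
    overshoot: float
    amplitude: float
    half_width: float
    depol_rate: float
    resting_vm: Optional[float] = None
    threshold_index: Optional[int] = None

    def __post_init__(self):
        if not (self.amplitude > 0):
            raise ValidationError("amplitude must be positive")
        if not (self.half_width > 0):
            raise ValidationError("half_width must be positive")
        if not (self.threshold_v < self.peak_v):
            raise ValidationError("threshold_v must be below peak_v")


@dataclass(frozen=True)
class PassiveProperties:
    resting_vm: float
    input_resistance: float

    def __post_init__(self):
        if not (self.input_resistance > 0):
            raise ValidationError("input_resistance must be positive")


# ---------------------------------------------------------------------------
# excursion detection and classification


def _window_indices(fs: float, t0: float, t1: float, n: int) -> tuple[int, int]:
    i0 = max(0, int(round(t0 * fs)))
    i1 = min(n, int(round(t1 * fs)))
    return i0, i1


def detect_excursions(
    sweep: TimeSeriesTrace,
    step: StimulusStep,
    min_rise: float = DEFAULT_MIN_RISE,
) -> list[Excursion]:
    """Find depolarizing excursions during a stimulus step.

    The within-step baseline is the median of the first 10 ms of the step
    response after a 2-ms settling interval; the scan starts after that
    baseline window (the settling transient itself is not an excursion).
    An excursion starts when the voltage exceeds baseline + ``min_rise``
    and ends when it falls back below baseline + ``min_rise``/2
    (hysteresis); successive excursions must be separated by such a
    return.  Returned in order of onset.
    """
    if sweep.unit != "mV":
        raise ProtocolError(f"excursion detection needs a voltage trace, got unit {sweep.unit!r}")
    fs = sweep.sampling_rate
    v = sweep.values
    on, off = _window_indices(fs, step.onset_time, step.offset_time, v.size)
    if step.duration < _BASELINE_SETTLE_S + _BASELINE_WINDOW_S:
        raise ProtocolError(
            f"step window {step.duration * 1e3:.1f} ms too short for baseline estimation"
        )
    b0, b1 = _window_indices(
        fs, step.onset_time + _BASELINE_SETTLE_S, step.onset_time + _BASELINE_SETTLE_S + _BASELINE_WINDOW_S, v.size
    )
    baseline = float(np.median(v[b0:b1]))
    return _scan_excursions(v, b1, off, baseline, min_rise)


def _scan_excursions(
    v: np.ndarray, start: int, stop: int, baseline: float, min_rise: float
) -> list[Excursion]:
    hi = baseline + min_rise
    lo = baseline + min_rise / 2.0
    out: list[Excursion] = []
    i = start
    in_event = False
    ev_start = start
    while i < stop:
        if not in_event:
            if v[i] >= hi:
                in_event = True
                # onset: walk back to the last sample below the lower level
                j = i
                while j > start and v[j - 1] >= lo:
                    j -= 1
                ev_start = j
        else:
            if v[i] < lo:
                seg = v[ev_start:i]
                peak_rel = int(np.argmax(seg))
                peak_v = float(seg[peak_rel])
                out.append(
                    Excursion(
                        onset_index=ev_start,
                        peak_index=ev_start + peak_rel,
                        peak_v=peak_v,
                        overshoots=peak_v > 0.0,
                    )
                )
                in_event = False
        i += 1
    if in_event:
        seg = v[ev_start:stop]
        peak_rel = int(np.argmax(seg))
        peak_v = float(seg[peak_rel])
        out.append(
            Excursion(
                onset_index=ev_start,
                peak_index=ev_start + peak_rel,
                peak_v=peak_v,
                overshoots=peak_v > 0.0,
            )
        )
    return out


def classify_sweep(excursions: list[Excursion]) -> ActivityClass:
    """Apply the five-level induced-activity rules to one sweep's excursions."""
    n = len(excursions)
    n_over = sum(e.overshoots for e in excursions)
    if n == 0:
        return ActivityClass.QUIET
    if n_over == 0:
        return ActivityClass.ATTEMPTING_SINGLE
    if n == 1:  # n_over == 1
        return ActivityClass.SINGLE
    if n_over == 1:
        return ActivityClass.ATTEMPTING_TRAIN
    return ActivityClass.TRAIN


def classify_induced(neuron: SweepSet, min_rise: float = DEFAULT_MIN_RISE) -> ActivityClass:
    """Code a neuron's induced activity over its current-step family.

    The neuron-level class is the maximum sweep class under the
    five-level ordering.
    """
    if neuron.mode != "current_clamp":
        raise ProtocolError(f"induced classification needs current_clamp mode, got {neuron.mode!r}")
    stepped = neuron.stepped_sweeps()
    if not stepped:
        raise ProtocolError("no sweeps with stimulus steps present")
    best = ActivityClass.QUIET
    for tr, st in stepped:
        cls = classify_sweep(detect_excursions(tr, st, min_rise))
        if best < cls:
            best = cls
    return best


def classify_spontaneous(neuron: SweepSet, min_rise: float = DEFAULT_MIN_RISE) -> ActivityClass:
    """Code non-induced activity: Spontaneous if any overshooting excursion
    occurs during a stimulus-free recording, else Quiet."""
    if neuron.mode != "current_clamp":
        raise ProtocolError(f"spontaneous coding needs current_clamp mode, got {neuron.mode!r}")
    free = neuron.stimulus_free_sweeps()
    if not free:
        raise ProtocolError("no stimulus-free recording present")
    for tr in free:
        baseline = float(np.median(tr.values))
        for exc in _scan_excursions(tr.values, 0, tr.values.size, baseline, min_rise):
            if exc.overshoots:
                return ActivityClass.SPONTANEOUS
    return ActivityClass.QUIET


# ---------------------------------------------------------------------------
# passive properties


def resting_vm(neuron: SweepSet, min_duration: float = 1.0) -> float:
    """Median voltage over the stimulus-free recording (robust to spontaneous
    spikes).  Requires at least ``min_duration`` seconds of stimulus-free data."""
    free = neuron.stimulus_free_sweeps()
    if not free:
        raise ProtocolError("no stimulus-free recording present")
    total = sum(tr.duration for tr in free)
    if total < min_duration:
        raise ProtocolError(
            f"stimulus-free segment too short: {total:.3f} s < {min_duration:g} s"
        )
    return float(np.median(np.concatenate([tr.values for tr in free])))


def input_resistance(sweep: TimeSeriesTrace, step: StimulusStep) -> float:
    """Input resistance (MΩ) from the voltage deflection of a hyperpolarizing
    current step: R = ΔV / I using the mean of the last 20% of the step as
    the steady state and the pre-step mean as baseline."""
    if step.level == 0:
        raise ZeroDivisionError("step level is 0 pA; input resistance undefined")
    if step.level > 0:
        raise ValidationError("input resistance requires a hyperpolarizing (negative) step")
    fs = sweep.sampling_rate
    v = sweep.values
    on, off = _window_indices(fs, step.onset_time, step.offset_time, v.size)
    tail0 = off - max(1, (off - on) // 5)
    baseline = float(np.mean(v[:on])) if on > 0 else float(v[0])
    steady = float(np.mean(v[tail0:off]))
    delta_v = steady - baseline  # mV
    r_mohm = delta_v / (step.level / 1000.0)  # mV / nA = MΩ
    if r_mohm == 0:
        warnings.warn("zero voltage deflection: input resistance 0 MΩ is implausible")
    return r_mohm


# ---------------------------------------------------------------------------
# spike morphometry


def _smooth(v: np.ndarray, fs: float, smooth_window_ms: float) -> np.ndarray:
    win = int(round(smooth_window_ms * 1e-3 * fs))
    win = max(win, 5)
    if win % 2 == 0:
        win += 1
    if win >= v.size:
        win = v.size - 1 if v.size % 2 == 0 else v.size - 2
    if win < 5:
        return v.astype(float)
    return savgol_filter(v, window_length=win, polyorder=3)


def _upstroke_start(vs: np.ndarray, lo: int, peak: int) -> int:
    """Last local minimum of the smoothed trace before the peak; falls back
    to the argmin of the search window for monotone rises."""
    if peak - lo < 3:
        raise MorphologyError("upstroke segment too short")
    seg = vs[lo:peak]
    d = np.diff(seg)
    # local minima: derivative changes from <=0 to >0
    minima = np.flatnonzero((d[:-1] <= 0) & (d[1:] > 0)) + 1
    if minima.size:
        return lo + int(minima[-1])
    return lo + int(np.argmin(seg))


def extract_spike_features(
    sweep: TimeSeriesTrace,
    excursion: Excursion,
    smooth_window_ms: float = DEFAULT_SMOOTH_WINDOW_MS,
    resting_vm: Optional[float] = None,
    max_subpeak_deficit: float = 10.0,
    search_back_ms: float = 50.0,
) -> SpikeFeatures:
    """Measure threshold, amplitude, overshoot, half-width and depolarization
    rate of one action potential.

    The upstroke runs from the last local minimum before the excursion peak
    to the peak.  Voltage is polynomial-smoothed (Savitzky–Golay, order 3,
    window ``smooth_window_ms``) before finite-difference differentiation;
    the threshold is the voltage at the maximum of d³V/dt³ on the
    upstroke's acceleration phase (up to the maximal dV/dt — threshold
    precedes the peak depolarization rate, and the rounding into the spike
    summit would otherwise contribute a spurious late d³ maximum).
    Half-width is the time between the two crossings of
    threshold + amplitude/2 flanking the peak, linearly interpolated to
    sub-sample precision.

    ``max_subpeak_deficit`` admits near-threshold spikes whose peak reaches
    within that many mV of 0 without overshooting.
    """
    if sweep.sampling_rate < 5000:
        raise ProtocolError(
            f"spike morphometry needs >= 5 kHz sampling, got {sweep.sampling_rate:g} Hz"
        )
    if not excursion.overshoots and excursion.peak_v < -max_subpeak_deficit:
        raise MorphologyError(
            f"excursion peak {excursion.peak_v:.1f} mV too far below 0 mV for spike analysis"
        )
    fs = sweep.sampling_rate
    v = sweep.values.astype(float)
    peak = excursion.peak_index
    lo = max(0, peak - int(round(search_back_ms * 1e-3 * fs)))
    lo = max(lo, excursion.onset_index - int(round(5e-3 * fs)))

    vs = _smooth(v, fs, smooth_window_ms)
    start = _upstroke_start(vs, lo, peak)
    peak_v = float(v[peak])
    if peak_v - vs[start] < 1.0:
        raise MorphologyError("no discernible upstroke (rise < 1 mV)")

    dt = 1.0 / fs
    d1 = np.gradient(vs, dt)
    d3 = np.gradient(np.gradient(d1, dt), dt)
    if peak - start < 4:
        raise MorphologyError("upstroke too short for third-derivative analysis")
    accel_end = start + int(np.argmax(d1[start:peak])) + 1
    if accel_end - start < 2:
        accel_end = peak
    thr_idx = start + int(np.argmax(d3[start:accel_end]))
    threshold_v = float(vs[thr_idx])
    amplitude = peak_v - threshold_v
    if amplitude <= 0:
        raise MorphologyError("non-positive spike amplitude")

    depol_rate = float(np.max(d1[thr_idx : peak + 1])) / 1000.0  # mV/s -> V/s

    half_level = threshold_v + amplitude / 2.0
    t_rise = _crossing_time(v, fs, thr_idx, peak, half_level, rising=True)
    t_fall = _crossing_time(v, fs, peak, v.size - 1, half_level, rising=False)
    if t_rise is None or t_fall is None:
        raise MorphologyError("half-amplitude level never re-crossed around the peak")
    half_width = (t_fall - t_rise) * 1e3  # s -> ms

    return SpikeFeatures(
        threshold_v=threshold_v,
        peak_v=peak_v,
        overshoot=peak_v,
        amplitude=amplitude,
        half_width=half_width,
        depol_rate=depol_rate,
        resting_vm=resting_vm,
        threshold_index=int(thr_idx),
    )


def _crossing_time(
    v: np.ndarray, fs: float, i0: int, i1: int, level: float, rising: bool
) -> Optional[float]:
    """Sub-sample time of the level crossing nearest the peak (last crossing
    for the rising flank, first for the falling flank)."""
    if rising:
        idx = None
        for i in range(i1 - 1, i0 - 1, -1):
            if v[i] < level <= v[i + 1]:
                idx = i
                break
        if idx is None:
            return None
    else:
        idx = None
        for i in range(i0, i1):
            if v[i] >= level > v[i + 1]:
                idx = i
                break
        if idx is None:
            return None
    frac = (level - v[idx]) / (v[idx + 1] - v[idx])
    return (idx + frac) / fs


# ---------------------------------------------------------------------------
# cohort tables


def cohort_feature_table(
    neurons: list[SweepSet],
    min_rise: float = DEFAULT_MIN_RISE,
    smooth_window_ms: float = DEFAULT_SMOOTH_WINDOW_MS,
) -> pd.DataFrame:
    """One row per neuron: activity class, passive properties, and the
    morphometry of the first qualifying spike (the first overshooting
    excursion in the lowest-current sweep containing one).  Neurons without
    a genuine spike get NaN feature columns."""
    if not neurons:
        raise ValidationError("cohort_feature_table needs at least one neuron")
    rows = []
    for neuron in neurons:
        row: dict = {
            "cell_id": neuron.cell_id,
            "group": neuron.group_label,
            "activity_class": classify_induced(neuron, min_rise).value,
            "resting_vm": np.nan,
            "threshold_v": np.nan,
            "peak_v": np.nan,
            "overshoot": np.nan,
            "amplitude": np.nan,
            "half_width": np.nan,
            "depol_rate": np.nan,
        }
        try:
            row["resting_vm"] = resting_vm(neuron)
        except ProtocolError:
            pass
        feats = _first_spike_features(neuron, min_rise, smooth_window_ms)
        if feats is not None:
            row.update(
                threshold_v=feats.threshold_v,
                peak_v=feats.peak_v,
                overshoot=feats.overshoot,
                amplitude=feats.amplitude,
                half_width=feats.half_width,
                depol_rate=feats.depol_rate,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _first_spike_features(
    neuron: SweepSet, min_rise: float, smooth_window_ms: float
) -> Optional[SpikeFeatures]:
    stepped = sorted(neuron.stepped_sweeps(), key=lambda pair: pair[1].level)
    for tr, st in stepped:
        for exc in detect_excursions(tr, st, min_rise):
            if exc.overshoots:
                try:
                    return extract_spike_features(tr, exc, smooth_window_ms)
                except (MorphologyError, ProtocolError):
                    return None
    return None
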