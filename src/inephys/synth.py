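"""Synthetic recordings with known ground truth.

Three generators emulate the recording conditions of a functional-maturation
study of iPSC-derived neurons:

* :func:`make_current_clamp_cohort` — families of 1-s current-injection
  steps (−10 to +190 pA from a hyperpolarized −80 mV holding level) whose
  sweeps contain templated action-potential excursions constructed so that
  each simulated neuron's activity class, by the classifier's own rules,
  equals the requested class.
* :func:`make_voltage_clamp_recording` — 80-ms voltage steps (−120 to
  +80 mV from −70 mV holding) carrying a transient inward Na⁺-like and a
  sustained outward K⁺-like current whose steady-state gating follows
  Boltzmann activation/inactivation curves with known parameters, plus the
  200-ms pre-pulse inactivation protocol (−120 to +80 mV in 5-mV steps,
  test step to 0 mV).
* :func:`make_fluorescence_trace` — 60-s fluorescence recordings at 5 Hz
  with a sinusoidal oscillation of known frequency and amplitude, linear
  drift and Gaussian noise.

Spikes are templated waveforms (logistic rise × exponential decay), not a
conductance-based membrane model: the classifier and morphometry need
controllable ground truth, not biophysical realism.  All generators are
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache
from typing import Optional

import numpy as np

from .current_clamp import ActivityClass
from .errors import ParameterError
from .io import StimulusStep, SweepSet, TimeSeriesTrace

__all__ = [
    "SpikeTemplateParams",
    "GatingGroundTruth",
    "CalciumGroundTruth",
    "make_current_clamp_cohort",
    "make_voltage_clamp_recording",
    "make_voltage_clamp_pair",
    "make_fluorescence_trace",
    "spike_waveform",
    "template_threshold_fraction",
    "spike_foot_for_threshold",
    "boltzmann",
    "closed_form_peak_iv",
    "gmax_for_peak_density",
    "DEFAULT_CURRENT_STEPS_PA",
    "DEFAULT_ACTIVATION_STEPS_MV",
    "DEFAULT_INACTIVATION_PREPULSES_MV",
]

#: default current-injection family: −10 … +190 pA, 20-pA increments
DEFAULT_CURRENT_STEPS_PA = tuple(float(i) for i in range(-10, 191, 20))
#: default activation voltage steps: −120 … +80 mV, 10-mV increments
DEFAULT_ACTIVATION_STEPS_MV = tuple(float(v) for v in range(-120, 81, 10))
#: default inactivation pre-pulse voltages: −120 … +80 mV, 5-mV increments
DEFAULT_INACTIVATION_PREPULSES_MV = tuple(float(v) for v in range(-120, 81, 5))


# ---------------------------------------------------------------------------
# ground-truth parameter containers


@dataclass(frozen=True)
class SpikeTemplateParams:
    """Shape parameters of the templated action potential.

    ``threshold_v`` is the operational threshold (voltage at the peak of
    the third time-derivative on the upstroke) the template is calibrated
    to; ``rise_tau``/``decay_tau`` are in ms.
    """

    threshold_v: float = -40.0
    peak_v: float = 25.0
    rise_tau: float = 0.8
    decay_tau: float = 4.0
    baseline_v: float = -80.0

    def __post_init__(self):
        if not (self.peak_v > self.threshold_v > self.baseline_v):
            raise ParameterError(
                "template requires peak_v > threshold_v > baseline_v, got "
                f"{self.peak_v}, {self.threshold_v}, {self.baseline_v}"
            )
        if not (self.rise_tau > 0 and self.decay_tau > 0):
            raise ParameterError("template time constants must be positive")
        if self.rise_tau >= self.decay_tau:
            raise ParameterError("rise_tau must be shorter than decay_tau")


@dataclass(frozen=True)
class GatingGroundTruth:
    """Boltzmann gating parameters of one voltage-gated conductance.

    ``gmax`` in nS; voltages in mV; ``h_act`` > 0 (activation increases
    with depolarization) and ``h_inact`` < 0 (availability decreases);
    ``kinetic_tau`` (activation) and ``kinetic_tau_inact`` in ms.
    """

    gmax: float
    v50_act: float
    h_act: float
    v50_inact: float
    h_inact: float
    e_rev: float
    kinetic_tau: float
    kinetic_tau_inact: float = 5.0

    def __post_init__(self):
        if not (self.gmax > 0):
            raise ParameterError(f"gmax must be > 0, got {self.gmax}")
        if not (self.h_act > 0):
            raise ParameterError(f"h_act must be > 0, got {self.h_act}")
        if not (self.h_inact < 0):
            raise ParameterError(f"h_inact must be < 0, got {self.h_inact}")
        if not (self.kinetic_tau > 0 and self.kinetic_tau_inact > 0):
            raise ParameterError("kinetic time constants must be positive")

    def act_inf(self, v) -> np.ndarray:
        """Steady-state activation."""
        return boltzmann(np.asarray(v, dtype=float), self.v50_act, self.h_act)

    def inact_inf(self, v) -> np.ndarray:
        """Steady-state availability (decreasing with depolarization)."""
        return boltzmann(np.asarray(v, dtype=float), self.v50_inact, self.h_inact)


@dataclass(frozen=True)
class CalciumGroundTruth:
    """Parameters of the simulated fluorescence signal (fractions of F0)."""

    f0: float = 100.0
    osc_freq: float = 0.05
    osc_amp: float = 0.3
    noise_sd: float = 0.05
    drift_slope: float = 0.0

    def __post_init__(self):
        if not (self.f0 > 0):
            raise ParameterError(f"f0 must be > 0, got {self.f0}")
        if self.osc_amp < 0 or self.noise_sd < 0:
            raise ParameterError("osc_amp and noise_sd must be non-negative")
        if self.osc_freq <= 0:
            raise ParameterError(f"osc_freq must be > 0, got {self.osc_freq}")


def boltzmann(v: np.ndarray, v50: float, h: float) -> np.ndarray:
    """Sigmoidal voltage dependence 1 / (1 + exp((v50 − v)/h)).

    Positive ``h`` gives a curve increasing with voltage (activation);
    negative ``h`` a decreasing one (inactivation/availability).
    """
    return 1.0 / (1.0 + np.exp(np.clip((v50 - np.asarray(v, float)) / h, -500, 500)))


# ---------------------------------------------------------------------------
# spike template


def _log_shape(x: np.ndarray, rho: float) -> np.ndarray:
    """log of sigmoid(x)·exp(−rho·x), computed overflow-safely."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0,
        -rho * x - np.log1p(np.exp(-np.clip(x, 0, None))),
        (1.0 - rho) * x - np.log1p(np.exp(np.clip(x, None, 0))),
    )
    return out


def _shape_peak(rho: float) -> tuple[float, float]:
    """(x, log-value) at the maximum of sigmoid(x)·exp(−rho·x)."""
    x_pk = np.log((1.0 - rho) / rho)
    return x_pk, float(_log_shape(np.array([x_pk]), rho)[0])


def spike_waveform(
    t: np.ndarray,
    tm: float,
    rise_tau_ms: float,
    decay_tau_ms: float,
    foot_v: float,
    peak_v: float,
) -> np.ndarray:
    """Evaluate one smooth (C-infinity) spike template.

    The shape is a logistic rise multiplied by an exponential decay,
    normalized so the waveform runs from ``foot_v`` (far before ``tm``)
    to exactly ``peak_v`` at its maximum.  ``t`` and ``tm`` in seconds,
    time constants in ms.
    """
    rho = rise_tau_ms / decay_tau_ms
    x = (np.asarray(t, float) - tm) / (rise_tau_ms * 1e-3)
    _, log_pk = _shape_peak(rho)
    g = np.exp(_log_shape(x, rho) - log_pk)
    return foot_v + (peak_v - foot_v) * g


@lru_cache(maxsize=32)
def _threshold_fraction(rho_key: int) -> float:
    """Fraction r of the foot-to-peak rise at which the third derivative of
    the template peaks, computed once on a dense grid; depends only on the
    rise/decay tau ratio."""
    rho = rho_key / 1_000_000.0
    x_pk, log_pk = _shape_peak(rho)
    x = np.arange(-14.0, x_pk, 1e-3)
    g = np.exp(_log_shape(x, rho) - log_pk)
    d1 = np.gradient(g, x)
    d3 = np.gradient(np.gradient(d1, x), x)
    # threshold lives in the acceleration phase: restrict to before max dV/dt
    # (the asymmetric summit produces a second, spurious d3 maximum);
    # skip edge samples where one-sided differences distort the estimate
    end = int(np.argmax(d1))
    idx = 5 + int(np.argmax(d3[5:end]))
    return float(g[idx])


def template_threshold_fraction(params: SpikeTemplateParams) -> float:
    rho = params.rise_tau / params.decay_tau
    return _threshold_fraction(int(round(rho * 1_000_000)))


def spike_foot_for_threshold(params: SpikeTemplateParams, peak_v: Optional[float] = None) -> float:
    """Foot (pre-spike plateau) voltage that places the template's
    operational threshold exactly at ``params.threshold_v``."""
    peak = params.peak_v if peak_v is None else peak_v
    r = template_threshold_fraction(params)
    foot = (params.threshold_v - r * peak) / (1.0 - r)
    return foot


# ---------------------------------------------------------------------------
# current-clamp cohort


def _passive_response(
    t: np.ndarray, step: StimulusStep, delta_v: float, tau_m_s: float
) -> np.ndarray:
    """RC-like voltage deflection of amplitude delta_v during the step."""
    v = np.zeros_like(t)
    on, off = step.onset_time, step.offset_time
    during = (t >= on) & (t < off)
    v[during] = delta_v * (1.0 - np.exp(-(t[during] - on) / tau_m_s))
    after = t >= off
    v_end = delta_v * (1.0 - np.exp(-step.duration / tau_m_s))
    v[after] = v_end * np.exp(-(t[after] - off) / tau_m_s)
    return v


def make_current_clamp_cohort(
    class_counts: dict[ActivityClass, int],
    params: SpikeTemplateParams | None = None,
    seed: int = 0,
    currents_pa: tuple[float, ...] = DEFAULT_CURRENT_STEPS_PA,
    sampling_rate: float = 10_000.0,
    noise_sd: float = 0.3,
    subpeak_v: float = -20.0,
    resting_v: float = -35.0,
    input_resistance_mohm: float = 100.0,
    group_label: str = "",
    include_resistance_step: bool = True,
) -> list[SweepSet]:
    """Simulate a cohort of neurons with prescribed activity classes.

    Each neuron carries a 2-s stimulus-free recording at ``resting_v``
    (with overshooting spontaneous spikes for the ``SPONTANEOUS`` class),
    the full 1-s current-step family at a −80 mV holding level, and —
    optionally — a −1 nA step for input-resistance measurement.  Excursion
    peaks default to +25 mV for overshooting spikes and ``subpeak_v``
    (−20 mV) for sub-threshold attempts, comfortably clear of the 0-mV
    rule boundary.  Ground truth is recorded in each SweepSet's metadata.
    """
    params = params or SpikeTemplateParams()
    if not class_counts or all(c == 0 for c in class_counts.values()):
        raise ParameterError("class_counts must request at least one neuron")
    for cls, count in class_counts.items():
        if count < 0:
            raise ParameterError(f"negative count for {cls}")
        if cls in (
            ActivityClass.SINGLE,
            ActivityClass.ATTEMPTING_TRAIN,
            ActivityClass.TRAIN,
            ActivityClass.SPONTANEOUS,
        ) and params.peak_v <= 0:
            raise ParameterError(
                f"class {cls.value} unachievable: template peak_v {params.peak_v} mV "
                "does not overshoot 0 mV"
            )
    if subpeak_v > 0:
        raise ParameterError(f"subpeak_v must not overshoot 0 mV, got {subpeak_v}")

    rng = np.random.default_rng(seed)
    order = [
        ActivityClass.QUIET,
        ActivityClass.ATTEMPTING_SINGLE,
        ActivityClass.SINGLE,
        ActivityClass.ATTEMPTING_TRAIN,
        ActivityClass.TRAIN,
        ActivityClass.SPONTANEOUS,
    ]
    cohort: list[SweepSet] = []
    idx = 0
    for cls in order:
        for _ in range(class_counts.get(cls, 0)):
            cohort.append(
                _make_neuron(
                    cls,
                    params,
                    rng,
                    currents_pa,
                    sampling_rate,
                    noise_sd,
                    subpeak_v,
                    resting_v,
                    input_resistance_mohm,
                    group_label,
                    include_resistance_step,
                    cell_id=f"{group_label or 'cell'}_{idx:03d}",
                )
            )
            idx += 1
    return cohort


def _make_neuron(
    cls: ActivityClass,
    params: SpikeTemplateParams,
    rng: np.random.Generator,
    currents_pa,
    fs: float,
    noise_sd: float,
    subpeak_v: float,
    resting_v: float,
    r_in_mohm: float,
    group_label: str,
    include_r_step: bool,
    cell_id: str,
) -> SweepSet:
    tau_m = 3e-3
    holding = params.baseline_v
    rest_v = resting_v + rng.uniform(-3.0, 3.0)
    sweeps: list[tuple[TimeSeriesTrace, Optional[StimulusStep]]] = []

    # stimulus-free recording (resting Vm / non-induced coding)
    n_rest = int(round(2.0 * fs))
    t_rest = np.arange(n_rest) / fs
    v_rest = np.full(n_rest, rest_v)
    if cls is ActivityClass.SPONTANEOUS:
        for tm in sorted(rng.uniform(0.3, 1.8, size=rng.integers(1, 4))):
            peak = params.peak_v + rng.uniform(-3.0, 3.0)
            v_rest += spike_waveform(
                t_rest, tm, params.rise_tau, params.decay_tau, 0.0, peak - rest_v
            )
    if noise_sd > 0:
        v_rest = v_rest + rng.normal(0.0, noise_sd, n_rest)
    sweeps.append(
        (TimeSeriesTrace(fs, v_rest, "mV", label="rest"), None)
    )

    # induced class realised by the step family
    induced = ActivityClass.SINGLE if cls is ActivityClass.SPONTANEOUS else cls
    currents = list(currents_pa)
    positive = [i for i, amp in enumerate(currents) if amp > 0]
    rheo_pos = rng.integers(1, max(2, len(positive) - 1))
    rheo_idx = positive[min(rheo_pos, len(positive) - 1)]

    step_on, step_dur, sweep_len = 0.1, 1.0, 1.2
    n = int(round(sweep_len * fs))
    t = np.arange(n) / fs
    foot = spike_foot_for_threshold(params)

    for j, amp_pa in enumerate(currents):
        step = StimulusStep(onset_time=step_on, duration=step_dur, level=amp_pa, pre_level=0.0)
        spiking = induced is not ActivityClass.QUIET and j >= rheo_idx
        if spiking:
            delta_v = foot - holding
        else:
            delta_v = amp_pa * 0.04  # 40 MΩ sub-threshold gain, < min_rise everywhere
        v = holding + _passive_response(t, step, delta_v, tau_m)
        if spiking:
            v += _spike_train(t, induced, params, rng, subpeak_v, foot, step)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, n)
        sweeps.append(
            (TimeSeriesTrace(fs, v, "mV", label=f"step_{amp_pa:+.0f}pA"), step)
        )

    if include_r_step:
        step = StimulusStep(onset_time=0.1, duration=0.5, level=-1000.0, pre_level=0.0)
        n_r = int(round(0.7 * fs))
        t_r = np.arange(n_r) / fs
        delta_v = -1.0 * r_in_mohm  # I(nA)·R(MΩ) = mV
        v = holding + _passive_response(t_r, step, delta_v, tau_m)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, n_r)
        sweeps.append((TimeSeriesTrace(fs, v, "mV", label="r_test"), step))

    noninduced = (
        ActivityClass.SPONTANEOUS if cls is ActivityClass.SPONTANEOUS else ActivityClass.QUIET
    )
    return SweepSet(
        mode="current_clamp",
        sweeps=sweeps,
        cell_id=cell_id,
        group_label=group_label,
        metadata={
            "true_induced_class": induced.value,
            "true_noninduced_class": noninduced.value,
            "true_resting_vm": float(rest_v),
            "true_input_resistance_mohm": float(r_in_mohm),
            "template": {k: float(v) for k, v in asdict(params).items()},
        },
    )


def _spike_train(
    t: np.ndarray,
    induced: ActivityClass,
    params: SpikeTemplateParams,
    rng: np.random.Generator,
    subpeak_v: float,
    foot: float,
    step: StimulusStep,
) -> np.ndarray:
    """Spike excursions (relative to the foot plateau) for one sweep."""
    if induced is ActivityClass.ATTEMPTING_SINGLE:
        peaks = [subpeak_v + rng.uniform(-3.0, 3.0)]
    elif induced is ActivityClass.SINGLE:
        peaks = [params.peak_v + rng.uniform(-3.0, 3.0)]
    elif induced is ActivityClass.ATTEMPTING_TRAIN:
        peaks = [
            params.peak_v + rng.uniform(-3.0, 3.0),
            subpeak_v + rng.uniform(-3.0, 3.0),
            subpeak_v + rng.uniform(-3.0, 3.0),
        ]
    elif induced is ActivityClass.TRAIN:
        n_spikes = int(rng.integers(3, 8))
        peaks = [params.peak_v + rng.uniform(-3.0, 3.0) for _ in range(n_spikes)]
    else:  # pragma: no cover - guarded by caller
        return np.zeros_like(t)
    tm = step.onset_time + rng.uniform(0.12, 0.2)
    out = np.zeros_like(t)
    for peak in peaks:
        out += spike_waveform(t, tm, params.rise_tau, params.decay_tau, 0.0, peak - foot)
        tm += rng.uniform(0.07, 0.1)
    return out


# ---------------------------------------------------------------------------
# voltage clamp


def _gating_current(
    gt: GatingGroundTruth,
    t_s: np.ndarray,
    vc: float,
    avail0: float,
    inactivating: bool,
) -> np.ndarray:
    """Current (pA) of one conductance during a step to ``vc`` starting at
    t = 0 with initial availability ``avail0``.

    Activation rises exponentially (tau ``kinetic_tau``) toward its
    Boltzmann steady state; availability relaxes first-order (tau
    ``kinetic_tau_inact``) from ``avail0`` toward its Boltzmann steady
    state at ``vc``.
    """
    tau_a = gt.kinetic_tau * 1e-3
    act = float(gt.act_inf(vc)) * (1.0 - np.exp(-t_s / tau_a))
    if inactivating:
        tau_h = gt.kinetic_tau_inact * 1e-3
        h_inf = float(gt.inact_inf(vc))
        avail = h_inf + (avail0 - h_inf) * np.exp(-t_s / tau_h)
    else:
        avail = 1.0
    return gt.gmax * act * avail * (vc - gt.e_rev)  # nS·mV = pA


def make_voltage_clamp_recording(
    na: Optional[GatingGroundTruth],
    k: Optional[GatingGroundTruth],
    capacitance: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    protocol: str = "activation",
    steps_mv: Optional[tuple[float, ...]] = None,
    holding_mv: float = -70.0,
    sampling_rate: float = 10_000.0,
    step_duration: float = 80e-3,
    prepulse_duration: float = 200e-3,
    test_potential: float = 0.0,
    capacitive_transient: bool = True,
    cell_id: str = "vc_cell",
    group_label: str = "",
) -> SweepSet:
    """Simulate a whole-cell voltage-clamp recording.

    ``protocol="activation"``: 80-ms steps from the holding potential
    (default −70 mV) to each command level (−120…+80 mV, 10-mV default).
    ``protocol="inactivation"``: 200-ms pre-pulses (−120…+80 mV, 5-mV
    default) followed by a 200-ms test step to ``test_potential`` (0 mV);
    the per-sweep :class:`StimulusStep` records the pre-pulse level, and
    the test-step window is stored in metadata.

    The Na⁺-like component transiently activates then inactivates; the
    K⁺-like component is non-inactivating.  Gaussian current noise of
    ``noise_sd`` pA is added throughout.
    """
    if na is None and k is None:
        raise ParameterError("at least one of na, k must be given")
    if not (capacitance > 0):
        raise ParameterError(f"capacitance must be > 0 pF, got {capacitance}")
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    if protocol not in ("activation", "inactivation"):
        raise ParameterError(f"unknown protocol {protocol!r}")

    rng = np.random.default_rng(seed)
    fs = sampling_rate
    pre_s = 10e-3
    metadata: dict = {
        "protocol": protocol,
        "holding_mv": holding_mv,
        "ground_truth": {
            name: {kk: float(vv) for kk, vv in asdict(gt).items()}
            for name, gt in (("na", na), ("k", k))
            if gt is not None
        },
    }

    sweeps = []
    if protocol == "activation":
        levels = steps_mv if steps_mv is not None else DEFAULT_ACTIVATION_STEPS_MV
        n = int(round((pre_s + step_duration + 10e-3) * fs))
        t = np.arange(n) / fs
        for vc in levels:
            i = np.zeros(n)
            seg = t >= pre_s
            ts = t[seg] - pre_s
            if na is not None:
                avail0 = float(na.inact_inf(holding_mv))
                i[seg] += _gating_current(na, ts, vc, avail0, inactivating=True)
            if k is not None:
                i[seg] += _gating_current(k, ts, vc, 1.0, inactivating=False)
            if capacitive_transient:
                i += _cap_transient(t, pre_s, vc - holding_mv, capacitance)
                i += _cap_transient(t, pre_s + step_duration, holding_mv - vc, capacitance)
            if noise_sd > 0:
                i = i + rng.normal(0.0, noise_sd, n)
            step = StimulusStep(pre_s, step_duration, level=vc, pre_level=holding_mv)
            sweeps.append((TimeSeriesTrace(fs, i, "pA", label=f"vc_{vc:+.0f}mV"), step))
    else:
        levels = steps_mv if steps_mv is not None else DEFAULT_INACTIVATION_PREPULSES_MV
        n = int(round((pre_s + prepulse_duration + prepulse_duration + 10e-3) * fs))
        t = np.arange(n) / fs
        test_on = pre_s + prepulse_duration
        metadata["test_onset_s"] = test_on
        metadata["test_duration_s"] = prepulse_duration
        metadata["test_potential_mv"] = test_potential
        for vpre in levels:
            i = np.zeros(n)
            seg1 = (t >= pre_s) & (t < test_on)
            seg2 = t >= test_on
            if na is not None:
                avail_hold = float(na.inact_inf(holding_mv))
                i[seg1] += _gating_current(na, t[seg1] - pre_s, vpre, avail_hold, True)
                # availability at the end of the 200-ms pre-pulse has settled
                tau_h = na.kinetic_tau_inact * 1e-3
                h_inf = float(na.inact_inf(vpre))
                avail_end = h_inf + (avail_hold - h_inf) * np.exp(-prepulse_duration / tau_h)
                i[seg2] += _gating_current(na, t[seg2] - test_on, test_potential, avail_end, True)
            if k is not None:
                i[seg1] += _gating_current(k, t[seg1] - pre_s, vpre, 1.0, False)
                i[seg2] += _gating_current(k, t[seg2] - test_on, test_potential, 1.0, False)
            if capacitive_transient:
                i += _cap_transient(t, pre_s, vpre - holding_mv, capacitance)
                i += _cap_transient(t, test_on, test_potential - vpre, capacitance)
            if noise_sd > 0:
                i = i + rng.normal(0.0, noise_sd, n)
            step = StimulusStep(pre_s, prepulse_duration, level=vpre, pre_level=holding_mv)
            sweeps.append((TimeSeriesTrace(fs, i, "pA", label=f"pre_{vpre:+.0f}mV"), step))

    return SweepSet(
        mode="voltage_clamp",
        sweeps=sweeps,
        cell_id=cell_id,
        capacitance=capacitance,
        group_label=group_label,
        metadata=metadata,
    )


def make_voltage_clamp_pair(
    na: Optional[GatingGroundTruth],
    k: Optional[GatingGroundTruth],
    capacitance: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> tuple[SweepSet, SweepSet]:
    """Activation and inactivation recordings of the same cell."""
    act = make_voltage_clamp_recording(
        na, k, capacitance, noise_sd, seed, protocol="activation", **kwargs
    )
    inact = make_voltage_clamp_recording(
        na, k, capacitance, noise_sd, seed + 1, protocol="inactivation", **kwargs
    )
    return act, inact


def _cap_transient(t: np.ndarray, onset: float, dv_mv: float, cap_pf: float) -> np.ndarray:
    """Brief capacitive charging spike at a voltage step edge (tau 0.03 ms)."""
    tau = 0.03e-3
    out = np.zeros_like(t)
    after = t >= onset
    out[after] = (dv_mv * cap_pf / (tau * 1e3 * 1e3)) * np.exp(-(t[after] - onset) / tau)
    return out


def closed_form_peak_iv(
    na: Optional[GatingGroundTruth],
    k: Optional[GatingGroundTruth],
    steps_mv=DEFAULT_ACTIVATION_STEPS_MV,
    holding_mv: float = -70.0,
    window_s: float = 10e-3,
    blank_s: float = 0.3e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless expected peak inward current (pA) per activation step.

    Evaluates the analytic current of both components on a dense time grid
    over the early peak-detection window and takes the (non-positive)
    minimum — the quantity :func:`inephys.voltage_clamp.extract_peak_currents`
    estimates from the sampled trace.
    """
    ts = np.linspace(blank_s, window_s, 20_001)
    vcs = np.asarray(steps_mv, dtype=float)
    peaks = np.zeros_like(vcs)
    for j, vc in enumerate(vcs):
        i = np.zeros_like(ts)
        if na is not None:
            avail0 = float(na.inact_inf(holding_mv))
            i += _gating_current(na, ts, vc, avail0, True)
        if k is not None:
            i += _gating_current(k, ts, vc, 1.0, False)
        peaks[j] = min(0.0, float(np.min(i)))
    return vcs, peaks


def gmax_for_peak_density(
    target_density_pa_per_pf: float,
    capacitance: float,
    na: GatingGroundTruth,
    k: Optional[GatingGroundTruth] = None,
    steps_mv=DEFAULT_ACTIVATION_STEPS_MV,
    holding_mv: float = -70.0,
) -> float:
    """Na gmax (nS) that makes the most negative peak current density over
    the activation family equal ``target_density_pa_per_pf`` (pA/pF,
    negative for inward)."""
    if target_density_pa_per_pf >= 0:
        raise ParameterError("target peak inward density must be negative")

    def density(gmax: float) -> float:
        na_g = GatingGroundTruth(**{**asdict(na), "gmax": gmax})
        _, peaks = closed_form_peak_iv(na_g, k, steps_mv, holding_mv)
        return float(np.min(peaks)) / capacitance

    from scipy.optimize import brentq

    target = target_density_pa_per_pf
    # density is monotone (more negative) in gmax; bracket by scaling
    lo, hi = 1e-3, 10.0
    while density(hi) > target:
        hi *= 4.0
        if hi > 1e7:  # pragma: no cover - unreachable for sane targets
            raise ParameterError("could not bracket the requested density")
    return float(brentq(lambda g: density(g) - target, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# fluorescence


def make_fluorescence_trace(
    gt: CalciumGroundTruth,
    duration: float = 60.0,
    sampling_rate: float = 5.0,
    seed: int = 0,
    cell_id: str = "roi",
    group_label: str = "",
) -> SweepSet:
    """Simulate a per-cell fluorescence recording.

    F(t) = f0·(1 + osc_amp·sin(2π·osc_freq·t) + drift_slope·t) plus
    Gaussian noise of sd ``noise_sd``·f0, clipped at 0.
    """
    if not (duration > 0):
        raise ParameterError(f"duration must be > 0, got {duration}")
    if gt.osc_freq >= sampling_rate / 2.0:
        raise ParameterError(
            f"osc_freq {gt.osc_freq} Hz is at or above Nyquist ({sampling_rate / 2} Hz)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    f = gt.f0 * (1.0 + gt.osc_amp * np.sin(2.0 * np.pi * gt.osc_freq * t) + gt.drift_slope * t)
    if gt.noise_sd > 0:
        f = f + rng.normal(0.0, gt.noise_sd * gt.f0, n)
    f = np.clip(f, 0.0, None)
    trace = TimeSeriesTrace(sampling_rate, f, "AFU", label="F")
    return SweepSet(
        mode="fluorescence",
        sweeps=[(trace, None)],
        cell_id=cell_id,
        group_label=group_label,
        metadata={"ground_truth": {kk: float(vv) for kk, vv in asdict(gt).items()}},
    )
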