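import numpy as np
import pytest

from inephys.io import StimulusStep, TimeSeriesTrace
from inephys.synth import (
    GatingGroundTruth,
    SpikeTemplateParams,
    spike_foot_for_threshold,
    spike_waveform,
)

FS = 10_000.0


@pytest.fixture
def na_gating() -> GatingGroundTruth:
    """Na⁺-like ground truth: transient inward, reversal +66.7 mV."""
    return GatingGroundTruth(
        gmax=50.0, v50_act=-30.0, h_act=7.0, v50_inact=-61.7, h_inact=-7.0,
        e_rev=66.7, kinetic_tau=0.5,
    )


@pytest.fixture
def na_gating_noninactivating() -> GatingGroundTruth:
    """Na⁺-like gating with inactivation pushed far right (negligible)."""
    return GatingGroundTruth(
        gmax=50.0, v50_act=-30.0, h_act=7.0, v50_inact=150.0, h_inact=-7.0,
        e_rev=66.7, kinetic_tau=0.5,
    )


@pytest.fixture
def k_gating() -> GatingGroundTruth:
    """K⁺-like ground truth: sustained outward, reversal −90 mV."""
    return GatingGroundTruth(
        gmax=20.0, v50_act=-5.0, h_act=12.0, v50_inact=60.0, h_inact=-7.0,
        e_rev=-90.0, kinetic_tau=3.0,
    )


def make_spike_sweep(
    params: SpikeTemplateParams,
    tm: float = 0.2,
    fs: float = FS,
    total_s: float = 0.4,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_v: float | None = None,
) -> tuple[TimeSeriesTrace, StimulusStep]:
    """One sweep holding a single calibrated spike on its foot plateau."""
    t = np.arange(int(total_s * fs)) / fs
    step = StimulusStep(0.02, total_s - 0.05, level=100.0)
    foot = spike_foot_for_threshold(params, peak_v)
    peak = params.peak_v if peak_v is None else peak_v
    v = np.where((t >= step.onset_time) & (t < step.offset_time), foot, params.baseline_v)
    v = v + spike_waveform(t, tm, params.rise_tau, params.decay_tau, 0.0, peak - foot)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return TimeSeriesTrace(fs, v, "mV"), step


def dense_spike_oracle(
    params: SpikeTemplateParams,
    tm: float = 0.2,
    window: tuple[float, float] = (0.15, 0.25),
    dt: float = 1e-6,
    peak_v: float | None = None,
) -> dict:
    """Brute-force morphometry of the analytic template on a dense grid:
    threshold at the argmax of the numerically tripled derivative on the
    acceleration phase of the upstroke, maximal dV/dt, and half-width."""
    foot = spike_foot_for_threshold(params, peak_v)
    peak = params.peak_v if peak_v is None else peak_v
    t = np.arange(window[0], window[1], dt)
    v = spike_waveform(t, tm, params.rise_tau, params.decay_tau, foot, peak)
    d1 = np.gradient(v, dt)
    d3 = np.gradient(np.gradient(d1, dt), dt)
    pk = int(np.argmax(v))
    accel_end = int(np.argmax(d1[:pk]))
    ti = 50 + int(np.argmax(d3[50:accel_end]))
    thr = float(v[ti])
    amp = float(v[pk]) - thr
    above = np.flatnonzero(v >= thr + amp / 2.0)
    return {
        "threshold_v": thr,
        "threshold_time": float(t[ti]),
        "peak_v": float(v[pk]),
        "amplitude": amp,
        "depol_rate": float(np.max(d1[ti : pk + 1])) / 1000.0,
        "half_width_ms": float((t[above[-1]] - t[above[0]]) * 1e3),
    }
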