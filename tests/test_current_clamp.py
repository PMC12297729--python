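"""Activity coding, passive properties and spike morphometry."""

import numpy as np
import pytest

from inephys.current_clamp import (
    ActivityClass,
    Excursion,
    classify_induced,
    classify_spontaneous,
    classify_sweep,
    cohort_feature_table,
    detect_excursions,
    extract_spike_features,
    input_resistance,
    resting_vm,
)
from inephys.errors import (
    MorphologyError,
    ProtocolError,
    ValidationError,
)
from inephys.io import StimulusStep, SweepSet, TimeSeriesTrace
from inephys.synth import (
    SpikeTemplateParams,
    make_current_clamp_cohort,
    spike_foot_for_threshold,
    spike_waveform,
)

from .conftest import FS, dense_spike_oracle, make_spike_sweep


def _flat_sweep(v=-80.0, n=12_000, fs=FS):
    return TimeSeriesTrace(fs, np.full(n, float(v)), "mV")


STEP = StimulusStep(0.1, 1.0, level=100.0)


def _sweep_with_excursions(peaks, fs=FS, foot=-50.0, tm0=0.25, spacing=0.15):
    t = np.arange(int(1.2 * fs)) / fs
    v = np.where((t >= STEP.onset_time) & (t < STEP.offset_time), foot, -80.0)
    tm = tm0
    for p in peaks:
        v = v + spike_waveform(t, tm, 0.8, 4.0, 0.0, p - foot)
        tm += spacing
    return TimeSeriesTrace(fs, v, "mV")


class TestDetectExcursions:
    def test_flat_sweep_yields_no_excursions(self):
        assert detect_excursions(_flat_sweep(), STEP) == []

    def test_single_subzero_excursion_not_overshooting(self):
        tr = _sweep_with_excursions([-20.0])
        (exc,) = detect_excursions(tr, STEP, min_rise=15.0)
        assert exc.overshoots is False
        assert exc.peak_v == pytest.approx(-20.0, abs=0.1)

    def test_three_excursions_order_and_overshoot_flags(self):
        """Brute-force check: peaks and order match construction."""
        tr = _sweep_with_excursions([25.0, -20.0, 25.0])
        excs = detect_excursions(tr, STEP, min_rise=15.0)
        assert [e.overshoots for e in excs] == [True, False, True]
        assert excs[0].onset_index < excs[1].onset_index < excs[2].onset_index
        # brute-force oracle: sweep maxima inside each detected event window
        v = tr.values
        for e, want in zip(excs, [25.0, -20.0, 25.0]):
            assert v[e.peak_index] == pytest.approx(want, abs=0.1)

    def test_short_step_window_is_protocol_error(self):
        tr = _flat_sweep(n=2000)
        with pytest.raises(ProtocolError, match="too short"):
            detect_excursions(tr, StimulusStep(0.1, 0.005, 100.0))

    def test_excursion_invariant_enforced(self):
        with pytest.raises(ValidationError):
            Excursion(onset_index=0, peak_index=5, peak_v=10.0, overshoots=False)


class TestClassification:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ([], ActivityClass.QUIET),
            ([-20.0], ActivityClass.ATTEMPTING_SINGLE),
            ([-20.0, -15.0], ActivityClass.ATTEMPTING_SINGLE),
            ([25.0], ActivityClass.SINGLE),
            ([10.0, -20.0, -25.0, -15.0], ActivityClass.ATTEMPTING_TRAIN),
            ([25.0, 20.0], ActivityClass.TRAIN),
            ([25.0, -20.0, 25.0], ActivityClass.TRAIN),
        ],
        ids=["none", "one-sub", "two-sub", "one-over", "four-one-over", "two-over", "mixed"],
    )
    def test_sweep_rules(self, peaks, expected):
        tr = _sweep_with_excursions(peaks) if peaks else _flat_sweep()
        assert classify_sweep(detect_excursions(tr, STEP, 15.0)) is expected

    def test_neuron_class_is_max_over_sweeps(self):
        """Sweeps classifying {Quiet, Single, AttemptingTrain} give the
        neuron AttemptingTrain under the five-level ordering."""
        sweeps = [
            (_flat_sweep(), STEP),
            (_sweep_with_excursions([25.0]), STEP),
            (_sweep_with_excursions([10.0, -20.0, -25.0]), STEP),
        ]
        neuron = SweepSet(mode="current_clamp", sweeps=sweeps)
        assert classify_induced(neuron) is ActivityClass.ATTEMPTING_TRAIN

    def test_overshoot_criterion_is_absolute_not_baseline_relative(self):
        """Shifting trace and foot up by 25 mV flips sub-threshold attempts
        into overshoots: the 0-mV rule references absolute voltage."""
        tr = _sweep_with_excursions([-20.0])
        neuron = SweepSet(mode="current_clamp", sweeps=[(tr, STEP)])
        assert classify_induced(neuron) is ActivityClass.ATTEMPTING_SINGLE
        shifted = TimeSeriesTrace(tr.sampling_rate, tr.values + 25.0, "mV")
        neuron_up = SweepSet(mode="current_clamp", sweeps=[(shifted, STEP)])
        assert classify_induced(neuron_up) is ActivityClass.SINGLE

    def test_peak_crossing_zero_flips_attempting_to_single_monotonically(self):
        classes = []
        for peak in np.linspace(-5.0, 5.0, 11):
            tr = _sweep_with_excursions([peak])
            neuron = SweepSet(mode="current_clamp", sweeps=[(tr, STEP)])
            classes.append(classify_induced(neuron, min_rise=15.0))
        ranks = [c.rank for c in classes]
        assert ranks == sorted(ranks)
        assert classes[0] is ActivityClass.ATTEMPTING_SINGLE
        assert classes[-1] is ActivityClass.SINGLE

    def test_no_stepped_sweeps_is_protocol_error(self):
        neuron = SweepSet(mode="current_clamp", sweeps=[(_flat_sweep(), None)])
        with pytest.raises(ProtocolError):
            classify_induced(neuron)

    def test_spontaneous_rules(self):
        fs = FS
        t = np.arange(int(2.0 * fs)) / fs
        flat = TimeSeriesTrace(fs, np.full(t.size, -40.0), "mV")
        assert (
            classify_spontaneous(SweepSet("current_clamp", [(flat, None)]))
            is ActivityClass.QUIET
        )
        v = np.full(t.size, -40.0) + spike_waveform(t, 1.0, 0.8, 4.0, 0.0, 60.0)
        spiky = TimeSeriesTrace(fs, v, "mV")
        assert (
            classify_spontaneous(SweepSet("current_clamp", [(spiky, None)]))
            is ActivityClass.SPONTANEOUS
        )
        rng = np.random.default_rng(0)
        wobble = TimeSeriesTrace(fs, -40.0 + 5.0 * np.sin(2 * np.pi * 3 * t) + rng.normal(0, 0.3, t.size), "mV")
        assert (
            classify_spontaneous(SweepSet("current_clamp", [(wobble, None)]), min_rise=15.0)
            is ActivityClass.QUIET
        )


class TestPassiveProperties:
    def test_resting_vm_is_median_of_free_segment(self):
        fs = FS
        tr = TimeSeriesTrace(fs, np.full(int(1.5 * fs), -40.0), "mV")
        neuron = SweepSet("current_clamp", [(tr, None)])
        assert resting_vm(neuron) == -40.0

    def test_resting_vm_robust_to_one_spike(self):
        fs = FS
        t = np.arange(int(2.0 * fs)) / fs
        v = np.full(t.size, -40.0) + spike_waveform(t, 1.0, 0.8, 4.0, 0.0, 65.0)
        neuron = SweepSet("current_clamp", [(TimeSeriesTrace(fs, v, "mV"), None)])
        assert resting_vm(neuron) == pytest.approx(-40.0, abs=0.5)

    def test_short_segment_is_protocol_error(self):
        tr = TimeSeriesTrace(FS, np.full(100, -40.0), "mV")
        with pytest.raises(ProtocolError, match="too short"):
            resting_vm(SweepSet("current_clamp", [(tr, None)]))

    def test_input_resistance_ohms_law(self):
        """ΔV = −100 mV at −1 nA gives 100 MΩ."""
        fs = FS
        step = StimulusStep(0.1, 0.5, level=-1000.0)
        t = np.arange(int(0.7 * fs)) / fs
        v = np.where((t >= 0.1) & (t < 0.6), -180.0, -80.0)
        assert input_resistance(TimeSeriesTrace(fs, v, "mV"), step) == pytest.approx(100.0)

    def test_zero_deflection_warns_and_returns_zero(self):
        step = StimulusStep(0.1, 0.5, level=-1000.0)
        tr = _flat_sweep(n=7000)
        with pytest.warns(UserWarning, match="implausible"):
            assert input_resistance(tr, step) == 0.0

    def test_zero_step_level_raises(self):
        with pytest.raises(ZeroDivisionError):
            input_resistance(_flat_sweep(n=7000), StimulusStep(0.1, 0.5, level=0.0))

    def test_depolarizing_step_rejected(self):
        with pytest.raises(ValidationError, match="hyperpolarizing"):
            input_resistance(_flat_sweep(n=7000), StimulusStep(0.1, 0.5, level=100.0))


class TestSpikeFeatures:
    def test_features_match_template_calibration(self):
        """Template calibrated for threshold −40, peak +30: amplitude 70 and
        overshoot +30 recovered within 1 mV."""
        params = SpikeTemplateParams(threshold_v=-40.0, peak_v=30.0)
        tr, step = make_spike_sweep(params)
        (exc,) = detect_excursions(tr, step)
        f = extract_spike_features(tr, exc)
        assert f.threshold_v == pytest.approx(-40.0, abs=1.0)
        assert f.amplitude == pytest.approx(70.0, abs=1.0)
        assert f.overshoot == pytest.approx(30.0, abs=0.1)
        assert f.overshoot == f.peak_v
        assert f.amplitude == pytest.approx(f.peak_v - f.threshold_v)

    def test_threshold_matches_dense_derivative_oracle(self):
        """Sampled-trace threshold agrees with a brute-force dense-grid
        differentiation oracle within 2 samples on randomized templates."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            params = SpikeTemplateParams(
                threshold_v=float(rng.uniform(-45, -35)),
                peak_v=float(rng.uniform(15, 35)),
                rise_tau=float(rng.uniform(0.8, 2.0)),
                decay_tau=float(rng.uniform(4.0, 8.0)),
            )
            tr, step = make_spike_sweep(params)
            (exc,) = detect_excursions(tr, step)
            f = extract_spike_features(tr, exc)
            oracle = dense_spike_oracle(params)
            offset = abs(f.threshold_index / FS - oracle["threshold_time"]) * FS
            assert offset <= 2.0
            assert f.threshold_v == pytest.approx(oracle["threshold_v"], abs=1.0)

    def test_half_width_and_depol_rate_match_oracle(self):
        params = SpikeTemplateParams()
        tr, step = make_spike_sweep(params)
        (exc,) = detect_excursions(tr, step)
        f = extract_spike_features(tr, exc)
        oracle = dense_spike_oracle(params)
        assert f.half_width == pytest.approx(oracle["half_width_ms"], rel=0.05)
        assert f.depol_rate == pytest.approx(oracle["depol_rate"], rel=0.05)

    def test_flat_trace_is_morphology_error(self):
        tr = _flat_sweep()
        exc = Excursion(onset_index=2000, peak_index=3000, peak_v=-80.0, overshoots=False)
        with pytest.raises(MorphologyError):
            extract_spike_features(tr, exc)

    def test_unrecrossed_half_level_is_morphology_error(self):
        """A sweep truncated at the spike summit never re-crosses the
        half-amplitude level on the way down."""
        params = SpikeTemplateParams()
        tr, step = make_spike_sweep(params, tm=0.2)
        pk = int(np.argmax(tr.values))
        cut = TimeSeriesTrace(FS, tr.values[: pk + 2], "mV")
        (exc,) = detect_excursions(
            cut, StimulusStep(step.onset_time, cut.duration - step.onset_time - 1e-4, 100.0)
        )
        with pytest.raises(MorphologyError, match="re-crossed"):
            extract_spike_features(cut, exc)

    def test_low_sampling_rate_rejected(self):
        tr = TimeSeriesTrace(1000.0, np.zeros(1000), "mV")
        exc = Excursion(0, 10, 5.0, True)
        with pytest.raises(ProtocolError, match="5 kHz"):
            extract_spike_features(tr, exc)


class TestCohortTable:
    def test_quiet_neurons_have_missing_spike_columns(self):
        cohort = make_current_clamp_cohort({ActivityClass.QUIET: 2}, seed=0)
        table = cohort_feature_table(cohort)
        assert len(table) == 2
        assert table["amplitude"].isna().all()
        assert (table["activity_class"] == "Quiet").all()

    def test_mixed_cohort_classes_match_ground_truth(self):
        counts = {
            ActivityClass.QUIET: 1,
            ActivityClass.ATTEMPTING_SINGLE: 1,
            ActivityClass.SINGLE: 1,
            ActivityClass.ATTEMPTING_TRAIN: 1,
            ActivityClass.TRAIN: 1,
        }
        cohort = make_current_clamp_cohort(counts, seed=4)
        table = cohort_feature_table(cohort)
        assert len(table) == 5
        truth = [n.metadata["true_induced_class"] for n in cohort]
        assert list(table["activity_class"]) == truth
        # spiking neurons have morphometry, quiet/attempting do not
        spiky = table["activity_class"].isin(["Single", "AttemptingTrain", "Train"])
        assert table.loc[spiky, "amplitude"].notna().all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            cohort_feature_table([])
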