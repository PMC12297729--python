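"""I–V extraction, conductance transform, Boltzmann fits, availability window."""

import numpy as np
import pytest

from inephys.errors import FitError, ParameterError
from inephys.synth import (
    GatingGroundTruth,
    make_voltage_clamp_recording,
)
from inephys.voltage_clamp import (
    BoltzmannFit,
    IVPoint,
    availability_window,
    conductance_transform,
    extract_inactivation_peaks,
    extract_peak_currents,
    fit_boltzmann,
)


def _grid_gv(gmax=20.0, v50=-30.0, h=7.0, sign=1.0, lo=-120, hi=80, step=10):
    v = np.arange(lo, hi + 1, step, dtype=float)
    g = gmax / (1.0 + np.exp(sign * (v50 - v) / h))
    return list(zip(v, g))


class TestExtraction:
    def test_density_is_peak_over_capacitance(self):
        p = IVPoint(vc=-20.0, peak_inward=-5000.0, peak_outward=0.0,
                    inward_density=-5000.0 / 10.0, outward_density=0.0)
        assert p.inward_density == -500.0

    def test_density_without_capacitance_rejected(self, na_gating):
        rec = make_voltage_clamp_recording(na_gating, None, capacitance=20.0)
        rec.capacitance = None
        with pytest.raises(ParameterError, match="capacitance"):
            extract_peak_currents(rec, with_density=True)

    def test_peaks_sorted_by_command_potential(self, na_gating, k_gating):
        rec = make_voltage_clamp_recording(na_gating, k_gating, capacitance=20.0)
        pts = extract_peak_currents(rec)
        vcs = [p.vc for p in pts]
        assert vcs == sorted(vcs)
        assert all(p.peak_inward <= 0 <= p.peak_outward for p in pts)

    def test_outward_current_sustained_at_depolarized_steps(self, k_gating):
        rec = make_voltage_clamp_recording(None, k_gating, capacitance=20.0)
        pts = {p.vc: p for p in extract_peak_currents(rec)}
        # steady state: gmax·act∞(vc)·(vc − e_rev)
        for vc in (0.0, 40.0, 80.0):
            want = k_gating.gmax * float(k_gating.act_inf(vc)) * (vc - k_gating.e_rev)
            assert pts[vc].peak_outward == pytest.approx(want, rel=0.01)

    def test_inactivation_peaks_follow_availability(self, na_gating):
        rec = make_voltage_clamp_recording(na_gating, None, 20.0, protocol="inactivation")
        pairs = dict(extract_inactivation_peaks(rec))
        # hyperpolarized pre-pulse: full availability; depolarized: none
        assert abs(pairs[-120.0]) > 100.0
        assert abs(pairs[40.0]) < 0.01 * abs(pairs[-120.0])


class TestConductanceTransform:
    def test_zero_current_gives_zero_conductance(self):
        out = conductance_transform([(-20.0, 0.0)], e_rev=66.7)
        assert out == [(-20.0, 0.0)]

    def test_driving_force_arithmetic(self):
        """I = −1000 pA at −20 mV against Erev +66.7 mV → 11.534 nS."""
        (pair,) = conductance_transform([(-20.0, -1000.0)], e_rev=66.7)
        assert pair[1] == pytest.approx(-1000.0 / (-86.7), abs=5e-4)
        assert pair[1] == pytest.approx(11.534, abs=1e-3)

    def test_point_at_reversal_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="reversal"):
            out = conductance_transform([(66.7, -50.0), (-20.0, -1000.0)], e_rev=66.7)
        assert len(out) == 1

    def test_inward_branch_restricted_below_reversal(self):
        pts = [IVPoint(vc, -100.0, 0.0) for vc in (-40.0, 0.0, 70.0)]
        out = conductance_transform(pts, e_rev=66.7, branch="inward")
        assert [v for v, _ in out] == [-40.0, 0.0]

    def test_transform_linearity_in_current(self):
        """Scaling all currents by c scales every conductance by c."""
        base = [(-40.0, -800.0), (-20.0, -1500.0), (0.0, -900.0)]
        g1 = conductance_transform(base)
        g3 = conductance_transform([(v, 3.0 * i) for v, i in base])
        for (_, a), (_, b) in zip(g1, g3):
            assert b == pytest.approx(3.0 * a)


class TestBoltzmannFit:
    def test_noiseless_activation_recovery(self):
        fit = fit_boltzmann(_grid_gv(gmax=20.0, v50=-30.0, h=7.0), "activation")
        assert fit.v50 == pytest.approx(-30.0, abs=0.1)
        assert fit.h == pytest.approx(7.0, rel=0.01)
        assert fit.gmax == pytest.approx(20.0, rel=0.01)
        assert fit.rss < 1e-12

    def test_fitted_curve_value_at_v50_is_half_gmax(self):
        fit = fit_boltzmann(_grid_gv(), "activation")
        assert float(fit(fit.v50)) == pytest.approx(fit.gmax / 2.0, rel=1e-6)

    def test_noiseless_inactivation_recovery(self):
        gv = _grid_gv(gmax=20.0, v50=-61.7, h=7.0, sign=-1.0)
        fit = fit_boltzmann(gv, "inactivation")
        assert fit.v50 == pytest.approx(-61.7, abs=0.1)
        assert fit.h == pytest.approx(7.0, rel=0.01)
        assert fit.curve_type == "inactivation"

    def test_noisy_recovery_bias_and_spread(self):
        """2% multiplicative-scale Gaussian noise over 200 seeded replicates:
        mean V50 error < 0.5 mV, estimator sd < 1.5 mV."""
        v50s = []
        clean = _grid_gv(gmax=20.0, v50=-30.0, h=7.0)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = [(v, g + rng.normal(0.0, 0.02 * 20.0)) for v, g in clean]
            v50s.append(fit_boltzmann(noisy, "activation").v50)
        v50s = np.asarray(v50s)
        assert abs(np.mean(v50s) + 30.0) < 0.5
        assert np.std(v50s) < 1.5

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match=">= 5"):
            fit_boltzmann(_grid_gv()[:4], "activation")

    def test_degenerate_constant_data_rejected(self):
        gv = [(v, 5.0) for v in range(-120, 81, 10)]
        with pytest.raises(FitError, match="degenerate"):
            fit_boltzmann(gv, "activation")

    def test_fitted_gmax_scales_linearly_with_current_scale(self):
        """Conductance scaling changes Gmax only; V50 and h are invariant."""
        gv = _grid_gv(gmax=20.0, v50=-30.0, h=7.0)
        f1 = fit_boltzmann(gv, "activation")
        f2 = fit_boltzmann([(v, 2.5 * g) for v, g in gv], "activation")
        assert f2.gmax == pytest.approx(2.5 * f1.gmax, rel=1e-6)
        assert f2.v50 == pytest.approx(f1.v50, abs=1e-6)
        assert f2.h == pytest.approx(f1.h, rel=1e-6)


class TestRoundTrip:
    def test_simulate_extract_transform_fit_recovers_gating(self):
        """Full noiseless pipeline over random ground truths recovers V50
        within 1 mV and h within 5% (the residual bias comes from
        voltage-dependent inactivation kinetics during the activation
        steps; with inactivation negligible recovery is exact — see the
        acceptance suite)."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            na = GatingGroundTruth(
                gmax=float(rng.uniform(20, 80)),
                v50_act=float(rng.uniform(-40, -20)),
                h_act=float(rng.uniform(5, 10)),
                v50_inact=float(rng.uniform(-70, -55)),
                h_inact=-float(rng.uniform(5, 10)),
                e_rev=66.7,
                kinetic_tau=0.5,
            )
            rec = make_voltage_clamp_recording(na, None, capacitance=20.0)
            fit = fit_boltzmann(
                conductance_transform(extract_peak_currents(rec)), "activation"
            )
            assert fit.v50 == pytest.approx(na.v50_act, abs=1.0)
            assert fit.h == pytest.approx(na.h_act, rel=0.05)

            inact_rec = make_voltage_clamp_recording(
                na, None, capacitance=20.0, protocol="inactivation"
            )
            gv = conductance_transform(
                extract_inactivation_peaks(inact_rec), driving_potential=0.0
            )
            ifit = fit_boltzmann(gv, "inactivation")
            assert ifit.v50 == pytest.approx(na.v50_inact, abs=1.0)
            assert ifit.h == pytest.approx(abs(na.h_inact), rel=0.05)


def _fit(v50, h, curve_type):
    return BoltzmannFit(gmax=1.0, v50=v50, h=h, rss=0.0, n_points=21, curve_type=curve_type)


class TestAvailabilityWindow:
    def test_symmetric_curves_cross_at_shared_v50_with_quarter_max(self):
        win = availability_window(_fit(-30.0, 7.0, "activation"), _fit(-30.0, 7.0, "inactivation"))
        assert win.crossing_v == pytest.approx(-30.0, abs=1e-5)
        assert win.window_max == pytest.approx(0.25, abs=1e-6)

    def test_right_shifted_inactivation_opens_the_window(self):
        win = availability_window(_fit(-30.0, 7.0, "activation"), _fit(30.0, 7.0, "inactivation"))
        assert win.window_max == pytest.approx(1.0, abs=0.05)

    def test_va50_minus_vi50_statistic(self):
        win = availability_window(_fit(-30.0, 7.0, "activation"), _fit(-61.7, 7.0, "inactivation"))
        assert win.va50_minus_vi50 == pytest.approx(31.7)

    def test_window_bounded_and_monotone_in_separation(self):
        """Window curve stays in [0,1]; pushing Vi50 left of Va50 shrinks
        the maximum monotonically."""
        maxima = []
        for vi50 in (-20.0, -40.0, -60.0, -80.0):
            win = availability_window(_fit(-30.0, 7.0, "activation"), _fit(vi50, 7.0, "inactivation"))
            assert np.all(win.window_curve >= 0.0) and np.all(win.window_curve <= 1.0)
            maxima.append(win.window_max)
        assert maxima == sorted(maxima, reverse=True)

    def test_crossing_satisfies_equality_to_tolerance(self):
        act, inact = _fit(-30.0, 7.0, "activation"), _fit(-61.7, 7.0, "inactivation")
        win = availability_window(act, inact)
        assert float(act.fraction(win.crossing_v) - inact.fraction(win.crossing_v)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_noncrossing_curves_warn_and_report_none(self):
        # on a grid far right of both midpoints, act∞ ≈ 1 > inact∞ ≈ 0 throughout
        act = _fit(-30.0, 7.0, "activation")
        inact = _fit(-100.0, 7.0, "inactivation")
        with pytest.warns(UserWarning, match="do not cross"):
            win = availability_window(act, inact, v_min=0.0, v_max=80.0)
        assert win.crossing_v is None
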