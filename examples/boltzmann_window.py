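"""Fit Boltzmann gating curves and compute the availability window.

Simulates whole-cell voltage-clamp recordings of a Na⁺-like conductance
(activation steps from −70 mV holding; 200-ms pre-pulse inactivation
protocol), extracts peak currents, converts them to conductance with the
driving force (Vc − 66.7 mV), fits both Boltzmann branches, and prints
the half-maximum voltages, slope factors and the availability window —
the voltage range where activation and availability curves overlap.
"""

from inephys.synth import GatingGroundTruth, make_voltage_clamp_recording
from inephys.voltage_clamp import (
    availability_window,
    conductance_transform,
    extract_inactivation_peaks,
    extract_peak_currents,
    fit_boltzmann,
)

na = GatingGroundTruth(gmax=50.0, v50_act=-30.0, h_act=7.0,
                       v50_inact=-61.7, h_inact=-7.0, e_rev=66.7, kinetic_tau=0.5)

act_rec = make_voltage_clamp_recording(na, None, capacitance=20.0)
points = extract_peak_currents(act_rec)
print("peak inward current density: "
      f"{min(p.inward_density for p in points):.1f} pA/pF")

act_fit = fit_boltzmann(conductance_transform(points), "activation")
inact_rec = make_voltage_clamp_recording(na, None, capacitance=20.0, protocol="inactivation")
inact_fit = fit_boltzmann(
    conductance_transform(extract_inactivation_peaks(inact_rec), driving_potential=0.0),
    "inactivation",
)
print(f"activation:   V50 = {act_fit.v50:7.2f} mV, h = {act_fit.h:.2f} mV (truth -30, 7)")
print(f"inactivation: V50 = {inact_fit.v50:7.2f} mV, h = {inact_fit.h:.2f} mV (truth -61.7, 7)")

win = availability_window(act_fit, inact_fit)
print(f"Va50 - Vi50 = {win.va50_minus_vi50:.1f} mV")
print(f"window maximum {win.window_max:.4f} at {win.v_at_max:.1f} mV, "
      f"curves cross at {win.crossing_v:.2f} mV")
print("(the window maximum bounds the steady-state fraction of Na+ conductance"
      " available for sustained current)")
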