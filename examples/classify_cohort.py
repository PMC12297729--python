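"""Classify a synthetic current-clamp cohort and tally the census.

Builds a 36-neuron cohort with a known mix of induced-activity classes,
runs the five-level classifier over each neuron's current-step family,
and prints the census with integer percentages and the genuine-AP share
(the fraction of neurons producing at least one overshooting spike).
"""

from inephys.current_clamp import ActivityClass as AC, classify_induced, cohort_feature_table
from inephys.report import genuine_ap_share, tally
from inephys.synth import make_current_clamp_cohort

census = {AC.QUIET: 3, AC.ATTEMPTING_SINGLE: 4, AC.SINGLE: 21, AC.ATTEMPTING_TRAIN: 3, AC.TRAIN: 5}
cohort = make_current_clamp_cohort(census, seed=1, group_label="control")

t = tally([(n.cell_id, classify_induced(n)) for n in cohort], "control")
print(f"cohort n = {t.n}")
for cls, count in t.counts.items():
    print(f"  {cls.value:<16s} {count:>3d}  ({t.percentages()[cls]}%)")
print(f"genuine-AP share: {genuine_ap_share(t):.1f}%  "
      "(Single + AttemptingTrain + Train; neurons firing true overshooting spikes)")

table = cohort_feature_table(cohort)
spiky = table.dropna(subset=["amplitude"])
print(f"\nspike morphometry over {len(spiky)} spiking neurons (first spike each):")
print(f"  amplitude  {spiky.amplitude.mean():6.1f} mV   half-width {spiky.half_width.mean():.2f} ms")
print(f"  threshold  {spiky.threshold_v.mean():6.1f} mV   depol rate {spiky.depol_rate.mean():.1f} V/s")
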