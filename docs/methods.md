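# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `inephys`. It is written for users who need to know
exactly what the numbers mean, and what passing the test suite does and
does not demonstrate about real recordings.

## Data model and exchange format

All analyses consume a `SweepSet`: a family of uniformly sampled traces
sharing one sampling rate and unit, each optionally paired with a
rectangular `StimulusStep`. Time is seconds internally; files may declare
a millisecond time column, converted on read. The exchange format is a
CSV sweep table plus a JSON protocol sidecar — inspectable, diff-able and
language-neutral. Values are printed at `%.17g` and parsed with
round-trip float precision, so `read(write(x)) == x` bit-identically
(property-tested). The time base must be uniform to a relative tolerance
of 1e-6; NaNs are rejected with their row/column. An Axon Binary Format
adapter can be registered behind the same `read_sweepset` contract but is
not required by any analysis.

## Activity coding

A *significant excursion* is a depolarizing deflection whose local peak
exceeds the within-step baseline by at least `min_rise` (default
**15 mV** — the coding rule itself never quantifies "significant", so
this is a package choice, configurable). The within-step baseline is the
median of the first 10 ms of the step response after a 2-ms settling
interval, and the excursion scan starts after that window so the
capacitive/RC settling transient is never read as an excursion.
Excursions end (and successive ones are separated) when voltage returns
below baseline + `min_rise`/2 — a hysteresis rule that prevents noise
from splitting one event. The overshoot criterion is **absolute 0 mV**,
not baseline-relative (regression-tested).

Sweep classes follow the five-level rules (Quiet / Attempting single /
Single / Attempting train / Train); the neuron-level class over a step
family is the **maximum** sweep class under the ordering — the natural
reduction when one class is assigned per neuron across a family.
Non-induced coding calls a neuron *Spontaneous* if any overshooting
excursion occurs in a stimulus-free recording.

## Spike morphometry

Threshold is operationalized as the voltage at the peak of d³V/dt³ during
the upstroke. Implementation details that matter:

* The upstroke runs from the last local minimum of the smoothed trace
  before the excursion peak (falling back to the window minimum for
  monotone rises) to the peak.
* Voltage is smoothed with a Savitzky–Golay filter (order 3, window
  default **1 ms**) before repeated finite differencing — raw third
  differences at 10 kHz are useless.
* The d³ search is restricted to the **acceleration phase** of the
  upstroke (up to the maximal dV/dt). Physiologically the threshold
  precedes the peak depolarization rate; numerically, the smooth rounding
  into the spike summit otherwise produces a second, larger d³ maximum
  that has nothing to do with threshold. The brute-force dense-grid
  oracle used in the tests applies the same restriction.

Derived features: amplitude = peak − threshold; overshoot = peak voltage
(amount above 0 mV); half-width = time between the two crossings of
threshold + amplitude/2 flanking the peak, linearly interpolated to
sub-sample precision; depolarization rate = max dV/dt on
[threshold, peak] in V/s. Resting V_m is the **median** of the
stimulus-free segment (robust to spontaneous spikes); input resistance is
ΔV/I between the pre-step baseline and the mean of the last 20% of a
hyperpolarizing step (−1 nA by default, configurable — a large test step
relative to the ±0.2 nA induction family, implemented as specified).

**Noise sensitivity.** The third derivative amplifies high-frequency
noise by ~(f/f_N)³; at 10 kHz with ≥0.3 mV RMS noise the threshold
estimate carries mV-scale uncertainty even after smoothing. The
oracle-agreement guarantees below therefore hold for noiseless templates;
on noisy recordings a wider smoothing window should be used, and
threshold scatter of a few mV across cells is expected.

## Voltage-clamp analysis

Peak transient inward current is the minimum in the first **10 ms** of
each step after **0.3 ms** of capacitive-transient blanking; sustained
outward current is the mean of the last **20%** of the step. These
windows are package defaults (configurable). No leak subtraction is
performed by default. Densities divide by whole-cell capacitance (pA/pF).

Conductance uses the driving force at the command potential,
G = I/(V_c − E_rev), with E_rev = +66.7 mV for the Na⁺ branch; inward
points at or beyond the reversal are excluded (the branch is ill-defined
there), and a point exactly at the reversal is dropped with a warning.
For the inactivation protocol the test step is fixed (0 mV default), so
the driving force is evaluated at the test potential.

Boltzmann fits use G = G_max/[1 + exp((V50 − V_c)/h)] for activation and
the mirrored sign for inactivation, so **h is reported positive for both
branches** with direction carried by `curve_type`. Nonlinear least
squares (trust-region reflective) starts from G_max = max G, V50 = the
voltage nearest half-max, h = 7 mV, with parameter tolerance 1e-8 and at
most 500 residual evaluations; non-convergence raises an error carrying
the last iterate. The availability window evaluates act∞·inact∞ on a
−120…+80 mV grid (step 0.5 mV); the crossing voltage solves
act∞ = inact∞ by bisection to 1e-6 mV.

## Synthetic recordings

The generators define the study conditions the tests run under.

**Current clamp.** Spikes are templated waveforms — a logistic rise
multiplied by an exponential decay (C∞ smooth; rise τ **0.8 ms**, decay τ
**4 ms** by default), not a conductance-based membrane model: the
classifier and morphometry need controllable ground truth, not
biophysical realism. The template is calibrated so its *operational*
threshold (the d³ criterion applied to the continuous waveform) lands
exactly at the requested threshold voltage; with the defaults this yields
half-widths near 5 ms and depolarization rates of ~25–30 V/s, in the
range reported for young induced neurons. Overshooting spikes peak at
**+25 mV** and sub-threshold attempts at **−20 mV** by default (±3 mV
jitter) — comfortably clear of the 0-mV rule boundary. Each neuron
carries a 2-s stimulus-free segment, the 1-s step family (−10…+190 pA,
20-pA increments by default; the increment is not fixed by the protocol
description and is configurable), and optionally a −1 nA resistance-test
step. Membrane noise is white Gaussian, default 0.3 mV RMS. Everything is
deterministic per seed, and ground truth (class, resting V_m, template
parameters) is stored in the SweepSet metadata.

**Voltage clamp.** Na⁺-like and K⁺-like currents obey
I = g_max·act∞(V_c)·avail(t)·(V_c − E_rev) with Boltzmann steady states.
Activation rises exponentially (Na τ 0.5 ms, K τ 3 ms); Na availability
relaxes first-order (τ 5 ms) from the pre-level steady state toward its
Boltzmann steady state at the step potential; K does not inactivate.
During the 80-ms activation steps the availability target is
voltage-dependent, which makes the measured peak-conductance factor vary
slightly across steps: the full simulate→extract→transform→fit round trip
therefore recovers V50 within **1 mV** and h within **5%** (tested over
random gating truths), while with inactivation negligible the recovery is
exact to within **0.1 mV / 1%**. A closed-form helper evaluates the
expected noiseless peak I–V (including both components and the transient
factor) on a dense time grid; extraction matches it within 1%. A brief
(τ 0.03 ms) capacitive charging transient is added at step edges to
exercise the blanking window. The inactivation protocol uses 200-ms
pre-pulses (−120…+80 mV, 5-mV steps) followed by a 200-ms test step to
0 mV, as is standard for steady-state availability curves.

**Fluorescence.** F(t) = F0·(1 + a·sin(2πft) + drift·t) + white Gaussian
noise, clipped at zero; 60 s at 5 Hz by default.

What the generators do **not** emulate: spike-frequency adaptation,
after-hyperpolarizations, voltage-dependent kinetics (τ–V curves), leak
and seal conductances, line-frequency artifacts, photobleaching
nonlinearity, and cell-to-cell correlation structure. Passing tests
demonstrates the estimators are correct under these controlled
conditions; they do not certify performance on pathological real-world
recordings.

## Calcium analysis

F0 defaults to the **mean of the lowest decile** of the trace — robust to
transients; with an oscillation present this baseline sits near the
trough, so the ΔF/F excursion of a pure sinusoid of relative amplitude
*a* is a/(1 − a), not *a*. Use `f0_method="mean"` when the baseline should
be the DC level. The spectrum is a single Hann-tapered periodogram of the
mean-subtracted, linearly detrended signal (detrending stops slow drift
from masquerading as 0–0.02 Hz power; a 300-sample trace leaves no room
for segment averaging, and resolution in the 0–0.1 Hz band dominates).
The PSD is normalized so that sum(psd)·Δf equals the variance of the
tapered signal (tapered sum of squares over the window power) — exact by
Parseval, tested to 1%. The band is (lo, hi] with the default upper edge
inclusive at 0.1 Hz; the exclusive lower edge drops the DC bin. With
60 s of data the bin width is 1/60 Hz, so band-peak frequencies are
quantized to ~0.017 Hz — the recovery guarantee is "within one bin".
Null behavior of the band peak was calibrated by Monte Carlo: for
noise-only traces the band peak-to-median-PSD ratio has median < 4 and
stays below 12 over 100 seeds, versus > 6 for a 0.3-amplitude
oscillation; single periodogram bins fluctuate too much for a hard
per-bin cutoff. Event counting uses peak prominence on ΔF/F (default
0.2); the prominence must sit well above the noise scale (≥~6σ) for a
clean zero on silent traces.

## Cohort statistics

Census percentages are rounded **half-up to integers** for report parity
(printed censuses of this kind use integer percents, occasionally not the
round-trip of the fraction — e.g. 29/36 = 80.6% printed as 80%); exact
proportions are always retained alongside. The genuine-AP share is
100·(Single + Attempting train + Train)/n. Two-group comparisons default
to **Welch** variance handling (a pooled-variance option exists);
multi-group uses one-way ANOVA with Tukey's post-hoc, and no further
multiple-testing correction is applied. 2^−ΔΔCt is computed exactly as
ΔCt = Ct_target − Ct_ref per condition, fold = 2^−(ΔCt_sample − ΔCt_control).
Degenerate comparisons (all groups constant and equal) return p = 1 with
a warning rather than NaN.

## Problem sizes

The test suite and the acceptance script run entirely on synthesized
data: two activity cohorts of 36 and 33 neurons (plus 37/34 for the
non-induced coding), 21-step activation and 41-step inactivation
voltage-clamp protocols at 10 kHz, 100-template threshold-oracle
comparisons, 200 Boltzmann noise replicates, and 100-seed-per-frequency
calcium recovery runs — sizes chosen so each check is statistically
meaningful while the whole suite completes in well under a minute.
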