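# Methods

This note documents the models, detection rules, and numerical choices the
package implements, including every place where a design was genuinely open
and a choice had to be made.

## Event detection and classification

A recording is segmented by a threshold/re-arm rule relative to a baseline
estimate: an event opens at the first upward crossing of baseline + 20 mV
while the detector is armed, closes at the next downward crossing of
baseline + 5 mV, and the detector then re-arms. Crossing times are linearly
interpolated between samples, so event boundaries have sub-sample
resolution. An event still open at the end of a record is closed at the last
sample.

**Baseline.** The resting potential is estimated from the quiet bulk of the
amplitude distribution: the median of samples below the trace's 60th
percentile (events push samples upward, so the lower 60% is almost entirely
inter-event baseline), plus a bias correction. Truncating a Gaussian at its
0.6 quantile shifts the subset median to −0.524 σ; dividing by the subset's
own standard deviation (0.6496 σ for the same truncation) gives a correction
of +0.807 × sd(quiet subset) that removes the bias under Gaussian recording
noise and vanishes on noise-free traces. Accuracy is ±0.3 mV at 1 mV noise.
Deep afterhyperpolarizations bias the estimate slightly downward at high
firing rates; at ≤ 1 Hz the effect is well under 1 mV.

**Classes.** Events ≤ 100 ms are spikes (the boundary itself counts as a
spike, with a 1 ns epsilon so floating-point noise cannot flip a
measure-zero case); events > 100 ms with at least two spikelets are bursts.
Long events with fewer than two spikelets — a case the classification rule
leaves open — get an explicit `other` class: they count toward total events
but never toward bursts. A *spikelet* is a local maximum above
baseline + 20 mV with prominence ≥ 5 mV, separated from its neighbours by
≥ 2 ms (`scipy.signal.find_peaks`); since any detected event crossed
threshold at least once, the count is floored at one.

**Spike shape.** Width is measured at half of (peak − baseline), walking
outward from the peak past the event bounds when the half level lies below
the detection threshold. Time-to-peak runs from the threshold crossing to
the peak sample. AHP amplitude is baseline minus the minimum within 200 ms
after the event's re-arm crossing, floored at zero, and flagged missing
(NaN) when the window is truncated by the end of the record. The 200 ms
window and the baseline reference (rather than threshold) for AHP are
package choices; both A/B thresholds are configurable.

**A/B phenotype.** The first run of ten consecutive spike-class events is
averaged; mean AHP > 25 mV ⇒ A, < 20 mV ⇒ B, values inside [20, 25] ⇒
`ambiguous` (rather than a forced assignment), fewer than ten usable spikes
⇒ `none` with the count reported.

**Per-cell summary.** Twelve parameters per cell: capacitance, membrane
potential, event/spike/burst frequency, event/spike/burst duration, burst
factor (#bursts / #events; missing, not zero, for an empty table), active
time (Σ event durations / analysis duration), event amplitude
(mean peak − baseline), and days in culture. Membrane potential is the mean
of three 50 ms window medians at the beginning, middle, and end of the
analysis period; medians reject any spike falling inside a window.

## Synthetic recordings

The generator emulates perforated-patch current-clamp records: 10 kHz
sampling, white Gaussian noise (default sd 0.8 mV, a calibration knob, not a
measured value) shaped by a 4-pole Butterworth low-pass at 2 kHz, resting
potential −51.4 mV, and a renewal event process. Inter-event gaps are a hard
refractory period (the template length plus 10 ms) plus an exponential draw
with mean 1/rate − refractory, so the mean gap is exactly 1/rate; rates too
high for the refractory period are rejected. Each event is a burst with
probability `burst_fraction`, otherwise a single spike.

Spike templates are piecewise exponential (rise to peak, fall through the
AHP minimum, recovery to within 1 mV of baseline): A-type peaks +32 mV with
a 30 mV AHP and 3 ms time-to-peak; B-type peaks +30 mV with a 12 mV AHP and
9 ms time-to-peak, so A is narrower and faster than B and both stay clear of
the ambiguous 20–25 mV AHP band (a generator guarantee; per-event amplitude
jitter of 3% is small enough to preserve it). Burst templates are a
depolarized plateau 22 mV above baseline carrying Gaussian spikelet bumps
(+8 mV, prominence ≥ 5 mV) with soft edges, so the event duration measured
by the detector equals the nominal plateau duration to within a few ms.
Ground-truth event boundaries are computed from the clean waveform with the
same threshold/re-arm geometry the detector uses, which is what makes exact
recovery testable at zero noise.

Cohorts draw capacitance from sex-specific normals (4.41 ± 1.7 pF male,
4.91 ± 2.1 pF female, clipped at 0.5 pF) and days in culture uniformly from
1–4. Condition presets encode the emulated study conditions: basal rates
0.53 Hz (male) and 0.70 Hz (female); CRH-evoked bursting with burst
fractions 0.73 (male), 0.48 (female B cells), and 0.64 (B cells with added
BK conductance); CRH-evoked spiking as a rate increase to 2 Hz without
bursting. Spontaneously bursting cells (a subset of B cells; A cells never
burst) get a 10% basal burst fraction with at least one burst guaranteed,
and their bursts are deferred until after ten leading single spikes
(`burst_free_head=10`) so the basal A/B phenotype is always measurable — a
generator guarantee in the same spirit as the ambiguous-band exclusion.

What the generator does **not** emulate: electrode drift and access-
resistance artifacts, the within-cell correlation structure of real spike
trains (real bursts cluster; the renewal process has no memory), cell-to-
cell variability in spike shape beyond amplitude jitter, and any secretion
or calcium dynamics. Tests passing on synthetic cohorts therefore validate
the *pipeline's* correctness and calibration, not the biological values
themselves.

## Model corticotroph

No measured corticotroph model was available to build on, so the package
ships a minimal three-variable pituitary-type cell — membrane potential V,
delayed-rectifier activation n, A-current inactivation h — with logistic
steady-state activations and first-order kinetics:

    C dV/dt = −[gCa·m∞(V)(V−VCa) + gK·n(V−VK) + gA·a∞(V)·h(V−VK)
               + gL(V−VL)] + I_app + I_noise + I_inject
    τn dn/dt = n∞(V) − n,   τh dh/dt = h∞(V) − h

Units are consistent by construction (nS·mV = pA, pA/pF = mV/ms). Stochastic
drive is an Ornstein–Uhlenbeck current with 10 ms correlation time,
integrated by Euler–Maruyama at a fixed step (default 50 µs, hard cap
100 µs); the integrator loop is numba-compiled, with a pure-Python path for
arbitrary per-step clamp hooks that is verified to match the compiled path
bit-for-bit on noise-free runs.

**B-like preset** (the burst-competent phenotype): C = 3 pF, gCa = 2.5 nS
(VCa = 60, vm = −18, sm = 8), gK = 4 nS (VK = −75, vn = −5, sn = 10,
τn = 60 ms), gA = 0, gL = 0.8 nS (VL = −56), noise 1.2 pA. This combination
was calibrated to satisfy four constraints at once: a stable rest near
−52 mV (noise-free runs converge to a fixed point), noise-driven single
spikes at 0.2–1 Hz whose AHP stays under 20 mV, a CRH response in range (see
below), and — the delicate one — pseudo-plateau bursting when a fast BK
conductance is added. The bursting mechanism needs the spike upstroke to be
faster than the 2 ms BK lag (hence the small C and steep Ca activation) and
the depolarized plateau to be only marginally stable (hence the slow τn), so
that BK truncates spikes into plateau spikelets while channel noise still
terminates each plateau after a few hundred ms. Faster τn or weaker gK locks
the cell at a depolarized fixed point; stronger gK collapses the plateaus.
Under CRH with gBK ∈ {0, 0.5, 1, 2} nS the detector-measured burst factor
rises monotonically (≈ 0, 0.11, 0.36, 0.99 averaged over ten seeds).

**A-like preset**: gA = 3 nS (va = −20, sa = 10, vh = −65, sh = −5,
τh = 20 ms) sharpening the spike, with gCa = 3, gK = 7, τn = 40 ms, noise
2.4 pA, and VK = −105 mV. The deep VK is an explicit calibration device, not
a physiological estimate: with rest near −52 mV a > 25 mV AHP is unreachable
against a −75 mV K reversal, and rather than add a second AHP mechanism the
preset exaggerates the driving force of the one it has. The preset fires at
~0.5 Hz with mean AHP ≈ 26 mV and resists BK-induced bursting (burst factor
stays at 0 under CRH + 1 nS BK), which is the qualitative A-phenotype
contract; it is a calibration goal, not a hard invariant.

**CRH stimulus.** `crh_stimulus(params, level)` scales a depolarizing
applied current, 1.5 pA at level 1, which depolarizes the noise-free B-like
cell by 4.1 mV (the 3–6 mV band of the real response) and roughly
quadruples the noise-driven event rate. All model constants are package
calibrations and labelled as such.

## BK dynamic clamp

The clamp computes f∞(V) = 1/(1 + exp((vf − V)/sf)), advances
τBK df/dt = f∞(V) − f by forward Euler, clips f to [0, 1] (guarding
overshoot at the stability boundary), and injects I_BK = gBK·f·(VK − V).
Defaults: gBK 1 nS, vf −10 mV, sf 2 mV, τBK 2 ms, VK −75 mV, step 21 µs.
The software clamp uses a fixed step (deterministic and testable) where
real-time hardware used a variable step of the same average; the ≤ 100 µs
bound is enforced, as is dt ≤ τBK for the explicit scheme's stability. VK is
exposed as a parameter since the clamp and the cell may assume different K
reversals. In closed loop, cell and clamp share the clamp's step; with
gBK = 0 the run is bit-identical to an unclamped simulation (the activation
variable is advanced either way, and injecting exactly 0 pA perturbs
nothing), which pins down the null-clamp contract exactly.

## Features, PCA, trajectories

The 12-parameter per-cell matrix is log-transformed in event frequency and
event duration (zeros handled by a half-minimum offset recorded in the
output metadata), then filtered: while any pair of features has |Pearson r|
≥ 0.8, the member of an offending pair with the largest mean |r| over its
over-cutoff partners is dropped (ties break toward the larger overall mean
|r|, then the later column), and the removal log is returned. A replication
mode removes an explicitly named set instead. The filter is idempotent.

PCA standardizes columns to zero mean and unit variance — the features have
incommensurate units (pF, Hz, ms), so the correlation rather than covariance
structure is the meaningful one — and decomposes by SVD. Components are
ordered by variance and each loading vector is flipped so its
largest-magnitude entry is positive, making scores reproducible across runs
and platforms. Basal and stimulated states are fitted jointly (both states
share one plane); projecting stimulated cells onto a basal-only fit is
available through `PCAResult.project`. Trajectories are per-cell score
displacements.

## Statistics

Fisher's exact test enumerates all 2×2 tables with the observed margins in
log space (lgamma); the two-sided p sums hypergeometric probabilities not
exceeding that of the observed table, with a 1e−7 relative tolerance for
ties — the minimum-likelihood convention matching R's `fisher.test`. A
doubling rule is available behind a flag. A zero margin yields p = 1 by
convention with a warning. Welch's t-test computes the statistic and
Welch–Satterthwaite degrees of freedom from summary statistics or raw
samples; only the t tail probability comes from scipy. `cohort_compare`
assembles the phenotype and bursting contingency tables (cells that are
neither A nor B are excluded from the A-vs-B table), applies the declared
log transforms, and emits one tidy row per test. Linear and mixed-effect
modelling with post-hoc contrasts is deliberately out of scope — those are
off-the-shelf inferential steps, not part of this package's contribution.

## Problem sizes and determinism

Default problem sizes: 62 s recordings (a ≥ 60 s basal analysis window plus
margin), 59-cell default cohort, 50-cell calibration cohorts, 20 s
closed-loop runs × 10 seeds for the burst-rescue experiment. Every random
draw flows from a single integer seed (numpy `default_rng` for generation;
the compiled integrator seeds its own generator), and equal (spec, seed)
gives bit-identical traces, truth lists, and results.

## Known limitations

- The model cell is a caricature: two K mechanisms, no calcium dynamics, no
  SK/secretion coupling; burst termination is noise-driven rather than
  governed by a slow variable, so plateau durations are exponentially
  distributed rather than stereotyped.
- The A-like preset's deep VK trades physiological realism for phenotype
  fidelity with a minimal current set.
- The baseline estimator's bias correction assumes Gaussian noise; strongly
  skewed artifacts would shift it.
- Welch p-values printed for real cohorts cannot be reproduced exactly from
  rounded summary statistics; the implementation is validated against its
  own closed form and scipy instead.
- ABF import and multi-conductance clamps are extension points, not
  implemented features.
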