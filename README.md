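# corticotroph

Analysis toolkit for the electrical excitability of anterior-pituitary
corticotrophs — the ACTH-secreting cells of the HPA stress axis — built for
studying how spontaneous and CRH-evoked activity differs between cell
phenotypes and between cohorts (for example male vs female cells).

It packages five things that normally live in ad-hoc lab scripts:

1. **Synthetic recordings** (`corticotroph.synthgen`) — current-clamp voltage
   traces with known ground truth: ~0.5 Hz single-spike firing on a −51 mV
   resting potential at 10 kHz with 2 kHz low-pass character, A-type spikes
   (sharp upstroke, afterhyperpolarization > 25 mV) or B-type spikes (slower,
   AHP < 20 mV), and pseudo-plateau bursts (> 100 ms, ≥ 2 spikelets). Whole
   labelled cohorts can be generated, so every downstream stage is testable
   without recorded data.
2. **Event detection and phenotyping** (`corticotroph.events`) — the
   threshold/re-arm segmentation used for these cells: an event opens when V
   rises Δ20 mV above baseline and closes when it falls below Δ5 mV; events
   ≤ 100 ms are spikes, events > 100 ms with ≥ 2 spikelets are bursts. Cells
   are classified A/B from the mean AHP of 10 consecutive spikes, and each
   recording is condensed into 12 excitability parameters (capacitance,
   membrane potential, event/spike/burst frequency and duration, burst
   factor, active time, event amplitude, days in culture).
3. **A model corticotroph** (`corticotroph.modelcell`) — a minimal
   conductance-based cell (V, n, h) obeying

   `C dV/dt = −[gCa·m∞(V)(V−VCa) + gK·n(V−VK) + gA·a∞(V)·h(V−VK) + gL(V−VL)] + I_app + I_noise + I_inject`

   that rests near −51 mV, fires noise-driven spikes at ~0.5 Hz, and
   depolarizes by 3–6 mV under a CRH-like drive.
4. **A BK dynamic clamp** (`corticotroph.dynclamp`) — forward-Euler
   integration of `τBK df/dt = f∞(V) − f` with
   `f∞(V) = 1/(1 + exp((vf − V)/sf))`, injecting `I_BK = gBK·f·(VK − V)` into
   the model cell each step (default step 21 µs, at most 100 µs; typical
   gBK 0.5–2 nS, vf = −10 mV, sf = 2 mV, τBK = 2 ms). Adding this fast
   conductance converts single-spike firing to pseudo-plateau bursting — the
   burst-rescue experiment.
5. **Features and statistics** (`corticotroph.features`,
   `corticotroph.stats`) — the 12-parameter feature matrix with a ≥ 0.8
   correlation filter and standardized PCA (deterministic sign convention),
   per-cell basal→CRH trajectories in the PC plane, and the cohort tests:
   two-sided Fisher's exact test (minimum-likelihood rule, as in R) for
   phenotype counts and Welch's t-test for continuous metrics, with log
   transforms for event frequency and duration.

## Worked example

Generate a labelled A-type recording, detect its events, and phenotype it:

```python
from corticotroph.synthgen import TraceSpec, make_trace
from corticotroph.events import detect_events, summarize_cell, classify_cell

lt = make_trace(TraceSpec(duration_s=62, event_rate_hz=0.7, spike_kind="A",
                          burst_fraction=0.1, min_bursts=1, seed=42))
table = detect_events(lt.trace)
s = summarize_cell(lt.trace, table)
ab = classify_cell(lt.trace, table)
print(f"events: {len(table)}  burst factor: {s.burst_factor:.3f}")
print(f"event frequency: {s.event_freq_hz:.3f} Hz")
print(f"membrane potential: {s.membrane_potential_mv:.1f} mV")
print(f"cell class: {ab.label} (mean AHP {ab.mean_ahp_mv:.1f} mV "
      f"over {ab.n_spikes_used} spikes)")
```

prints

```
events: 39  burst factor: 0.077
event frequency: 0.629 Hz
membrane potential: -51.4 mV
cell class: A (mean AHP 32.4 mV over 10 spikes)
```

39 events in 62 s is 0.63 Hz, typical spontaneous corticotroph activity; 3
of them are bursts (burst factor 0.077); the mean AHP of the first ten
consecutive spikes (32.4 mV > 25 mV) marks the cell A-type.

The same pipeline runs from the shell — a full two-sex cohort
(29 male cells: 3 A / 25 B / 1 neither, 13 spontaneously bursting;
30 female cells: 12 A / 17 B / 1 neither, 6 bursting) end to end:

```sh
corticotroph pipeline --replicate-reference --seed 1 --out results/
```

which detects and classifies every cell and prints the cohort test table,
including Fisher p = 0.0148 for the A/B phenotype proportions and
p = 0.0539 for spontaneous bursting. Individual stages are exposed as
`corticotroph simulate | modelcell | dynclamp | detect | summarize | pca |
stats`, each taking `--config <json>` and `--seed`.

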