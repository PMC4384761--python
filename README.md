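# thetaloop

Closed-loop, theta-phase-triggered stimulation of hippocampus — simulated,
detected, and analysed end to end.

## The problem

A long-standing hypothesis holds that the hippocampal theta rhythm (4–12 Hz)
temporally segregates **encoding** of new information from **retrieval** of
stored information: entorhinal input dominates CA1 near one phase of theta,
CA3 input near the opposite phase. Testing this causally requires triggering
an intervention at a *specific phase* of the ongoing rhythm, in real time,
while an animal performs a task whose encoding and retrieval demands are
spatially separated — an end-to-end T-maze in which reward-location cues are
available only in the sample arms (encoding segment) and the choice must be
driven by memory in the central arm (retrieval segment).

This package implements that entire experimental logic as testable code, for
researchers building or analysing closed-loop phase-triggered experiments:

- **`synthetic_lfp`** — an LFP generator with asymmetric theta cycles (the
  falling phase outlasts the rising phase by a configurable ratio),
  high-gamma (60–80 Hz) bursts locked to a fixed theta phase, 1/f noise,
  and a 200–400 µV biphasic deflection evoked by each light pulse.
- **`closed_loop`** — the causal online detector: forward-only 4–12 Hz
  Butterworth filter, two-sample extremum comparator, refractory period
  (one pulse per theta cycle), stimulation-zone gating, and a processing
  latency, emitting 10 ms pulses.
- **`phase_metrics`** — offline zero-phase filtering + Hilbert phase
  (0° = peak, increasing through the falling phase), circular statistics of
  stimulation phase (circular SD = √(−2 ln R)), extremum-to-pulse latency,
  and the high-gamma power landmark that serves as an absolute within-cycle
  phase reference.
- **`spectral`** — multitaper spectra (DPSS, time–bandwidth 2, 3 tapers)
  and pulse-aligned evoked averages with dummy alignment.
- **`behavior_sim`** — a generative T-maze model: reward-side balancing
  P(reward left) = P(chose right in last 12 trials), uniform interleaving of
  baseline/peak/trough trial labels, and choice accuracy specified per
  outcome-history trial type (win-stay/lose-switch structure).
- **`behavior_stats`** — per-mouse binomial tests against each mouse's own
  baseline accuracy (both the exact one-sided tail and the pdf-at-k rule
  used to score the published per-mouse table), trial-type breakdowns, the
  tie-corrected Friedman test, Wilcoxon rank-sum occupancy tests, and the
  label-shuffling bootstrap for the 2×2 (task segment × trigger phase)
  **double dissociation**.

## The statistic at the core

For mouse *m*, condition *c* ∈ {retrieval, encoding} and label
*s* ∈ {peak, trough}, let k/n be the correct-trial count and p₀ the same
mouse's baseline accuracy. A quadrant (c, s) of the 2×2 design is classed
**up / down / null** per mouse from the binomial significance of k/n versus
p₀, and is *consistent* when ≥ 3 of 4 mice agree. The matched diagonal
A = {retrieval×trough, encoding×peak} and complementary diagonal
B = {retrieval×peak, encoding×trough} exhibit the double dissociation when
one diagonal is consistently enhanced while the other is consistently
unchanged. Shuffling the trial labels within each (mouse, condition) —
preserving label counts — and reclassifying 10,000 times yields the null
probabilities `p_any_diagonal` and `p_both_diagonals`; a tiny-cohort mode
enumerates the permutation distribution exactly.

## Worked example

The numbered drivers under `analysis/` run the full chain and print what
they find (`python analysis/01_simulate_lfp.py`, then 02…07). Output from a
run with the default seed:

```
peak-triggered: 480 pulses, delay 21.6 ± 1.6 ms (closed form 23.2 ms)
peak: phase 64 ± 6 deg (n=480, 100% falling phase)
trough: phase -116 ± 5 deg (n=480, 0% falling phase)
evoked deflection: 335 uV peak within 50 ms of the pulse
high-gamma landmark at theta phase -170 deg (modulated: True)
  peak-triggered pulses before the landmark (mean -126 deg)
  trough-triggered pulses after the landmark (mean 54 deg)
```

The detector fires once per theta cycle ~21.6 ms after the true extremum
(filter phase delay + comparator + processing latency), placing
peak-triggered pulses on the falling phase and trough-triggered pulses on
the rising phase — before and after the high-gamma power peak respectively.
The behavioral chain then reproduces the published group numbers from the
per-mouse accuracy table and the dissociation statistic:

```
diagonal hits: matched pairing A=True, complementary B=True
shuffled-label null (10000 reps): p(any diagonal)=0.0013, p(both diagonals)=0.0001
zero-effect calibration: 0/200 cohorts (0.0%) show a spurious observed dissociation
```

A `thetaloop` console script exposes the same steps
(`simulate-lfp`, `simulate-behavior`, `detect`, `analyze`, `bootstrap`,
`run-all`) for file-based workflows.

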