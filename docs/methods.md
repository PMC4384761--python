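# Methods

This note documents the models, numerical choices and known limitations of
the package, in the order data flows through it.

## Synthetic LFP

**Theta.** The theta component is a phase-warped cosine: the instantaneous
phase advances piecewise-linearly so the falling half-cycle (0°→180°)
occupies the fraction `asym/(1+asym)` of each cycle. The warp is monotone
and invertible, keeps 0° on the waveform peak, and makes the generative
phase available in closed form. Default `asym = 1.3`, a mid-range value for
hippocampal theta asymmetry (the rising phase is reliably the shorter one);
the asymmetry tests use 1.5 where the effect must be unambiguous. Default
amplitude 350 µV and frequency 8 Hz are typical of mouse CA1 during
locomotion.

**High gamma.** 60–80 Hz bursts (default 70 Hz carrier, 30 µV) are
amplitude-modulated by a von-Mises-like window
`exp(κ(cos(φ − hg_phase) − 1))`, κ = 4, centred on the **Hilbert**
instantaneous phase of the theta component rather than the warp phase.
These are two different conventions on an asymmetric wave; the Hilbert
angle of the band-limited component is the standard definition of
instantaneous phase in phase–amplitude coupling analyses, and using it at
generation time makes the configured burst phase directly recoverable by
the same convention the analysis uses. Default `hg_phase = 180°` (bursts
near the local theta trough) places the landmark after peak-triggered and
before trough-triggered stimulation, the ordering expected when high gamma
marks entorhinal-coupled phases.

**Noise.** Broadband 1/f^1 Gaussian noise (default SD 80 µV) synthesised in
the frequency domain with random phases. With these defaults the in-band
(4–12 Hz) noise is small relative to theta, so phase targeting is tight;
real recordings carry nonstationary theta and movement artifacts that widen
the phase distributions (observed circular SDs of ~54–63° versus ~6° here).
Passing tests therefore validate the *machinery* (filters, comparator,
statistics), not detector performance on noisy in vivo data.

**Evoked response.** Each pulse adds a biphasic kernel — a
difference-of-exponentials lobe (rise τ/4, decay τ, τ = 12 ms), negative
first, with a 45 % rebound delayed 1.5 τ — peak-normalised to
`evoked_amp` (default 300 µV, the middle of the reported 200–400 µV range)
and ~60 ms total extent. No functional form is published for the in vivo
response; only its amplitude and ~50 ms extent constrain the choice. The
~50 ms deflection is what raises beta-band (16–25 Hz) power in stimulated
spectra.

## Online detector

The causal path is a forward-only 2nd-order Butterworth bandpass (4–12 Hz)
followed by a two-sample comparator: a peak trigger fires at sample *t*
when `y[t−1] > y[t]` and `y[t−1] ≥ y[t−2]`. The comparator is the simplest
rule that confirms an extremum one sample after it occurs; the original
software's exact rule is unpublished. A refractory period (default 83 ms,
one cycle at the 12 Hz band edge) enforces one pulse per theta cycle, and
triggering is gated to half-open stimulation-zone intervals. No amplitude
gate is applied by default; an optional threshold exists for noisy traces.

**Latency decomposition.** For a steady sinusoid the filtered waveform is
shifted by the filter's *phase delay* −∠H(ω)/ω (≈ 7.2 ms at 8 Hz for this
design), not its group delay (~52 ms at 8 Hz), which applies to envelope
transients. The closed form used throughout is
`phase delay + 2 samples + processing latency`. The default processing
latency of 14 ms (software + LED path) is calibrated so the end-to-end
clean-trace delay is ~23 ms closed-form / ~21.6 ms measured, matching the
~21.7 ms reported for systems of this design; at 8 Hz this places
peak-triggered pulses ~64° into the falling phase.

## Offline analysis

Offline phase is `filtfilt` (zero-phase) 4–12 Hz Butterworth followed by
the analytic-signal angle, in degrees on (−180°, 180°] with 0° at filtered
maxima and phase increasing through the falling half. True extrema for
latency measurement are the samples where this phase crosses 0° (peaks) or
wraps at ±180° (troughs), ties to the earlier sample; delays are measured
to the nearest *preceding* extremum (whether the original analysis used
preceding or nearest is unstated; preceding matches the causal reading).
Circular dispersion is the Mardia convention √(−2 ln R).

The high-gamma landmark averages the 60–80 Hz zero-phase envelope in 20°
theta-phase bins (no published bin width; 20° balances resolution against
per-bin sample count) over baseline signal and takes the maximal bin's
centre. A flatness threshold of 0.15 on (max−min)/mean flags unmodulated
envelopes, e.g. when `hg_amp = 0`. Landmark error is therefore quantised to
the bin width; recovery tests accept ≤ 15° median error.

Multitaper spectra use DPSS tapers (time–bandwidth 2, 3 tapers — the
published setting), eigenspectra averaged over tapers then segments,
zero-padded to the next power of two. Segment length is configurable,
default 1 s (the published segmentation is unstated). Peak-location tests
use the taper resolution half-bandwidth tw/T, the correct resolution scale
for multitaper estimates. Evoked averages report mean ± SEM across pulses;
dummy alignment recomputes trigger times on a pulse-free trace.

## Behavioral model

The choice model assigns each trial one of four outcome-history types —
previous outcome × whether the cue repeats or switches the rewarded arm —
with baseline accuracies {incorrect/switch 0.82, correct/stay 0.72,
correct/switch 0.32, incorrect/stay 0.40} (the win-stay/lose-switch bias)
and additive per-(condition, label) stimulation effects, clipped to [0, 1].
This is the minimal model sufficient for the reported type-conditional
accuracies; it has no latent strategy state. A session's first trial has no
type and is excluded from type-conditional tallies (its choice is drawn at
the mean baseline). Reward sides follow the balancing rule
P(left) = fraction of right choices over the last 12 trials. Labels are
i.i.d. uniform over {baseline, peak, trough} (block-balanced assignment is
possible in principle but unstated; i.i.d. is assumed). Occupancy times are
log-normal (σ = 0.35) with medians 1.5 s (central arm), 2.5 s / 6.5 s
(sample-arm inbound/outbound), drawn from the reported 1–2 s and 2–3 s /
5–8 s ranges; stimulated-trial pulse counts are Poisson at
occupancy × 8 Hz. One known gap: the emergent overall baseline accuracy is
~0.50–0.55, slightly below the observed 57–59 %, because the type mixture
induced by the balancing dynamics differs from the real task's.

## Binomial significance rules

Two rules are implemented. `binomial_pvalue` is the adaptive one-sided
exact tail (upper tail when k/n ≥ p₀, lower otherwise), by direct
summation. `binomial_pdf_pvalue` is the probability mass *at* the observed
count; comparing it to α is unusual as a test, but it reproduces the
published per-mouse p-values from the printed accuracy table at 50 trials
per label (e.g. pmf(41; 50, 0.56) = 0.0001) where tail probabilities do
not, so it is the classification rule the dissociation analysis uses by
default (`method="tail"` switches to the tail rule).

## Double-dissociation bootstrap

Per repetition, stimulation labels are permuted within each
(mouse, condition) preserving label counts — the exchangeable null for
interleaved labels; equivalently, per-label correct counts are multivariate
hypergeometric, which the exhaustive mode enumerates exactly for small
cohorts. Quadrants are classed up/down/null per mouse and *consistent* when
≥ 3 of 4 mice agree — including consistent no-change, which the published
definition counts as a behavior. A diagonal *hits* when its two quadrants
share a consistent non-null direction, or (default `count_no_change=True`)
when it is a consistent null pair while the complementary diagonal carries
the effect — so the full observed pattern (one enhanced diagonal, one
consistently unchanged diagonal) hits both. Two stricter variants are
flagged: `count_no_change=False` (only effect-carrying diagonals hit) and
`require_off_diagonal_null=True` (an effect diagonal hits only if the other
diagonal is null). The exact null event behind the published probabilities
is ambiguous between these readings; none is claimed exact, and the
reported numbers land at the same order (≈ 0.001 / ≈ 0.0001) under the
default.

Because per-label trial counts are unpublished, the reference cohort is
reconstructed from the printed per-mouse accuracies at 50 trials per label
(150 analysed trials per condition, equal label probability);
`round(p·50)` quantises odd-hundredth accuracies by half a trial, which is
why reconstructed group means can differ from printed ones by up to
0.5 percentage points. Analyses are limited to the first 150 trials per
condition throughout.

## Problem sizes

Signal-level analyses use 20–60 s traces at 1 kHz (a few hundred theta
cycles — ample for filter, latency and landmark statistics); seed sweeps
use 20 seeds; the bootstrap uses the full 10,000 repetitions and the
zero-effect calibration 200 generative cohorts. All randomness flows from
explicit seeds; generation is byte-deterministic given (config, seed).
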