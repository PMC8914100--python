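# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `isapac`, and what the synthetic validation does and
does not demonstrate.

## Signal model and preprocessing

The object of study is infraslow activity (ISA): EEG fluctuations in the
0.01–0.1 Hz band, and the dependence of peripheral arousal signals
(skin-conductance / GSR, respiration) on its instantaneous phase.

Preprocessing per channel:

1. **EEG** — zero-phase Butterworth bandpass 0.01–0.1 Hz (order 2 per
   pass, applied forward–backward, effective order 4), then the Hilbert
   analytic signal at the native sampling rate, giving phase θ(t) ∈
   (−π, π] and envelope a(t) ≥ 0. Instantaneous frequency is the central
   finite difference of the unwrapped phase divided by 2π (one-sided at
   the ends).
2. **GSR / respiration** — zero-phase highpass at 0.01 Hz (drift
   removal), then the Hilbert envelope. "Amplitude" means this envelope
   by default; the signed highpass-filtered value is available via
   `peripheral_amp="filtered"`.
3. **Decimation to 1 Hz** happens *after* filtering and the Hilbert
   transform. Because the retained content sits at or below 0.1 Hz —
   far under the 0.5 Hz output Nyquist — plain sample-picking is
   alias-free and no second anti-aliasing filter is applied. A
   regression test pins this order; extracting the analytic signal from
   an already-decimated series measurably distorts the phase.

The filter family and order are deliberate choices, not givens:
Butterworth for its flat passband at these extreme low frequencies,
order 2 per pass because higher orders are numerically fragile with
normalized cutoffs near 4·10⁻⁵. Both are configurable.

**Edge guard.** A 0.01 Hz edge implies transients lasting tens of
seconds. The first and last 100 s (configurable) of every analytic
series are flagged invalid and excluded from all statistics by default.

**Non-finite samples** in a recording raise immediately rather than
being interpolated — silent repair would bias every downstream
statistic.

## Phase–amplitude coupling

The circle is partitioned into 8 equal, left-closed bins covering
(−π, π] (the final bin closes at +π). Peripheral amplitude samples (1 Hz)
are grouped by the simultaneous EEG phase bin; the bins with maximal and
minimal **median** amplitude are selected (the mean variant is a switch),
and those two bins' raw samples are compared by

d′ = |μ₁ − μ₂| / ((σ₁ + σ₂)/2),

with sample (n−1) standard deviations — a configurable convention, since
either denominator choice is defensible — plus a two-sided Welch t-test
(pooled-variance optional). Per-channel tests are reported uncorrected;
Bonferroni/FDR switches exist but are off by default, matching the
per-channel reporting convention this pipeline reproduces.

Two statistical caveats are properties of the method itself and are
reproduced deliberately:

* **Extreme-bin selection bias.** Because the compared bins are chosen
  for extremity, the t-test is anti-conservative under the null: with
  i.i.d. amplitude noise and ~7000 one-hertz samples the measured
  false-positive rate at α = 0.05 is ≈ 0.27, and the null d′ floor is
  ≈ 0.1 (range statistics of 8 bin medians). The test suite measures and
  reports this floor from an independent i.i.d. oracle rather than
  asserting uniform null p-values.
* **Autocorrelation.** One-hertz samples of a 0.01–0.1 Hz process are
  serially dependent, so nominal sample sizes overstate the effective n.

Subject summaries: fraction of channels with p < α, arithmetic mean of
channel d′, and the circular mean (resultant angle) of per-channel
preferred phases. A resultant length ≤ 10⁻⁹ makes the circular mean
undefined: the strict API raises, while pipeline summaries record NaN
with a warning (uncoupled data with quantized bin centres hits this
case routinely).

## Coherence statistics

ICPC and ITPC are both the mean-resultant length R = |N⁻¹ Σ exp(iθₙ)| —
over channels at matched definition points, or over trials at a fixed
time t after onset (epochs are the first 30 s post-onset, 31 points at
1 Hz). ITPC significance uses a timing-permutation null: N phases drawn
uniformly with replacement from all valid time points of the recording,
10⁴ permutations by default, with the +1-corrected empirical p-value so
p is never zero.

**Lag scan.** A single-signal resultant cannot depend on a lag, so the
two-signal statistic is the mean resultant of the *phase difference*
series — the standard phase-locking value — evaluated at lags −60..+60 s
(1 s steps, configurable; positive lag = peripheral signal delayed
relative to EEG). The peripheral phase entering the scan is the
ISA-band (0.01–0.1 Hz) Hilbert phase of the amplitude *envelope*: the
envelope is the quantity coupled to ISA, whereas the phase of the raw
highpassed peripheral signal reflects its carrier and is uninformative.
The significance reference is the 95% level of best-lag PLV over 1000
replicates of i.i.d. uniform-phase series of the same length; it depends
only on series length and lag grid, so it can be computed once and
shared.

**Known limitation.** That randomized-phase null is calibrated for
phase-scrambled signals only. Independent but *autocorrelated* phase
series (two unrelated quasi-periodic oscillators) reach best-lag PLVs of
~0.15 against a null95 of ~0.06–0.07, so the null is anti-conservative
for realistic uncoupled signals; the analysis scripts show this
directly on the uncoupled cohort. Detection claims should lean on the
designed-lag recovery, not on the null threshold alone.

## Group machinery

The median split ranks subjects by channel-average d′ (descending; ties
broken by subject id) and takes the top half; an all-tied cohort is
undefined without an explicit tie-break seed. Per-time-point group
comparisons pool subject × channel values as independent samples (e.g.,
12 × 64 = 768 for a full cohort) — a convention that ignores
within-subject correlation; a subject-level variant is available. The
ITPC group test is two-sided; the instantaneous-frequency test against
the first-10-s baseline is one-sided (decrease), unpaired by default
with a paired option. GSR epoch traces get mean ± SEM only.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as plausible study conditions:

* **Background:** Fourier-synthesized 1/f noise (PSD ∝ f^slope,
  slope −1, so the log-log *magnitude* slope is −0.5) in every channel,
  5 µV sd against a 10 µV ISA oscillation.
* **ISA:** a master oscillator around f₀ = 0.05 Hz whose instantaneous
  frequency is a mean-reverting random walk (innovation sd
  0.005 Hz·s^−½, reversion timescale 60 s) reflected at the 0.01/0.1 Hz
  band edges. A pure reflected walk would mix toward the band centre
  (0.055 Hz) and forget f₀, so reversion is required for the oscillator
  to be "around f₀" in any stationary sense. EEG channels share this
  phase up to wrapped-normal offsets (sd 0.3 rad), which sets the
  attainable inter-channel coherence.
* **Peripheral coupling:** GSR is a positive conductance baseline plus
  an in-band carrier (0.3 Hz; respiration 0.25 Hz ≈ 15 breaths/min)
  whose envelope is 1 + 0.9·m·cos(φ(t − lag) − φ_pref). Coupling the
  *envelope* rather than adding a slow sinusoid is essential: the
  Hilbert envelope of an additive slow component is phase-blind, and the
  envelope is what the default analysis path measures. The envelope
  model simultaneously gives the lag scan a well-defined ISA-band
  envelope phase carrying the designed lag (GSR 0 s, respiration 10 s
  by default). m ∈ [0, 1] is the modulation fraction; m = 0 is the null.
* **Trials:** onset times from uniform 30–90 s trial lengths plus
  15–45 s pauses (41 trials attempted over 7200 s by default). At each
  onset the master phase is redrawn from a von Mises distribution around
  a fixed reset angle; concentration κ = 0 means no reset, κ ≈ 8
  produces onset ITPC ≈ 0.6 after filtering (the narrowband filter
  smears the instantaneous reset over ~10 s) decaying over the epoch as
  frequency jitter decorrelates trials.

Determinism: every random element derives from the config seed; equal
configs give bit-identical recordings.

What the generator does **not** emulate: EEG topography, ocular/EMG
artifacts (the analysis band excludes them anyway), physiological
skin-conductance response kernels, non-stationary arousal drift. Passing
tests therefore validate the *statistical machinery* — recovery of
designed coupling phases, depths, lags and resets — not the
physiological claims one might make on real recordings.

## Validation scales

The test suite and analysis scripts run reduced problem sizes chosen to
keep ensembles statistically meaningful: phase-recovery ensembles use
100 single-channel sessions of 7200 s generated at 4 Hz; the group study
uses 24 subjects × 8 EEG channels × 25 trials at 2400 s per session;
permutation-calibration checks use 200 repetitions at 1000 permutations.
File I/O round-trips use 16-bit EDF, so sample agreement is bounded by
one part in 2¹⁶ of each channel's range.

## Dataset reproduction

The pipeline reads BioSemi BDF/EDF recordings with BIDS-style events
tables, so it can be pointed at the public meditation dataset it was
designed around (OpenNeuro ds001787, 64-ch EEG + GSR + respiration at
256 Hz) after a manual download; none of the bundled analyses require
it, and no automated download is provided.
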