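# Methods

This note documents the models, estimators and numerical choices behind
padpipe: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Signal model and session container

A session is a set of uniformly sampled channels (nerve-cuff neurogram,
EMG, wrist torque) on one clock, plus trial, stimulation and optional
spike logs.  Canonical internal rates are 40 kHz (neurogram), 5 kHz
(EMG) and 1 kHz (torque); `harmonize_rates` resamples heterogeneous
hardware rates on load with polyphase anti-alias filtering
(`scipy.signal.resample_poly`), preserving duration to within one sample
period.  Epoch membership is always half-open `[start, end)`, so a
stimulus on a boundary belongs to the later epoch and the epoch cells
partition the trial.

All filters in the pipeline are 4th-order Butterworth applied
forward–backward (zero phase).  Hardware chains in real rigs are causal
and heterogeneous; zero-phase filtering avoids group-delay bias in onset
estimates at the cost of acausal smearing, which is why onset estimators
are compared against analytic oracles with a tolerance of roughly the
filter rise time (≈ 40 ms at 5 Hz) rather than a sample.

## Behavioural epoching

* **Torque onset** — the paper-style "arbitrary threshold on the
  derivative" is made concrete as `k·SD` of the Rest-window derivative
  (default `k = 3`) sustained for ≥ 50 ms.  Two guards handle degenerate
  input: the threshold never falls below 2% of the peak derivative in
  the search window (otherwise a noise-free rest would give a zero
  threshold), and a trial with no suprathreshold torque excursion of at
  least the short-hold fraction of the target is classified as
  no-movement rather than given a spurious onset.
* **Torque offset** — first zero crossing of the movement-signed
  derivative after its peak; when the derivative is asymptotically
  positive (ideal noise-free ramps) the first fall below 2% of the peak
  substitutes, and a trial with neither is flagged.
* **EMG onset** — rectified, 10 Hz low-passed trace exceeding the Rest
  mean + 5 SD for ≥ 50 ms.  The amplitude statistics are computed on the
  rectified *unsmoothed* Rest trace: with statistics taken after heavy
  smoothing the threshold collapses towards the smoothed mean and brief
  (< 50 ms) bursts smeared by the filter would pass the persistence
  rule, defeating its purpose.
* **EMG offset** — among local maxima of the < 3 Hz-smoothed rectified
  EMG within ±300 ms of torque offset, the one with the largest drop to
  its subsequent trough.  "Largest difference" is ambiguous between
  peak-to-trough and peak-to-baseline; peak-to-trough is used because it
  yields a unique point without requiring a baseline convention.  No
  local maximum ⇒ fall back to torque offset, flagged.
* **Outcomes** — no-movement, wrong-direction (sign of torque at the
  first crossing of the short-hold threshold after Go), short-hold
  (minimum torque between the peak and 1 s after onset below a
  configurable fraction of target, default 0.25, admissible band
  0.143–0.375), else success; success is promoted to *perfect* when all
  five epochs were completed without flags.  Only perfect trials enter
  the modulation analysis; success ∪ short-hold trials enter the
  performance analysis.

The representative agonist per direction is the EMG channel with the
earliest mean onset across that direction's trials.

## Volley quantification

Sweeps are aligned to stimuli over [−0.3 s, +10 ms]; a 0.5 ms blanking
window zeroes every stimulus artifact *globally* before alignment, so
neighbouring pulses of the 10 Hz train cannot leak artifacts into
another sweep's baseline (at 10 Hz the −0.3 s baseline necessarily
overlaps earlier stimuli; the documented error for overlapping sweeps
therefore fires only when spacing undercuts the 10 ms post-stimulus
analysis window, which is what actually corrupts measurement).
Baseline statistics come from −0.3 to −0.1 s of the average.

Detection requires |average − baseline mean| > 2 SD sustained > 0.2 ms
with excursion onset < 5 ms.  Landmark finding reuses the sustained-run
rule to identify lobes — the global extremum of a 10 ms window would
exceed 2 SD by chance alone — then takes onset/inflection/offset as
baseline crossings (inflection = crossing nearest the midpoint of peak
and trough when several exist; monophasic volleys have
inflection = offset).  Areas integrate per lobe at the native sample
period with the negative lobe sign-inverted, after per-sweep baseline
subtraction, making the measure offset-invariant and gain-linear.

Normalisation is per volley: z-scores against the Rest-epoch area
distribution (population SD, `ddof = 0`), which fixes the Rest mean at
exactly 0.  Normality of the Rest distribution is checked
(Shapiro–Wilk) and deviations are logged, never fatal.  At least 20
Rest measures are required.

## Modulation statistics

Per-epoch means use perfect trials only.  Event-aligned profiles slide
a 0.2 s bin in 0.1 s steps over ±1 s (19 bins); population CIs are
t-based across volleys.  Contrasts: paired t vs the Rest level (0) with
Bonferroni size 4 per direction; the static aggregate (Delay + AH
pooled) with size 2; flexion-vs-extension paired t on aggregated cells.
Correction sizes are configuration — the event-series default of 11
follows the printed convention even though a full ±1 s sweep has 19
bins, since the tested sub-span is a reporting choice.  Zero-variance
contrasts (identical inputs) return t = 0, p = 1 rather than NaN.

The many-to-one rank comparison is implemented as standardised
Mann–Whitney statistics against the control with max-statistic
permutation p-values (seeded, default 10 000 permutations): exact by
construction for the family it controls, replacing tabulated critical
values.

## Decomposition

FastICA (tanh contrast, symmetric decorrelation, tol 1e-6, ≤ 1000
iterations, seeded) on the `(2·n) × 4` epoch-mean matrix; at most 4
components.  Identifiability conventions: components are unit-norm with
their largest-magnitude entry positive, amplitude carried in the
weights, components ordered by weight energy.  Bootstrap CIs resample
rows with replacement; each replicate is aligned to the reference by
greedy maximal |Pearson correlation| (cosine similarity when a profile
is near-constant, where correlation is undefined), sign-flipped to
positive correlation; replicates whose best match falls below |r| = 0.5
are dropped and counted.  Percentile 2.5/97.5 bounds are reported for
component entries and median weights.  Reconstructed time courses use
representative epoch durations (Delay 0.5 s, AM 0.2 s, AH 1 s,
PM 0.2 s) at 100 points/s with a 10-point moving average.

The canonical latent patterns used by the population generator — an
AM-centred transient `(0.15, 1, 0.2, 0.1)` (normalised) and a sustained
pattern orthogonalised against it — deliberately avoid pure coordinate
vectors: a unit-norm component whose mass sits entirely in one entry
lies on the boundary of the parameter space, and bootstrap percentiles
of normalised entries cannot cover such a boundary point even when the
pattern itself is recovered with |r| > 0.999.

## Performance, oscillations, PSTH

Tertile splits sort ascending with stable ties; both extreme groups get
`n // 3` trials and remainders go to the intermediate group, keeping
the paired contrast balanced.  Ten behavioural measures are computed per
trial (reaction time; AH torque mean/SD; peak speed/acceleration and
latencies from the < 5 Hz-filtered torque; AH EMG mean/SD from the
rectified 10 Hz-smoothed agonist; success flag), with the stated subset
z-normalised per recording day.  Contrasts pair large vs small tertile
means across volleys.

Oscillation screening band-passes torque 3–100 Hz and EMG 3–200 Hz
without rectification; spectra are Hann-tapered single-sided amplitudes
of 1 s post-onset, truncated below 60 Hz and compensated for the
taper's coherent gain; autocorrelations of the 0.3–1 s segment are
normalised to r(0) = 1, low-passed below 60 Hz, and the *first* strict
local maximum at positive lag qualifies only with r > 0.3 and lag
25–350 ms (2.86–40 Hz) — a first peak outside the window disqualifies
the trial rather than deferring to a later peak.

PSTHs use 0.5 ms bins over [−50, +10] ms with baseline statistics from
the pre-stimulus bins; the response peak is the contiguous
above-(mean + 2 SD) run around the maximal bin within 0.5–5 ms
(monosynaptic latency bounds), and its above-baseline area per stimulus
estimates the response probability.  For the epoch contrasts the
response window is detected once from the *pooled* histogram and shared
across epochs: per-epoch windows widen with stimulus count and would
bias comparisons between epochs of very different size.  Binomial tests
are exact and two-tailed with the Rest probability as the null
parameter (degenerate p₀ ∈ {0, 1} handled explicitly).  Because the
test conditions on the estimated Rest probability, epochs whose true
probability equals Rest can occasionally reach nominal significance;
this is a property of the procedure, not of the implementation.

## The synthetic generator

`generate_session` emulates the statistical structure the analysis
assumes: trial skeletons with the task's stated timing (0.8 s rest,
0.7 ± 0.2 s delay, 0.7–1 s hold, spring-driven passive return), a
logistic torque ramp (10–90% rise time 150 ms; plateau defined
2.5 rise-times after onset), EMG as Gaussian noise amplitude-modulated
by phasic (gain 8, movement) plus tonic (gain 3, hold) envelopes with
EMG leading torque onset by 60 ms, and a neurogram of white noise plus,
per stimulus, a saturating 0.3 ms artifact and a biphasic
negative-then-positive raised-cosine volley (1 ms total) at the
conduction latency (0.13 m at 65 m/s ⇒ 2 ms, centre of the plausible
group I/II range).  Volley amplitude is
`base × epoch_gain(direction, epoch) × (1 + Σ wₖ·patternₖ[epoch]) ×
(1 + CV·ε)` with amplitude CV 0.15 and neurogram noise 0.1× the volley
amplitude.  Error trials (no movement / wrong direction / short hold)
are injected at exact per-direction counts; spike trains give each
stimulus an epoch-dependent response at 1.2 ± 0.1 ms over 5 Hz Poisson
background.  Everything is bit-reproducible given the seed.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: drifting electrode contact and
non-stationary noise, volley waveform changes over a session, muscle
crosstalk and movement artifacts in EMG, correlated trial-to-trial
excitability states, or orthodromic contamination of the nerve volley.
Parameter recovery here demonstrates the estimators' correctness under
the stated model, not robustness to those real-world failure modes.

Population-scale questions (ICA, statistical calibration, tertile
power) use compiled-measures generators
(`generate_profile_population`, `generate_null_epoch_means`) that draw
per-volley epoch means directly — the contrasts consume compiled
measures, so simulating thousands of full signal sessions would add
cost without information.

## Problem sizes

Tests and the acceptance script run the generator at 20 kHz neurogram,
2 kHz EMG, 500 Hz torque and 8–20 trials per direction; population
analyses use 77 volleys (matching the decomposition's 154 × 4 design),
bootstrap sizes of 150–1000, and 600–3000 null replicates for
calibration.  These sizes keep every Monte-Carlo standard error well
inside the asserted tolerances; the full-rate defaults (40 kHz etc.)
remain the package defaults.

## Known limitations

* Onset estimators inherit the zero-phase filters' acausal smear; onset
  times are accurate to tens of milliseconds, not samples.
* Percentile bootstrap CIs for ICA components need a few hundred
  replicates before their tail estimates stabilise; below that, widths
  fluctuate by more than 20%.
* The binomial epoch contrast treats the Rest probability as known
  (see above) and is mildly anticonservative when Rest and test epochs
  have comparable stimulus counts.
* Steel-type permutation p-values are exact only for the exchangeable
  null of identical distributions, not for pure location shifts with
  unequal variances.
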