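# Methods

This note documents the models, conventions and design choices behind the
package, what the synthetic-data generators do and do not emulate, and the
problem sizes used by the validation studies.

## Trial design

A session is `n_runs × trials_per_run` trials (default 8 × 64 = 512),
split exactly into quarters over the four conditions (zero words; one
word; two words sequential; two words simultaneous). Each trial has three
183 ms frames separated by 50 ms ISIs (649 ms of stimulus; the nominal
"650 ms" is treated as rounding), two character strings per frame (top and
bottom, six strings in all), frame 3 always a false-font post-mask, and a
3651 ms response window. After every block of five trials (and at run
end) a blank of 4, 6 or 8 s is drawn uniformly.

Counterbalancing is exact, not in expectation: one-word trials split
equally over frame {1,2} × location {top,bottom}; sequential pairs put
word 1 in frame 1 equally often top/bottom with word 2 at the opposite
location in frame 2; simultaneous pairs split equally over frames 1 and 2.
Divisibility is checked up front and violations raise configuration
errors.

**Word-list balancing.** The balancing algorithm (unspecified beyond its
goal in the source protocol) sorts words into joint quantile strata of
(log frequency, neighborhood size), deals them round-robin into groups,
and hill-climbs random swaps until the worst pairwise group-mean gap of
both standardized statistics is below a tolerance (default 0.05). The
session draws legible words from groups sized to the conditions' demands
(128/128/256/256 of a 768-word lexicon for the default configuration);
the zero-word group is never shown legibly and seeds the filler pool.
Because 512 trials × 6 slots exceeds 768 words, fillers are sampled *with
reuse* from the words never shown legibly; "presented exactly once" is
enforced for legible presentation only.

## Evidence-accumulation models

Activation for a word rises linearly at slope *s* (default 0.01
evidence/ms) until it reaches a recognition threshold (θ_high = 1.0 for
high-frequency, θ_low = 1.6 for low-frequency words) or until the next
frame interrupts processing (per-frame window = SOA = 233 ms). The BOLD
prediction is the area under activation, summed over words: θ²/(2s) for a
completed word under the default reset-at-threshold convention, sT²/2 for
an interrupted word. A plateau variant (activation held at threshold
until window end) is kept as an option; both variants preserve the
qualitative orderings that matter, with one exception noted below.

Defaults were chosen so that sequential words complete (θ_low/s = 160 ms
< 233 ms) while limited-parallel simultaneous words do not
((s/κ)·233 = 0.932 < θ_high with κ = 2.5). The source models were
explicitly not fit quantitatively to data; these parameters reproduce
every qualitative pattern.

- **Serial:** one word at a time. Simultaneous trials: word 2 starts at
  word 1's crossing and is truncated at the window end. Predicts a
  positive but reduced simultaneous frequency effect.
- **Limited-capacity parallel:** sequential trials identical to serial;
  simultaneous trials accumulate both words at s/κ for the full window.
  When the reduced slope cannot reach θ_high, areas are
  threshold-independent and the simultaneous frequency effect is exactly
  0.
- **Unlimited parallel:** simultaneous identical to sequential per word.
  Predicts no difference between presentation conditions (rejected by the
  behavioral cost of simultaneous presentation).
- **Hybrid parallel-then-serial:** both words rise sublexically in
  parallel to a fraction of threshold (default one half); lexical
  completion is serial. Word B's sublexical evidence is maintained in an
  *activity-silent* state — its BOLD-generating activation returns to
  baseline during the wait and resumes from the maintained level once
  word A is recognized. This concretization was chosen deliberately: a
  sustained hold at level h would add area h(θ−h)/s to word B, making the
  two defining constraints (equal per-word areas; simultaneous total =
  sequential total) unattainable simultaneously. With activity-silent
  maintenance both constraints hold exactly (each word contributes
  θ²/(2s)) while the second word's trace keeps its characteristic jagged
  rise–drop–re-rise shape. An optional post-mask interruption truncates
  word B; it is off by default.

**Known non-monotonicity.** Under the reset convention, a completed
word's area θ²/(2s) *grows* as the effective slope shrinks, so total area
is not monotone in the interference factor κ across the
crossing/no-crossing boundary; monotonicity in κ holds under the plateau
variant, and that is how it is tested. Relatedly, the simultaneous-pair
total under reset (217.2) is numerically closer to the sequential
low-frequency total than to the high-frequency one; under the plateau
variant the simultaneous totals sit below the sequential high-frequency
total, matching the qualitative "similar to sequential high" description.
The discriminating prediction (zero vs. positive simultaneous frequency
effect) is unaffected by the choice.

## Eye-tracking quality control

Pipeline order is fixed: run gate → trial gate → drift correction → event
detection.

- **Run gate:** per-trial SD of 2-D gaze over the 250 ms pre-onset window
  (pooled radial SD, √(var x + var y)); the run is excluded iff the
  across-trial *median* SD exceeds 1°. Per-axis SD would be an
  alternative reading; the pooled form is used and flagged here.
- **Trial gate:** a sample is unacceptable if missing or more than 10°
  from the fixation mark (strict); the trial is analyzable iff at least
  80 % (inclusive) of stimulus-window samples are acceptable.
- **Drift correction:** per-trial median (x, y) over the pre-onset
  window for trials with ≥ 90 % acceptable pre-onset samples, then the
  coordinate-wise across-trial median. If no trial qualifies the run is
  analyzed uncorrected and flagged (raw positions are used).
- **Blinks:** maximal runs of pupil = 0 lasting ≥ 100 ms within the
  stimulus window.
- **Saccades:** velocities from a 5-sample moving-window central
  difference (the standard companion to ellipse-threshold detection —
  the criterion itself specifies only the ellipse); ellipse radii are 4 ×
  the horizontal/vertical median-based SDs (√(median v² − (median v)²),
  floored at ε), computed from 250 ms pre-onset through stimulus offset.
  Candidate events are maximal supra-ellipse runs lasting ≥ 6 ms;
  adjacent runs separated by < 4 ms are merged (unstated in the source;
  prevents double-counting); events are kept iff 1° < amplitude < 15°.
- **Fixation breaks:** distance from the corrected fixation > 1.5°
  sustained ≥ 100 ms, any blink, or any saccade with vertical extent
  > 1.5°.
- **Word fixation:** cumulative gaze time inside the word's bounding box
  during its 183 ms frame ≥ 50 ms.

Tie rules: "at least"-type thresholds (80 %, 90 %, 100 ms, 50 ms, 6 ms)
are inclusive; "more than"-type thresholds (1.5°, 10°, 1°, 15°, 1° run
gate) are strict. Duration thresholds convert to sample counts by ceiling
(rounding toward inclusion) at the configured rate (default 500 Hz);
boolean decisions on noise-free inputs are invariant from 250 to 1000 Hz.

## Statistical analyses

Behavioral accuracy is the fraction of correct count reports within the
3.65 s response period after the final frame offset; later or absent
button presses count as no-response and are excluded. Response times are
measured from the critical-frame (frame 2) onset; trials with two
simultaneous words in frame 1 and one-word trials with the word in frame 1
are excluded from RT analyses (zero-word trials are retained, since every
analyzed RT is measured from frame-2 onset). Stimulus items are coded as
the concatenation of the two words (frame order for sequential pairs,
top-then-bottom for simultaneous — the storage order of placements), the
single word, or a randomly chosen frame-1/2 filler suffixed `_ff` on
zero-word trials.

Gaussian mixed models are fit by maximum likelihood with statsmodels
`MixedLM`: random intercept and slopes by subject via `re_formula`, the
stimulus-item intercept as a variance component. ML (not REML) is used so
BIC comparisons across nested fixed-effect structures are valid. A fixed
convergence ladder (full slopes → drop item component → subject intercept
only) runs on failure and every reduction is recorded in the result.
Binomial models (accuracy) use the variational `BinomialBayesMixedGLM`
with subject and item random intercepts; random slopes are reduced to
intercepts for this family and recorded. The four-level condition factor
uses reference dummy coding with the zero-word condition as reference
(two-word models use the sequential condition as reference).

F tests and contrasts follow the single-trial reporting convention:
denominator DF = number of observations − number of fixed effects. This
convention is anticonservative relative to subject-level DF when
subject-level variance dominates a contrast; the type-I calibration study
below quantifies the operating behavior under the generator's default
variance mix. FDR correction across ROIs is Benjamini–Hochberg step-up at
q = 0.05. The Bayes factor is the BIC approximation
exp((BIC₀ − BIC₁)/2), labelled approximate: it is not expected to match
toolbox Bayes factors computed on trial-averaged data without random
slopes.

**Item effects at scale.** In generated sessions every trial carries a
unique stimulus string, so within a subject the item effect is confounded
with the residual; across subjects sharing a session it is identified but
enters `MixedLM` as a subject-nested component. The large-scale recovery
studies therefore generate item variance but absorb it into the residual
when fitting (a recorded ladder reduction): the slope estimate is
unbiased either way, and a single replicate fits in well under a second
instead of ~40 s. A dedicated test verifies that the item variance
component is recovered when items truly repeat and fitting includes it.

## Synthetic-data generators

- **Lexicon:** Zipf values on a deterministic piecewise-linear quantile
  grid through (0, 2.2), (0.5, 4.1), (1, 6.1) — range and median match
  the stimulus set exactly up to grid resolution; tokens are unique
  random five-letter strings; neighborhood sizes are Poisson(2.5), a
  realistic count scale for five-letter words.
- **Betas:** β = intercept + b₀ + item + (slope + b₁)·W + condition and
  low-frequency-pair terms + residual. Presets for pOTS-words,
  mOTS-words and mFus-words use the published number-of-words slopes
  (0.116, 0.100, 0.109 psc/word) as generating truths, with subject
  slope SD 0.05, item SD 0.05, residual SD 0.4 (values that produce
  standard errors of realistic magnitude), subject intercept SD 0.10 and
  a zero-word intercept of 0.2 psc. Sequential low-frequency pairs get a
  larger boost (0.04–0.06) than simultaneous ones (0.01), emulating the
  attenuated simultaneous frequency effect.
- **Behavior:** per-condition accuracies (0.95/0.88/0.89/0.84) and
  lognormal RTs ordered as observed (one-word slower than zero-word,
  simultaneous slower than sequential); 1.3 % no-response rate; errors on
  missed-word simultaneous trials report "1" 94 % of the time. The
  per-condition means are order-of-magnitude choices — the source figures
  are not tabulated numerically. Optionally, accuracy is linked to the
  accumulator: simultaneous trials whose second word is left unfinished
  lose a fixed accuracy penalty.
- **Gaze:** gaussian fixation noise (default SD 0.05°) around an optional
  drift offset; injected minimum-jerk saccades, pupil-zero blinks, and
  ramped excursions, all recorded in a truth table. Not emulated: smooth
  physiological drift, pupil dynamics beyond loss, tracker-specific
  artifacts, or saccadic main-sequence velocity profiles — so detector
  recovery rates here bound performance on idealized, not raw, data.

## Power analysis

Per-subject condition means are drawn as sequential = 0.32 + δ and
simultaneous = 0.32, both with SD 0.2 (the prior-study calibration), and
tested with a two-sided paired t at α = 0.05 (the minimal standard choice;
the original test is unstated). The suppression delta is a required
input: the original effect size is not published, so the package reports
which δ calibrates an 18-participant design to 90 % power
(δ ≈ 0.23 psc, d ≈ 0.81, for independent condition draws) as a
calibration exercise rather than asserting it. The closed-form
noncentral-t power is the oracle; simulation agrees within Monte-Carlo
error, and the minimal-n rule applies a running-maximum smoothing before
thresholding.

## Problem sizes and validation studies

- Slope recovery: 20 replicates per ROI preset, 20 subjects × 384 trials
  (pOTS-words) and 15 × 384 (mFus-words); mean recovered slope within
  ±0.02 of truth.
- Type-I calibration: 200 replicates of a null sequential/simultaneous
  contrast at 20 subjects × 128 trials; rejection within 2 binomial SEs
  of 0.05.
- FDR: the step-up implementation equals a brute-force oracle on
  0.01-grid p-vectors of every length up to 6 (exhaustive at length 1, a
  large seeded grid sample above — full enumeration at length 6 would be
  ~10¹² vectors).
- Saccade detection: ≥ 95 % recovery of injected 2–10° saccades at noise
  SD ≤ 0.1°, ≤ 1 false alarm per 100 pure-noise trials.
- Power: 5000 Monte-Carlo replicates per grid point, agreement with the
  closed form within 3 Monte-Carlo SEs.

## Limitations

The package operates downstream of beta estimation: no hemodynamics, raw
BOLD time series, preprocessing, or surface analyses. Model parameters
are illustrative, not fit to data. The binomial mixed model is a
variational approximation with intercept-only random effects. Synthetic
gaze is idealized; real tracker data would need upstream parsing and
calibration handling. Passing recovery tests demonstrates that the
machinery is correct under the generative assumptions, not that those
assumptions exhaust real data.
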