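# Methods

This note documents the models, numerical choices and known limitations of
`oculomet`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The battery and its parameters

The package models a four-test clinical video-oculography battery.  Each
saccadic test (prosaccade, antisaccade, memory-guided saccade) comprises 12
horizontal trials (targets at ±5, ±10 or ±20° of visual angle) followed by
8 vertical trials (±5 or ±12°), each eccentricity appearing twice in a
seeded random order; the sinusoidal smooth-pursuit test comprises 6
horizontal and 6 vertical trials.  Gaze is expressed in degrees with the
screen centre at (0, 0), right/up positive.

Extracted parameters fall into three domains:

* **time** — latency (go signal → onset of the first qualifying saccade;
  the go signal is target onset, or central-target offset for memory
  trials), return-saccade latency, corrected-antisaccade latency, and
  pursuit gain (eye velocity / target velocity);
* **spatial accuracy** — signed endpoint error, |final gaze eccentricity| −
  |reference eccentricity| along the trial axis (overshoot positive,
  hypometria negative; positive and negative errors are averaged
  separately), and pursuit error (mean absolute eye−target position
  difference);
* **success** — % correct antisaccades, % corrected antisaccades
  (denominator: erroneous trials), % successful antisaccades (correct +
  corrected over attempted), % correct memory saccades, pooled over planes.

The feature vector has 29 entries: 12 plane-resolved time/accuracy
parameters × 2 planes, 4 pooled success percentages, and the early-saccade
total.

## Synthetic cohorts

No public recordings accompany the published group tables, so the
generator is a first-class, tested component: every downstream stage is
validated against cohorts whose ground truth is known exactly.

**Hierarchy.**  A subject's latent parameter means are drawn from the
published group (mean, SD) marginals as truncated normals — latencies
≥ 80 ms, percentages in [0, 100], pursuit gain in [0, 1.5], signed errors
confined to their sign — and trial-level values are drawn around the
subject means (within-subject SDs: 40 ms for visually-guided latencies,
120 ms for volitional ones, 0.5° for endpoint errors; declared defaults).
A published SD of zero is honoured as a degenerate distribution (every
subject at the mean).

**Kinematics.**  Saccades are raised-cosine displacement segments obeying
a main-sequence duration rule `T = d0 + k·|A|` (defaults d0 = 20 ms,
k = 2 ms/deg), which makes peak velocity saturate in amplitude.  Traces
carry white Gaussian positional noise (SD 0.3°, 0.15° off-axis) and
Poisson blink spans (0.1 s⁻¹, 150 ms) flagged invalid.  Pursuit trials are
`eye = gain·target + offset + noise`, with the positional offset chosen to
realize the subject's drawn pursuit error and flipped in sign through
saccadic transitions at Poisson times (a stand-in for catch-up
corrections).  The pursuit sinusoid is ±20° H / ±12° V at 0.25 Hz
(configurable; unpublished device settings).  Stimulus windows are 1,000 ms
fixation, 1,500 ms visually-guided target, and 4,500 ms response windows
for the antisaccade and memory tests so that multi-second volitional
latencies fit (declared assumptions).

**Truth as oracle.**  Physical consistency clamps what can be injected: an
endpoint error cannot push a landing across the midline, a "correct"
memory saccade must land beyond the 50% amplitude criterion, a response
must fit its stimulus window, and a subject's pursuit error cannot fall
below the floor `(2/π)·A·|1 − gain|` implied by their own gain.  Together
with the truncations this shifts *realized* cohort means away from some
printed means (most visibly pursuit error, % corrected in severely
impaired groups, and large-SD gains).  The per-trial `SubjectTruth` record
therefore stores realized values, aggregated exactly as the extractor
aggregates measurements, and parameter-recovery tests compare extraction
against that oracle.  Generator fidelity to the printed values is checked
separately at the latent-draw level, where truncation is negligible for
the cells tested.

**Independence idealization.**  Only marginal means/SDs are published, so
features are sampled independently within subject.  Real oculomotor
parameters are correlated; independence inflates multivariate
separability, which is why synthetic classification performance should be
read as an upper bound and why the acceptance checks for the classifier
are one-sided (at least the published AUC).  What passing tests show is
that the pipeline's machinery is correct under the published group
distributions — not that clinical data would reproduce the same numbers.

The `sample_feature_matrix` path draws ready-made feature vectors directly
from the marginals (including `% successful`, which in trace-level cohorts
is instead *derived* from sampled outcomes; the published success
marginals are mutually inconsistent under independence, and the direct
sampler follows the printed distribution for each feature separately).

## Event detection and extraction

Saccades are detected on the trial-axis position: invalid samples are
bridged by linear interpolation, velocity is estimated with a centred
Savitzky–Golay differentiator (window ≈ 50 ms, order 2), and contiguous
runs with |v| ≥ 30 °/s lasting ≥ 10 ms with displacement ≥ 1° become
events; events overlapping invalid spans are dropped.

At 100 Hz the smoothing kernel is as wide as a short saccade, and the raw
threshold crossing is dragged several milliseconds early.  Event times are
therefore refined on the *unsmoothed* position, where the signal-to-noise
ratio is high: start/end levels come from plateau medians flanking the
run, the half-amplitude crossing pins the saccade's temporal centre
(sub-sample, smoothing-invariant), and a one-parameter least-squares fit
of the sigmoid displacement template around that centre recovers the
duration; onset/offset are centre ∓ half duration.  On real data the
template is an approximation to actual saccade shape; residual onset bias
is below ~2 ms on the synthetic benchmark (versus ~15 ms for raw
crossings).

Further conventions, all configurable on `DetectionParams`:

* anticipatory floor 80 ms — earlier saccades count as *early* and are
  excluded from latency statistics;
* the final position for endpoint errors folds in a corrective saccade
  starting ≤ 100 ms after the primary offset and averages a short
  post-saccadic fixation window (noise suppression);
* corrected-antisaccade latency is referenced to stimulus onset by default
  (`"error_offset"` re-references it to the erroneous saccade's end —
  the published definition is ambiguous between the two);
* a memory response is correct iff directed to the remembered side with
  ≥ 50% of the target eccentricity (declared tolerance); a trial with no
  response stays in the denominator as incorrect;
* blink robustness: when the only evidence of a response was obliterated
  by a blink, outcomes fall back to fixation-position scoring (an
  antisaccade "correction" that leaves the eye resting on the mirror side,
  a memory response parked at the remembered location, a mirror-directed
  saccade launched from the target side).  Without these fallbacks,
  blink-lost events depress success percentages by about the blink rate ×
  event duration (~2%), which is visible at cohort scale;
* pursuit: saccades are detected on the eye−target residual (the pursuit
  component itself may exceed the velocity threshold); gain is the median
  ratio of smoothed eye to target velocity where the target exceeds 20% of
  its peak velocity (identical filtering cancels in the ratio); pursuit
  error is the mean absolute deviation by default, RMS optionally; trials
  under 50% valid are excluded.

Aggregation averages time/accuracy parameters within plane, pools success
percentages over planes, and propagates empty denominators as missing
(never zero).

## Statistics

Crude p-values: one-way ANOVA with Tukey HSD (scipy).  Adjusted p-values:
OLS with treatment-coded group plus age and sex (binary indicator), with
pairwise contrasts tested on the fitted model — "adjusted" means
covariate-adjusted, without an additional Tukey step, and no
multiple-testing correction is applied across parameters, matching the
source analysis layout.  The sedative count joins the covariates for
exactly those parameters whose Spearman correlation with it has p < 0.1
(a screen whose type-I rate under independence is ~10%, verified by
simulation).  Subjects with missing covariates are dropped listwise.
Neuropsychology panels report Spearman ρ with crude p and an age-adjusted
p from a raw-scale linear model.

## Classification

The pairwise pipeline: z-normalization with the training column mean and
sample SD (ddof = 1) stored and re-applied verbatim to held-out or
external rows; univariate selection keeping features whose two-sample
t-test (the two-group ANOVA) reaches p < 0.001, after excluding any
feature with a missing value (availability is not label-dependent, so this
screen runs on the whole cohort without leakage); Fisher discriminant
ratio ranking `(μ₁ − μ₂)²/(σ₁² + σ₂²)` — the summed-variance denominator
is used because a difference of variances is sign-indefinite and the score
must be non-negative, zero exactly when the class means coincide, and
infinite only for zero-variance separation (flagged explicitly); then the
classifier.  A PLS2 projection (NIPALS with component-wise deflation;
`X = TPᵀ + E`, `Y = UQᵀ + F`, orthogonal X-scores, exact reconstruction at
full rank) is available for the regime where features outnumber subjects,
off by default; both the "FDR-selected raw features" and the "PLS scores"
readings of the original pipeline are runnable.

Model search evaluates SVMs (linear and RBF, C = 1, unpublished
hyperparameters left at convention) and KNN (k ∈ {1, 3, 5, 7}) by 5-fold
cross-validated AUC with selection inside each training fold, breaking
ties toward the simpler model (linear before RBF, larger k first).

The confidence loop re-randomizes a stratified five-way partition each
iteration (four subsets train, one tests — an 80/20 split), refits the
pipeline on the 80% and scores ROC AUC and accuracy on the 20%; the report
carries best/worst/mean over (by default) 1,000 iterations and requires at
least 5 subjects per class.  Feature selection defaults to running inside
each training split (leakage guard); `selection="cohort"` fixes the
feature list once on the full sample before the loop, which matches the
published procedure (the per-pair feature list was frozen before the
external cross-validation loop) and is what the acceptance script uses.
Whether the original 80/20 splits were the five disjoint folds of one
partition or fully re-randomized is unstated; re-randomization was chosen
as the stronger interpretation for a confidence interval.

External validation applies a fitted pipeline to new rows with no
refitting (stored normalization, stored features) and reports AUC and
confusion counts.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed; cohort generation spawns
per-subject child seeds so runs are reproducible subject-by-subject, and
a pipeline rerun under the same config is byte-identical.  The test suite
validates parameter recovery on 200-subject-per-group trace-level cohorts
(3 SE criterion per group and parameter) and runs the classifier loops at
the published group sizes with 1,000 iterations; closed-form pursuit
checks use high-rate analytic sinusoids (5 kHz) so grid discretization
sits below the 10⁻⁶ tolerance.

## Known limitations

* No between-feature covariance, no age/sex coupling to oculomotor
  parameters, and no disease-severity gradient within group — the
  generator reproduces marginals, not joint structure.
* Saccade kinematics are "good enough to exercise detection": no
  oculomotor-plant dynamics, no curved trajectories, no pupil or
  microsaccade modelling; blink artefacts are clean invalid spans rather
  than the lash-induced position excursions real trackers produce.
* The detector's template refinement assumes roughly symmetric saccadic
  velocity profiles; on real data from other devices the velocity
  threshold, minimum amplitude and smoothing window likely need retuning.
* Trace-level success percentages and pursuit errors realize shifted means
  relative to the printed tables (truncation and consistency clamps, see
  above); analyses that need the printed marginals exactly should use the
  direct feature sampler.
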