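# Methods

This note documents the models, default parameters, numerical choices, and
limitations behind `cfserp`.  It is written for someone who wants to trust —
or challenge — what the package computes.

## 1. Experimental design model

The generator reproduces a within-subject 2 (expression: fearful, neutral) ×
3 (contrast: low, medium, high) × 2 (CFS, noCFS) design plus one face-absent
catch condition per visibility condition: 14 conditions × 60 trials = 840
trials, in seven blocks of 120, with a detection + discrimination response
prompt on a random third of trials.  The calibration pretest presents faces
at four fixed contrasts (5, 15, 25, 35% by default) plus catches, 48
repetitions each (240 trials, four blocks).  Trial order is a seeded
permutation; all schedules, responses, and epochs are bit-reproducible given
their seeds.

Catch trials of a visibility condition supply the false-alarm rate for every
face condition under that visibility — there is one catch condition per
visibility, so all face cells in a CFS block share the same FA estimate.

## 2. Behavioral observer

An equal-variance Gaussian SDT observer generates responses.  Detection:
internal evidence X ~ N(d′, 1) on face trials, N(0, 1) on catches; "anything
else" is reported iff X > criterion (default c = 0.5, a conservative
reporting criterion typical of detection-under-masking tasks).  Under CFS,
d′ is linear in contrast, d′ = −0.2 + 10·c clamped at 0, so that a perfectly
calibrated medium contrast (0.02) sits at chance and the high contrast
(0.32) at d′ = 3.  Without CFS, sensitivity is level-keyed (1.5 / 2.5 / 3.5
for low / medium / high): graded but always well above chance.  Fearful
faces receive +0.5 d′ at high contrast, reproducing the observed detection
advantage for fearful expressions at suprathreshold contrast.
Discrimination is an unbiased 2AFC with sensitivity 0.8 × detection d′.

d′ computation applies a correction for proportions of exactly 0 or 1
before the quantile transform; the default replaces them with 1/(2N) and
1 − 1/(2N) (`rate_clamp`), with `loglinear` and `none` as alternatives.
The choice matters near ceiling — at 48 trials the largest measurable z is
z(95/96) ≈ 2.34 — which is why measured calibration lines flatten at high
contrast and why individual calibrations can fail (Section 3).

## 3. Contrast calibration

Per-level d′ values are fitted by ordinary least squares, d′ = a + b·c, and
inverted at d′ = 0 (medium), d′ = 3 (high); low = medium / 2 exactly.  Two
failure modes raise a typed `CalibrationError` rather than silently
clamping: a non-positive slope (no monotone psychometric data) and a
non-positive medium contrast (the observer was above chance throughout the
tested range).  The orchestrator mimics the experimenter: it re-runs a
failed calibration up to three times with the grid shifted toward the
informative range (halved when stimuli were visible throughout, raised by
50% when the line was flat).  Subjects still failing are excluded and
counted, as are subjects whose main-experiment medium-contrast CFS d′
exceeds 1 (strict inequality, as is the recalibration criterion below).

Between blocks, a pooled d′ (pooled hit and false-alarm *counts* over the
low- and medium-contrast CFS trials of the preceding block, not averaged
per-condition d′ values) triggers a 20% multiplicative reduction of both
contrasts when it strictly exceeds 0.3.  The high contrast never changes.
With ~34 low/medium face trials and ~9 catch trials per block, the pooled
estimate has a standard error near 0.5, so occasional spurious reductions
for a chance-level observer are expected behavior of the rule, not a bug.

## 4. ERP generator

Epochs span [−200, 600) ms at 500 Hz (400 samples; onset at sample 100), in
μV.  Two unit-peak spatiotemporal templates carry all effects:

* **early posterior** — Gaussian time course centered 220 ms (SD 40 ms),
  channel weights Gaussian in chord distance from an occipital seed;
* **late centro-parietal** — centered 450 ms (SD 120 ms), weights centered
  near the vertex.

Per trial, voltage = contrast gain × (early + late) + fearful-only
expression amplitudes × templates + noise.  Contrast gains default to 2 / 4
/ 8 μV (a large, robust contrast main effect).  Expression amplitudes
(negative = larger negativity for fearful) encode the target pattern:

|            | low  | medium | high |
|------------|------|--------|------|
| CFS, early | +0.5 | −0.5   | −0.8 |
| CFS, late  | 0    | 0      | +0.5 |
| noCFS, early | −0.8 | −0.8 | −0.8 |
| noCFS, late  | +0.8 | +0.8 | +0.8 |

i.e. a uniform conscious effect in both windows, and a nonconscious early
effect that grows with contrast and inverts at low contrast, with no
nonconscious late effect below breakthrough contrast.

**Noise model.**  Trial noise is an AR(1) process over time (coefficient
0.985 at 500 Hz, marginal SD 4 μV) with spatially correlated innovations
(exponential kernel, length 0.4 chord units), plus a per-subject,
per-channel DC offset (SD 1 μV).  Two constraints fixed these values, both
applied before the validation suite was frozen: (i) clean trials must pass
the artifact-rejection rules — the successive-sample gradient SD is
σ√(2(1−a)) ≈ 0.69 μV/sample, comfortably under the 5 μV/sample threshold,
whereas faster noise of realistic amplitude would reject every trial; and
(ii) a 0.5–0.8 μV expression effect at 60 trials/condition and 24 subjects
must be detectable with high power, as the design presupposes — the
condition-mean noise SD works out to ≈ 0.6 μV per point (baseline
correction re-injects part of the slow drift, which a naive √n argument
misses), giving point-wise interaction noncentrality ≈ 30.  The resulting
noise is drift-dominated, which matches the character of residual EEG noise
after cleaning but **not** its full spectrum: there is no alpha rhythm, no
line noise, no ocular component (an amplitude-spike injector exists solely
to exercise rejection).  Passing tests therefore demonstrate correctness of
the statistical machinery under a plausible correlation structure, not
robustness to every artifact class of real recordings.

**Sensor layout.**  A Fibonacci spiral on the upper unit hemisphere (64
channels by default; the real study's 256-channel net is represented at
desk scale).  Adjacency is chord distance below 1.5× the median
nearest-neighbor spacing (≈ 0.44 for 64 channels, giving 3–7 neighbors per
channel) unless an explicit threshold is supplied.  Regions of interest are
geometric: *posterior* = y < −0.25 (23 of 64 channels), *central* = z > 0.70
(19 of 64); the early template peaks inside the posterior ROI, the late
template inside the central ROI.

## 5. Preprocessing

Fixed order: average reference → baseline (−200–0 ms) → artifact rejection
→ bad-channel interpolation → per-condition trial averaging → zero-phase
low-pass → decimation.  Rejection is per trial if **any** channel violates
any criterion (inclusive bounds): max |v| ≥ 120 μV, max |Δv| ≥ 5 μV/sample,
or SD(Δv) ≤ 0.01 μV/sample ("μV/∂T" is interpreted as μV per sample at the
native 500 Hz).  Interpolation is inverse-distance weighting over good graph
neighbors — a deliberate simplification of spherical splines, exact for
constant fields and within 10% of range for linear fields at well-connected
channels.  Averages are filtered with a 4th-order Butterworth at 25 Hz
(−24 dB/octave asymptotic roll-off per pass) applied forward-backward
(`sosfiltfilt`, zero phase, so the effective attenuation is squared), then
decimated 500 → 125 Hz by stride 4; filtering precedes decimation to avoid
aliasing.  Ocular-artifact correction is out of scope: the generator
produces no ocular component.

## 6. Mass-univariate CBP test

F-maps come from the within-subject sums of squares (effect MS over
effect × subject MS).  Main effects are computed on data collapsed over the
other factor — algebraically identical to the two-way main-effect F in a
balanced design — and the interaction from the full two-way decomposition.
The cluster-forming threshold is the uncorrected parametric F quantile at
α = 0.05 with sphericity-uncorrected dfs; Greenhouse–Geisser correction is
reserved for follow-up scalar ANOVAs.  Clusters are connected components
over (same channel, adjacent samples) ∪ (neighbor channels, same sample) —
no diagonal connectivity — with minimum cardinality 2, scored by mass Σ F.

Permutation schemes: main effects permute the tested factor's levels within
each subject after collapsing; the interaction removes both estimated
grand-level main effects and permutes cell labels within each subject
(ter Braak-style residual permutation).  The null distribution is the
maximum cluster mass per permutation; p_raw = (1 + b)/(1 + B) (the
plain-proportion estimator is available as a flag), and p_corrected =
min(1, 2·p_raw) for the two analysis windows (configurable).  5000
permutations at full scale; desk-scale runs default to 500 (300 in the
heaviest validation loop), which bounds the smallest attainable p at
≈ 0.002–0.003 and is ample for α = 0.05 decisions.

Validation: the F-maps match a brute-force sums-of-squares oracle to 1e−10;
cluster finding matches an independent flood fill on random masks; the
family-wise error over 200 effect-free cohorts (12 subjects, 16 channels,
500 permutations) falls inside the 95% binomial interval around 0.05.

## 7. Follow-up inference

`rm_anova` covers fully within-subject one- and two-factor designs.
Greenhouse–Geisser ε̂ is Box's epsilon of the covariance of orthonormal
contrast scores (interaction: the Kronecker contrast space), bounded to
[1/(k−1), 1]; GG-corrected p-values are reported whenever an effect has ≥ 2
numerator df (ε̂ = 1 exactly for 2-level effects).  The three-factor
behavioral ANOVA of the original design is represented as 2 × 3 ANOVAs per
visibility condition; a three-way decomposition is out of scope.

The JZS Bayes factor integrates the Cauchy-prior scale mixture in log space
over g, mapped to (0, 1) via g = u/(1−u), with adaptive quadrature;
non-convergence raises with diagnostics rather than returning a number.
Prior scale defaults to 0.707 (the convention of standard Bayes-factor
software; the published values are reproduced within 1.2% at this scale,
well inside the 2% the worked examples tolerate).  Independent-samples
contrasts of cluster-average differences use pooled-variance t with
df = n₁ + n₂ − 2 and effective N = n₁n₂/(n₁+n₂), matching the published
degrees of freedom, even where the samples derive from the same subjects.
The correlation Bayes factor integrates the exact sampling density of
Pearson's r against a stretched-beta prior (width 1/3, "medium"); perfect
correlations return BF₁₀ = ∞ (the integral genuinely diverges).  Holm
adjustment is step-down with monotonicity enforcement, capped at 1.

## 8. Orchestration and problem sizes

`run_study` executes calibration → main experiment (block-wise, with
recalibration) → per-subject epoch simulation and preprocessing → CBP in
both windows and visibility conditions → follow-ups (interaction-cluster
t tests with Holm and JZS BFs; awareness correlations), writing every
intermediate table so stages can be re-run and audited.  Epochs are
simulated and preprocessed one subject at a time (a 24-subject cohort would
otherwise hold ~2 GB of trial data in memory at once).  Desk-scale defaults
are 12 subjects / 64 channels / 500 permutations; `full_scale()` switches
to 48 subjects and 5000 permutations.  The validation suite runs the
pattern-recovery check at 24 subjects × 20 seeded runs with 300
permutations, and the null calibration at 200 replicates × 500 permutations
on 16 channels — sizes chosen to make the Monte-Carlo assertions sharp while
keeping a full validation run interactive.

Exclusion accounting is explicit: n_included + n_excluded = n_simulated,
with per-subject reasons in the report.

## 9. Known limitations

* The generator's noise has no oscillatory, ocular, or line components, and
  effect topographies are single smooth dipole-like patches.
* Spherical-spline interpolation is approximated by inverse-distance
  weighting; BESA's ocular correction and per-subject manual amplitude
  thresholds are represented by fixed configurable scalars.
* The interaction permutation is one member of the family of
  residual-permutation schemes; exchangeability holds only approximately
  under its null, as for all such schemes.
* Published ERP amplitudes, topographies, and cluster masses depend on the
  original recordings and are not reproduction targets; the package
  reproduces design arithmetic, printed Bayes factors, and the qualitative
  effect structure.
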