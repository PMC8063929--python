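# Methods

`erpemd` reimplements an analysis pipeline for classifying infants by
familial autism risk, and by later diagnostic outcome, from features of
their visual event-related potentials (ERPs). The original cohort data
are not publicly available, so the package pairs the analysis with a
synthetic-cohort generator that reproduces the statistical structure the
analysis assumes; every downstream stage is exercised end to end on data
the package itself creates.

## Pipeline overview

1. **Epochs → ERPs** (`erp`). Per subject and stimulus condition,
   epoched trials (−200 to 800 ms around stimulus onset, 500 Hz) are
   averaged into one ERP after average re-referencing and baseline
   correction. Subjects with fewer than 10 trials in *any* condition are
   excluded first.
2. **ERP → IMFs** (`emd`). Each channel waveform is decomposed by
   empirical mode decomposition (EMD) into its first three intrinsic
   mode functions (IMFs) plus a residual.
3. **IMFs → features** (`features`). Six scalars per IMF per channel
   (energy, Shannon entropy, mean, standard deviation, skewness, fourth
   central moment); with 6 conditions × 3 IMFs × 6 features this gives a
   channels × 108 matrix per subject, reduced to a 1 × 108 vector by the
   per-column maximum over channels.
4. **Features → classification** (`selection`, `evaluate`). Nested
   stratified cross-validation around k-NN and SVM classifiers, with
   z-scoring, correlation-weight feature ranking and hyperparameter
   choice all refit inside each training fold. The imbalanced
   outcome problem (17 vs 33) is evaluated over five balanced
   majority subsamples.

## ERP conventions

The epoch window is half-open, [−200, 800) ms, which at 500 Hz is
exactly 500 samples with stimulus onset at index 100; the baseline
window [−200, 0) covers the first 100 samples. The pipeline order is
fixed — exclude → re-reference → baseline → average — although baseline
correction and averaging commute (both are linear), which the test suite
verifies. Exclusion uses the *any-condition* reading of the 10-trial
rule: one deficient condition removes the subject.

## EMD: numerical choices

Envelopes are cubic splines through the local extrema, with the two
extrema nearest each signal edge mirrored about that edge before spline
fitting; for 500-sample epochs end effects otherwise dominate the slow
modes. A flat run in the signal counts as a single extremum at its
midpoint, and an exact-zero sample counts once toward the zero-crossing
count.

The textbook IMF condition — mean envelope exactly zero everywhere — is
unattainable in finite arithmetic, so a candidate is accepted when the
extrema and zero-crossing counts differ by at most one *and* the maximum
absolute mean envelope is below 5% of the candidate's peak-to-peak
range. Sifting otherwise stops on a Cauchy criterion
(Σ(d_prev − d)² / Σd_prev² < 0.2) or a hard cap of 50 iterations. The
Cauchy stop alone can leave a mode violating the count criterion, so it
is only honored once the counts agree (the usual combined stopping
rule); this keeps the package's guarantee that every returned IMF
satisfies the count criterion.

Decomposition extracts at most three IMFs: in these ERPs the higher
modes are smooth slow trends that carry no discriminative oscillatory
content, and the feature battery is defined on IMF1–3. Reconstruction
(signal = ΣIMF + residual) is exact by construction, since each residual
is computed by subtraction; the suite checks it to 1e−9 relative on
random signals and the acceptance script reports the observed maximum
(order 1e−16).

Because a smooth waveform can exhaust its extrema before three modes are
found, the feature stage pads missing modes with zeros (all six features
of a zero mode are 0), keeping the 108-column layout fixed.

## Feature battery

Energy is Σx², and entropy applies −Σ x²·ln x² verbatim to squared
amplitudes with 0·ln 0 := 0 — deliberately without normalizing to a
probability distribution, since the ranking that consumes these features
is scale-insensitive per column. The "moment" feature is the fourth
central moment: mean, standard deviation and skewness already cover
orders 1–3. Standard deviation uses the n−1 denominator; skewness is the
biased third standardized moment, defined as 0 when the variance is 0.
The channel reduction takes the signed per-column maximum; an `"abs"`
mode (largest magnitude, sign preserved) is available as a config
switch.

## Feature selection and evaluation

The selection weight is the absolute point-biserial (Pearson)
correlation between a feature column and the binary label — the standard
correlation filter; a constant column has weight 0 and ties in the
ranking break toward the lower column index. Weights are invariant to
positive affine rescaling of a column, so z-scoring does not affect the
ranking.

k-NN uses Euclidean distance on z-scored features (training-fold
statistics only); without standardization, energy (µV², order 10²–10⁴)
would dominate skewness (order 1). The neighbor grid is k ∈ {1, 3, …,
21}; odd k cannot tie in a binary vote, but a general tie rule (the tied
class with the single nearest member wins) is implemented for even k.
SVM compares linear, quadratic, cubic and Gaussian kernels at three
width presets — kernel scale σ = √p/4, √p, 4√p for p features — with
C ∈ {0.01, 0.1, 1, 10, 100}. Inner-CV ties prefer the earlier grid
entry, ordered simplest kernel first, then smallest C (for k-NN,
smallest k).

The risk problem (control vs high-risk, positive class HR) uses 10 outer
× 9 inner folds and 30 selected features; the outcome problem (HR-ASD vs
HR-noASD, positive class HR-ASD) uses 5 outer × 4 inner folds, 11
selected features, and five balanced resamples of 17 + 17 subjects,
aggregated as the unweighted mean. Confusion counts are pooled over
outer test folds. CV folds split by subject; the 6 condition-level
waveforms per subject (564 for 94 subjects) are inputs to feature
assembly, not independent observations.

## Synthetic cohort: what it emulates, and what it does not

Each trial is a deterministic evoked part plus noise. The evoked part
sums three Gaussian-bump components with the canonical infant
face-processing morphology — P100 (+4 µV at 100 ms, σ 25 ms), N290
(−6 µV at 290 ms, σ 45 ms), P400 (+5 µV at 400 ms, σ 70 ms) — each with
a smooth occipitally-concentrated channel-weight profile, plus
stimulus-locked beta (13–30 Hz) and gamma (30–60 Hz) Gabor bursts.
Group effects enter three ways: milliseconds added to the N290/P400
latency for high-risk-family subjects, a per-group multiplicative
amplitude scale, and per-group burst amplitudes. The "noise" stimulus
condition omits the face components but keeps the bursts: a noise image
is still a visual stimulus, so condition-level group information is
weaker but not absent there. Trial noise is 1/f-shaped background plus
white noise at half that scale, both scaled by `noise_sd` (default 1 µV
against component amplitudes of 4–6 µV).

Trials per subject × condition are Poisson around `trials_mean` with a
floor of 10; low-trial recordings (uniform 1–9 trials) occur with
probability `p_low_trials`, or deterministically for
`n_forced_low_trials` control subjects, which exercises the exclusion
rule. Oscillatory bursts are phase-locked to stimulus onset, so they
survive trial averaging; non-phase-locked (induced) activity, ocular and
muscle artifacts, channel bridging, electrode geometry and volume
conduction are all *not* modeled. Passing tests therefore demonstrate
that the pipeline recovers group structure of the kind the generator
encodes — latency shifts, amplitude scaling, band-limited power — not
that real infant EEG is classifiable at any particular accuracy.

Two presets define the study conditions for end-to-end checks. The
`strong` preset (40 ms latency shift; amplitude scales 1.0/0.75/0.55 and
escalating beta/gamma burst amplitudes for control/HR-noASD/HR-ASD) is
cleanly separable after feature extraction: nested-CV risk accuracy
reaches 1.0. The `null` preset has zero group differences, so accuracy
must fall inside the 95% binomial chance band around 0.5 at n = 94
(±0.101), which is the leakage canary for the whole pipeline: any
test-fold information reaching selection or model choice shows up as
above-chance accuracy on null data.

## Problem sizes

End-to-end runs use the study's retained-sample group sizes (44 control,
33 HR-noASD, 17 HR-ASD) at a 16-channel montage with 20 expected trials
per condition; the single-subject dimensionality check runs the full 128
channels. The structural design-count check generates the pre-exclusion
cohort (104 subjects: 50 control, 33 + 17 + 4 unknown-outcome HR, six
forced low-trial controls) at 4 channels, since retention arithmetic
does not depend on the montage.

## Known limitations

- EMD mode mixing is not addressed (no ensemble/noise-assisted
  variants); for tones closer than about a factor of 2 in frequency the
  modes blend, which is inherent to plain EMD.
- The generator's channel axis is an abstract index with a smooth
  occipital weight profile; there is no electrode montage, so topography
  is only qualitatively realistic.
- Statistical power of the chance-band check is that of a single
  binomial draw; it bounds gross leakage, not subtle bias.
- `Cohort` objects hold all trials in memory; a full 128-channel,
  94-subject cohort at 25 trials is ~7 GB and should be generated
  per-subject (or at a reduced montage) rather than materialized whole.
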