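# erpemd

Empirical-mode-decomposition (EMD) analysis of infant event-related
potentials (ERPs), with nested cross-validated classification of
familial autism risk and diagnostic outcome — plus a synthetic-cohort
generator so the entire pipeline runs and is tested without any
external data.

## Who this is for

Researchers working on EEG/ERP biomarkers who want a tested, end-to-end
reference implementation of the IMF-feature approach to infant
face-processing ERPs: decompose each channel's condition-averaged ERP
into intrinsic mode functions, summarize each mode with a small feature
battery, and classify subjects with leakage-free nested
cross-validation.

## The method

Each subject's epoched EEG (−200 to 800 ms around stimulus onset,
500 Hz, 6 face/gaze stimulus conditions) is averaged into one ERP per
condition after average re-referencing and baseline correction; subjects
with fewer than 10 trials in any condition are excluded. Every channel
waveform *erp(t)* is then decomposed by sifting into intrinsic mode
functions and a residual,

&nbsp;&nbsp;&nbsp;&nbsp;erp(t) = Σᵢ imfᵢ(t) + rₙ(t),

where each IMF has extrema and zero-crossing counts differing by at most
one and a near-zero mean envelope. The first three IMFs (the
high-frequency, beta/gamma-range content) are summarized per channel by
six features:

- energy E = Σₖ x²(k) and Shannon entropy SE = −Σₖ x²(k)·ln x²(k)
- mean, standard deviation, skewness, and the fourth central moment

With 6 conditions × 3 IMFs × 6 features this yields a channels × 108
matrix per subject, reduced to 1 × 108 by the per-column maximum over
channels. Features are ranked by |point-biserial correlation| with the
class label, and k-NN (Euclidean) or SVM (linear, polynomial, Gaussian
kernels) classifiers are evaluated by nested stratified
cross-validation — 10 outer × 9 inner folds for control vs high-risk
(HR), and 5 outer × 4 inner folds over five balanced 17 + 17 resamples
for HR-ASD vs HR-noASD — with standardization, selection and
hyperparameter tuning all refit inside each training fold. Accuracy,
sensitivity and specificity are pooled over outer test folds.

## Worked example

```python
import numpy as np
from erpemd import CohortSpec, EffectSpec, generate_cohort, features_from_cohort
from erpemd.evaluate import CVConfig, run_experiment
from erpemd.emd import emd_decompose

# decompose a two-tone test signal
t = np.arange(500) / 500.0
x = np.sin(2 * np.pi * 40 * t) + np.sin(2 * np.pi * 5 * t)
dec = emd_decompose(x)
freqs = np.fft.rfftfreq(500, 1 / 500.0)
for i, imf in enumerate(dec.imfs, 1):
    peak = freqs[np.argmax(np.abs(np.fft.rfft(imf)))]
    print(f"IMF{i}: spectral peak {peak:.1f} Hz")
print(f"reconstruction error: {np.max(np.abs(dec.reconstruct() - x)):.2e}")

# small strong-effect cohort, risk classification
spec = CohortSpec(n_control=12, n_hr_noasd=8, n_hr_asd=6, n_channels=8,
                  trials_mean=15, effect=EffectSpec.strong(), seed=0)
cohort = generate_cohort(spec)
table, labels, log = features_from_cohort(cohort)
print(f"feature table: {table.shape[0]} subjects x {table.shape[1]} features")
groups = [labels[s] for s in table.index]
res = run_experiment(table, groups, "risk", "knn",
                     CVConfig(outer_folds=5, inner_folds=4, selection_k=11, seed=0))
rep = res.reports[0]
print(f"risk accuracy {rep.accuracy:.3f}  sensitivity {rep.sensitivity:.3f}  "
      f"specificity {rep.specificity:.3f}")
```

prints

```
IMF1: spectral peak 40.0 Hz
IMF2: spectral peak 5.0 Hz
IMF3: spectral peak 2.0 Hz
reconstruction error: 2.22e-16
feature table: 26 subjects x 108 features
risk accuracy 0.962  sensitivity 0.929  specificity 1.000
```

The two tones separate into the first two modes (IMF3 picks up the
slow boundary-limited remainder), decomposition is additive to machine
precision, and on a cohort generated with strong group effects (latency
shift, amplitude attenuation and elevated beta/gamma burst power in the
high-risk groups) the nested-CV risk classifier is nearly perfect.
Sensitivity is the proportion of high-risk subjects correctly
identified, specificity the proportion of controls.

A command-line interface mirrors the stages (`erpemd simulate`,
`extract-erps`, `decompose`, `extract-features`, `select`, `classify`,
`run-all`); see `erpemd --help`.

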