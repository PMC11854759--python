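# mseeg — multiscale entropy features for EEG group discrimination

`mseeg` is a Python library for asking, of resting-state EEG, *at which
temporal scale does a group difference in signal complexity live, and how
well can it be classified?*  It was built around the problem of
discriminating patients with major depressive disorder (MDD) from healthy
controls (HC), where complexity differences are reported to concentrate
at coarse temporal scales rather than the raw sampling rate.

The chain it implements:

1. **Coarse-graining** — replace each block of τ consecutive samples by
   its mean, `y_j^(τ) = (1/τ) Σ_{i=(j−1)τ+1}^{jτ} x_i`, for scales
   τ = 1..10.
2. **Refined composite multiscale entropies** — per 10-s epoch and
   channel, sample entropy with match counts pooled across coarse-grained
   series, `RCMSE(x, τ, m, r) = −ln(Σ_k n_{m+1}^k / Σ_k n_m^k)`
   (m = 2, r = 0.15σ), and permutation entropy with ordinal-pattern
   frequencies averaged before the Shannon entropy,
   `RCMPE(x, τ, m) = −Σ_π p̄(π) ln p̄(π)` (m = 4, 24 patterns).  Pooling
   the intermediate statistics keeps the estimates defined on short
   series.  Both the scales-1..τ pooling and the classic offset-shifted
   ("refined composite") pooling are available.
3. **Per-scale classification** — feature vectors concatenate RCMSE and
   RCMPE over all channels; LDA, logistic regression, RBF-SVM (kernel
   scale 6.2) and KNN (k = 10) are evaluated by stratified 10-fold
   cross-validation, reporting accuracy, sensitivity, specificity and
   F1 per (classifier, τ).
4. **Scale analysis** — per-electrode group t-tests per scale, and the
   forward difference `f′(τ) = f(τ+1) − f(τ)` of the metric-vs-scale
   curve, whose positive-to-negative zero crossings mark locally optimal
   scales.
5. **Cost model** — the analytic decomposition
   `E(τ) = aL²Σ1/k² + bLΣ1/k + c1Lτ + (c2−c1)LΣ1/k` of extraction time,
   with a drift-robust timing harness that checks the near-linear growth
   of measured cost with τ.

A seeded synthetic-cohort generator produces two-group multichannel
EEG-like recordings whose complexity contrast is pinned to a chosen
temporal scale, so the whole pipeline is testable and calibratable
without any data download.  Real EDF recordings are supported through the
optional `mne` dependency.

## Worked example

`examples/02_synthetic_cohort_scan.py` generates a 16-subject cohort with
the group contrast injected at scale 3, scans classifiers × scales, and
applies the zero-crossing rule:

```
96 epochs from 16 subjects

accuracy grid (classifier x scale):
tau          1      2    3     4      5      6      7      8      9      10
classifier
KNN         1.0  0.772  1.0  0.99  0.979  0.908  0.872  0.811  0.792  0.730
LDA         1.0  0.822  1.0  0.99  0.968  0.897  0.831  0.803  0.729  0.719
LR          1.0  0.822  1.0  0.98  0.968  0.908  0.863  0.813  0.749  0.719
RBF-SVM     1.0  0.823  1.0  0.99  0.979  0.918  0.842  0.811  0.781  0.738

classifier-averaged accuracy per scale:
tau
1     1.000
2     0.810
3     1.000
4     0.988
5     0.973
6     0.908
7     0.852
8     0.810
9     0.763
10    0.726

forward difference f'(tau): [-0.19   0.19  -0.012 -0.014 -0.066 -0.055 -0.042 -0.047 -0.036]
detected extrema: [(2, 'min'), (3, 'max')]
```

The classifier-averaged accuracy dips at scale 2 and peaks at scale 3 —
`(3, 'max')` is the forward-difference zero crossing recovering the scale
at which the generator injected the group difference.  (Scale 1 is also
highly separable here: the injected narrowband component is *regular* at
fine scales and lowers permutation entropy, the mirror image of its
coarse-scale irregularity.)

The other examples cover the entropy primitives on reference noises
(`01`), the per-electrode t-test map (`03`), and the cost model and
timing harness (`04`).

A thin CLI wraps the same functions for shell use:

```bash
mseeg simulate --out cohort/ --n-hc 8 --n-mdd 8 --duration 60 --seed 1
mseeg scale-scan --cohort cohort/ --out metrics.csv
mseeg extrema --metrics metrics.csv
mseeg profile --length 2560
```

## Layout

```
src/mseeg/
  entropy.py        coarse-graining, SampEn/PE, RCMSE/RCMPE, curves
  synthetic.py      seeded two-group cohort generator, reference signals
  preprocessing.py  recording containers, band-pass, epoching, EDF/CSV IO
  features.py       per-scale feature matrices + lossless CSV round-trip
  classify.py       classifiers, 10-fold CV, confusion-matrix metrics
  scales.py         group t-tests, forward differences, extremum detection
  profiling.py      analytic cost model + drift-robust timing harness
  pipeline.py       RunConfig, seed derivation, end-to-end runs
  cli.py            thin command-line surface
docs/methods.md     model assumptions, defaults, numerical conventions
examples/           one narrative script per capability
```

See `docs/methods.md` for the full account of the models, parameter
choices, and what the synthetic benchmark does and does not establish.
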