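# Methods

`mseeg` implements a complete multiscale-entropy analysis chain for
two-group resting-state EEG: coarse-graining, refined composite multiscale
sample entropy (RCMSE) and permutation entropy (RCMPE), per-epoch feature
construction, per-scale cross-validated classification, scale–performance
extremum analysis, and an analytic model of the extraction cost.  This
note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic benchmark does and does not
establish.

## Coarse-graining and the two entropies

A series `x` of length `N` is coarse-grained at temporal scale `τ` by
replacing each block of `τ` consecutive samples with its mean,

    y_j^(τ) = (1/τ) · Σ_{i=(j−1)τ+1..jτ} x_i ,   j = 1..⌊N/τ⌋,

dropping the trailing remainder (complete blocks only).  Scale 1 is the
original series.

**Sample entropy** (embedding `m`, tolerance `r`) counts ordered pairs of
`m`-length templates whose Chebyshev distance is ≤ `r`, self-matches
excluded, with the same `N − m` template start positions at lengths `m`
and `m+1` so the two counts are comparable, and returns
`−ln(n_{m+1}/n_m)`.  Pair counting is done with a KD-tree under the
infinity norm; tests cross-check it against an explicit distance-matrix
implementation.

**Permutation entropy** (order `m`, delay `d`) maps every window
`(y_i, y_{i+d}, …, y_{i+(m−1)d})` to the permutation that sorts it and
returns the Shannon entropy (nats) of the pattern frequencies, in
`[0, ln m!]`.  Ties are broken by index order (stable sort), so a
constant window yields the ascending pattern; `0·ln 0 ≡ 0`.

**Refined composite pooling.**  Both multiscale variants pool the
*intermediate* statistics across several coarse-grained series before
taking the entropy — summed match counts for RCMSE, averaged pattern
frequencies for RCMPE — which keeps the estimate defined on short series.
Two pooling conventions exist in the literature and both are implemented:

* `cumulative` (default): pool the coarse-grained series at **every
  scale k = 1..τ**.  The RCMSE at scale τ is
  `−ln(Σ_k n_{m+1}^k / Σ_k n_m^k)`; the RCMPE is the Shannon entropy of
  the pattern distribution averaged over k.
* `offset_composite`: pool the τ offset-shifted coarse-grainings **at
  scale τ** (the original refined-composite formulation).

The first convention averages over scales, so the value at scale τ blends
all finer scales; the second is a pure scale-τ statistic.  Descriptions of
"refined composite" multiscale entropy in the applied literature are often
ambiguous between the two.  The cumulative reading is the default here —
it is the convention the cost model in this package describes (its
sample-entropy term sums `(L/k)²` over `k = 1..τ`) and the more robust
one on short epochs — with the offset formulation behind
`EntropyConfig(variant=...)` for comparison.  Neither is asserted to be
"the correct" refined composite; results should state which convention
was used.  At τ = 1 both reduce exactly to the classic single-scale
entropies — a tested identity.

An RCMSE value is *undefined* only when the match counts are zero at both
template lengths on every pooled series (`UndefinedEntropyError`); a zero
only at length `m+1` yields `+inf` (no (m+1)-matches at finite r).  In
the offset variant an offset series may be one sample shorter than
`⌊N/τ⌋`; one too short to form a template pair contributes zero counts
rather than failing the composite.

**Defaults** (`EntropyConfig`): `m_se = 2`, `r = 0.15·σ` with σ the
standard deviation (ddof 0) of the scale-1 series of the epoch-channel,
held fixed across pooled scales (standard multiscale practice — one σ per
series); `m_pe = 4` (24 patterns — reliable from 10-s epochs), delay 1
(the Bandt–Pompe default), scales τ = 1..10.  The permutation order is
restricted to [3, 7]: below 3 the statistic is trivial, above 7 the m!
patterns cannot be populated from epochs of this length.

## Preprocessing

Band-pass 0.1–45 Hz by default: a 4th-order Butterworth applied forward
and backward (`sosfiltfilt`), i.e. zero-phase, since phase distortion
would alter ordinal patterns.  Note the modest stop-band: this design
leaves ≈ 25 % of a 50 Hz component in amplitude; recordings acquired with
a mains notch (as typical clinical EEG is) need nothing more, but
un-notched data would.  Epochs are non-overlapping 10-s rectangular
windows; the trailing remainder is dropped.  An optional amplitude
threshold drops epochs whose any-channel peak exceeds it.  Expert
artifact screening (ICA component review) is a human-in-the-loop step and
deliberately out of scope; the synthetic cohorts are artifact-free by
construction.  EDF recordings are read through `mne` (optional
dependency); CSV matrices with a JSON sidecar are the native text format.

## Features and classification

Per epoch and scale, the feature vector concatenates the RCMSE of every
channel followed by the RCMPE of every channel (2 × n_channels columns,
electrodes in the fixed 10-20 order Fp1…Pz).  One matrix per scale;
models are trained per scale, never across scales.  Epochs with any
undefined entropy are dropped and counted, not imputed.

Four classifiers are evaluated: LDA, logistic regression (fitted by
maximum likelihood, regularisation disabled), an RBF-kernel SVM with
kernel scale s = 6.2 under `K(u,v) = exp(−‖u−v‖²/s²)` (so `gamma = 1/s²`
for gamma-parameterised libraries), and KNN with k = 10 and Euclidean
distance, vote ties falling to the single nearest neighbour (a
deterministic rule sklearn's stock classifier does not offer, hence the
small custom estimator).  Evaluation is stratified 10-fold
cross-validation over epochs with a seeded shuffle; features are z-scored
with training-fold statistics only.  Per fold, confusion counts (positive
class MDD) give accuracy `(TP+TN)/N`, sensitivity `TP/(TP+FN)`,
specificity `TN/(TN+FP)` and F1 `2TP/(2TP+FP+FN)`; a zero denominator is
a flagged missing value and fold averages are NaN-aware.

Epoch-level folds mean epochs of one subject can appear in training and
test folds; on real cohorts this inflates absolute performance.  It is
the convention matched here (and the common one in this literature); a
`subject_grouped=True` mode keeps subjects intact for a leakage-free
estimate.

## Scale analysis

Two views.  (1) Per (electrode, scale, measure), an independent-samples
Student t-test (equal variances; Welch deliberately not used) between
groups on per-epoch entropy values pooled across subjects — pooling
epochs treats correlated samples as independent and understates p-values,
which is why a per-subject-mean mode exists; no multiple-comparison
correction is applied, matching raw-p reporting conventions (caveat
documented).  Zero variance in both groups with equal means returns p = 1
by convention.  (2) The discrete metric-vs-scale function f(τ) from the
classification grid, analysed through its forward difference
`f′(τ) = f(τ+1) − f(τ)`: a sign change of f′ from positive to negative at
τ* marks a local maximum of f at τ*.  Endpoints are never reported and an
exact zero (plateau) produces no extremum — the rule needs a genuine sign
change.

## Synthetic cohorts

The generator exists so every downstream stage is testable and
calibratable without recordings.  Per subject and channel,

    x = (1 − β) · AR(1)(φ) + β · n(t),

both components standardised to unit variance, φ = 0.9 jittered per
subject by N(0, 0.02²).  The groups differ only in the irregularity
weight: `β_HC = 0.2`, `β_MDD = β_HC + 0.2 · effect_size`.  The noise
component `n(t)` is white for `effect_scale = 1` and otherwise
band-limited to `[0.9, 1.1] · fs/(2 · effect_scale)` — straddling the
effective Nyquist frequency of the target scale.  Block-averaging keeps
the component (aliased, maximally irregular) up to that scale and
averages it away beyond, so the group entropy contrast peaks at
`effect_scale`; at fine scales the same component is a coherent
oscillation and *lowers* permutation entropy, giving the cohort the
qualitative signature reported for depression — complexity elevated at
coarse scales, reduced or inverted at fine ones.  Band placement was
validated by Monte-Carlo: the classifier-averaged accuracy curve peaks at
the injected scale in the large majority of replicate cohorts at
`effect_size ≈ 0.3`, and `effect_size = 0` makes the two groups'
generative distributions identical (null calibration).

What the generator does **not** emulate: volume conduction and
inter-channel correlation (channels are independent), 1/f spectral
backgrounds, artifacts (blinks, EMG), age/sex structure, non-stationary
state changes.  Passing tests on this cohort demonstrate that the
pipeline recovers a known scale-specific contrast under controlled
conditions — not that any particular clinical effect is real or that
absolute accuracies transfer to real data.

Defaults mirror the study design the package targets: 30 HC + 34 MDD
subjects, 19 channels, 256 Hz, 5-minute recordings.  Monte-Carlo tests
use smaller cohorts (fewer subjects/channels, 30–100 s) so the suite
completes on one CPU; the tested properties are size-invariant
(calibration, ordering, recovery rates with stated replicate counts).

## Cost model

For a length-L series, extraction at scale τ touches coarse series at
scales k = 1..τ.  With sample entropy quadratic and permutation entropy
linear in series length, and coarse-graining costing k−1 additions and
one multiplication per output sample:

    T1(τ) = a·L²·Σ 1/k²     T2(τ) = b·L·Σ 1/k
    T3(τ) = c1·L·τ + (c2 − c1)·L·Σ 1/k      E = T1 + T2 + T3

The partial sums converge, so the linear coarse-graining term dominates
asymptotically and E(τ) is near-linear in τ; when c1 = c2,
T3 = c1·L·τ exactly.  `fit_cost_constants` projects measured times onto
the basis {L²Σ1/k², LΣ1/k, Lτ, 1} by nonnegative least squares; b and c2
enter only through the combined LΣ1/k coefficient, so the fit reports the
c2 = c1 convention.  The timing harness asserts only *shape* (Pearson
correlation of time with τ, fit R²), never absolute seconds, and is
hardened against clock drift: a warm-up sweep, scales visited in a fresh
random order per sweep, per-scale median over repeats, whole 19-channel
epochs as the timed unit.  In this vectorised implementation the
per-scale cost is closer to O((L/k)·polylog) than to the interpreted
per-sample costs the model was abstracted from, so measured curves track
the harmonic partial sum plus a linear component; the correlation with τ
is ≈ 0.95–0.97.

## Numerical conventions and edge cases

- Coarse-graining: complete blocks only (`⌊N/τ⌋` samples).
- r computed once per epoch-channel at scale 1; never re-estimated on
  coarse series.
- Matching is `≤ r` (closed ball), consistent between implementation and
  oracle.
- Constant series: all templates match → RCMSE 0; single ordinal pattern
  → RCMPE 0.
- Seeds: every stochastic component (cohorts, CV folds, subject
  parameters) is driven by explicit seeds; a cohort is a pure function of
  its `CohortSpec`, and one root seed derives all pipeline stage seeds, so
  identical configs reproduce outputs byte for byte.
- Feature CSVs are written at %.17g and read with round-trip float
  parsing, so matrix I/O is lossless.

## Known limitations

- Independent channels and a stylised two-component spectrum: the
  synthetic benchmark is a functional test bed, not a claim of EEG
  realism.
- Epoch-level CV (default) overstates real-world accuracy; use the
  grouped mode for subject-level claims.
- Raw p-values, uncorrected, in the t-test tables.
- The `cumulative` pooling makes scale-τ features blend finer scales;
  interpret "optimal scale" accordingly (the offset variant isolates the
  scale but is noisier on short epochs).
- Absolute timings are hardware-bound; only relative shape is meaningful.
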