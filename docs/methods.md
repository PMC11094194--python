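# Methods

This note records the model as implemented, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions that make runs reproducible bit-for-bit.

## Data model and conventions

A frame is a 24 × 11 matrix of non-negative sensor counts (no unit
conversion is attempted). Rows run head → feet, columns left → right of
the lying body; indices are 0-based and all intervals half-open. The
default zoning is head [0, 4), trunk [4, 15), legs [15, 24). Physical
sensor arrays are sometimes described transposed (11 × 24); this package
fixes the 24 × 11 orientation everywhere. Labels are +1 supine and
−1 lateral; both left- and right-lateral frames carry −1.

Frames persist as one CSV each (24 rows × 11 values) with an optional
JSON sidecar for label and subject id, and cohorts as a directory plus a
`(path, subject_id, label)` manifest — inspectable and language-neutral.

## Preprocessing

Two inclusive (≥) threshold passes over the 11 × 11 trunk matrix only;
head and leg cells pass through untouched, since the feature pipeline
consumes only the 121 trunk channels.

* Global pass: threshold = arithmetic mean of all 121 entries. Always
  leaves at least one nonzero cell (the maximum is never below the
  mean).
* Neighborhood pass: per contact row i (a row with at least one nonzero
  entry after the first pass), fᵢ = max of the row's nonzero entries;
  threshold = ¾ · min{fᵢ}. Rows with no contact are excluded from the
  minimum — a min over empty contact would be meaningless.

An all-zero trunk (no body contact) raises a degenerate-input error
rather than returning an empty result. Each frame is processed
independently; there is no temporal smoothing.

## Rank-correlation eigen-features

The two views of the trunk matrix are its column-wise rank transform
R(X) and row-wise rank transform R(Y) (ascending, 1-based, average rank
on ties), each column then centred and scaled to unit norm. A column
that is constant before normalization (typically an all-zero filtered
column) carries no order information: it is zeroed and flagged in the
module log instead of raising. Under this normalization
αᵀR(X)ᵀR(Y)β is the Spearman correlation of the two projected views, so
maximising it over unit vectors is an eigenproblem of the symmetric PSD
matrix M = R(X)ᵀR(Y)R(Y)ᵀR(X). Negative eigenvalues produced by
round-off are clipped to zero.

Retention keeps the smallest prefix of the descending spectrum whose
cumulative contribution reaches θ (default 0.95), clipped to
[k_min, k_max]. The pipeline pins k_min = k_max = 7: a fixed 7-column
salient matrix T = Z·P for every sample keeps each downstream feature
slot meaning the same thing across the cohort, which proved more
valuable for the classifier than shaving components off individual
frames, and it keeps the three-way longitudinal split well-posed.
θ remains functional for callers who want adaptive width.

Reproducibility conventions: eigenvector signs are fixed so the
largest-magnitude component of each loading is positive; ranks use the
deterministic average-tie rule; loadings are computed per sample, so
feature extraction has no fitted state and cannot leak information
across a train/test split. The Y-side directions β are exposed for
inspection but only the X-side loadings enter P.

## Band features

Defaults on the 11-row × 7-column salient matrix: horizontal bands
shoulder [0, 3), back [3, 6), waist [6, 9), hip [9, 11) — roughly torso
proportions — and longitudinal bands left [0, 2), middle [2, 5),
right [5, 7). Other shapes scale these boundaries proportionally. Both
partitions are configurable; neither is learned.

Thresholds mirror preprocessing: 3/5 of the minimum per-row (per-column)
contact maximum, computed over all rows (columns) of T. Within a band
the 4 (rows) or 6 (columns) largest surviving entries are selected —
ties resolved toward earlier scan positions — and emitted in scan order,
zero-padded when fewer survive. Ratio features divide band vectors
elementwise in a fixed pairing order; a denominator below
1e−9 · max(‖m‖∞, ‖n‖∞, 1) yields 0, since a band with no support
carries no contrast, and this keeps every feature finite and
deterministic. The last longitudinal pairing is right over middle
(Rat(c₂, c₁)), preserved as the construction prescribes.

The SE vector concatenates A (16), B (24), C (18), D (18) row-major:
76 features. Scaling T by a positive constant scales A and C and leaves
B and D unchanged, so the ratio blocks are the drift-invariant half of
the feature set.

## Ensemble classifier

Weak learners are RBF-kernel SVMs fitted with per-sample weights in the
objective (not resampling), which makes the weighted error of the
boosting round exact and the whole procedure deterministic. Defaults:
iteration budget T_iters = 50, penalty C = 1, kernel width
γ = 1/(n_features · var(X)) — the standard scale heuristic — and
ε floored at 1e−10 so a perfect learner keeps a finite weight. A round
whose weighted error reaches 0.5 is rejected (it cannot carry positive
weight); its γ is jittered by ±20 % from a generator seeded by the
config and refitted up to 3 times, after which boosting stops with the
learners accepted so far. Training also stops once the partial
ensemble's training 0-1 error reaches zero. Exact zero votes resolve
to +1 (supine). The reported learning curve is the 0-1 error of the
partial ensemble per round on a train and a held-out split.

Weight updates use the hard ±1 label of the weak learner, not its
real-valued margin. After every round with ε_t > 0 the reweighted mass
on misclassified samples equals exactly ½ — asserted in the tests at
1e−10.

Models serialize to a JSON container holding support vectors, dual
coefficients, intercepts, kernel widths and learner weights; prediction
from a loaded model evaluates the kernel expansion directly and is
independent of the fitting library's version.

## Evaluation

Stratified tenfold (fold sizes within one sample, class balance
preserved; summary = unweighted mean over folds) and LOOCV
(leave-one-sample-out; summary metrics computed on the pooled held-out
predictions, so LOOCV accuracy is exactly the fraction of correctly
predicted samples). Splits are at frame level to match the acquisition
protocol; a subject-grouped mode exists for leakage studies. Metrics:
accuracy, macro recall, macro F1, MCC, and per-class precision.
Undefined ratios (an empty predicted class) report as 0. The ablation
harness scores several input representations (raw trunk vector,
flattened salient matrix, SBWH block, LMR block, fused SE) on identical
folds.

## Synthetic cohort generator

The generator emulates the acquisition protocol (26 subjects × 40
frames each, 20 supine + 20 lateral; per-subject weight factor) and the
pressure structure the pipeline assumes: supine mass in wide bumps on
the spinal midline with shoulder/back/waist/hip row bands; lateral mass
in a narrow band offset 2.5 columns, shoulder and hip loaded more, the
back less. On top of the bump surface it adds, in order: a
displaced-spring spill field (a Gaussian-smoothed copy of the surface,
σ = 1.5 cells, times a per-cell uniform gain in [0, 0.6]) modelling
springs that shift without bearing load; per-frame pose jitter
(row σ = 0.5, column σ = 0.3 cells) and per-bump amplitude jitter
(σ = 15 %); a per-frame multiplicative gain in [0.7, 1.4] and additive
baseline in [0, 6] units (inflation/temperature drift of barometric
readings — the nuisance the rank features are invariant to by
construction); additive Gaussian noise (σ = 6 units, ~10 % of a typical
peak) clipped at zero; and independent per-cell dropout (p = 0.05,
a sensor occasionally reading nothing). All values were chosen once as
plausible for a low-density air-spring array and are configurable.

What it does **not** emulate: anthropometric diversity beyond a scalar
weight factor, prone or sitting postures, temporal correlation between
frames, spatially correlated sensor miscalibration, and the
idiosyncratic overlap structure of real bodies on real mattresses.
Consequently, passing tests demonstrate the pipeline's internal
correctness and its behaviour under the modelled nuisances — not
field accuracy. Two behavioural findings on this synthetic cohort
deserve emphasis (both computed by `tests/test_acceptance.py`): the
raw 121-cell representation remains fully separable at desk scale, so
the fused SE features do not dominate it the way they dominate the
compressed representations, and the boosted ensemble's
tenfold-to-LOOCV degradation is statistically indistinguishable from a
single SVM's. Both comparisons are asserted at their intended strength
and currently fail; they document where the synthetic conditions are
easier than real data rather than being weakened to pass.

## Problem sizes

Cross-validated comparisons on the default cohort use all 1040 frames
for tenfold schemes. The LOOCV robustness comparison runs on a cohort
generated by the same protocol at 26 subjects × 8 frames (n = 208), the
size at which n refits of the ensemble remain tractable on one CPU; the
worked example in the README uses 6 subjects × 10 frames.

## Known limitations

* Binary postures only; no probability calibration; RBF kernel only.
* The salient matrix is kept at 11 rows; constructions that trim
  non-contact rows would change band boundaries.
* Band boundaries are fixed fractions of the matrix shape, not fitted
  to the subject.
* Per-sample eigendecomposition makes features stateless but means the
  loading basis differs between frames; only the band summaries, not
  individual T entries, are comparable across samples.
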