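# Methods

This note documents the models and procedures `eegcaps` implements, the
choices made where the design was open, and what the synthetic benchmark
does and does not demonstrate.

## Problem setting

The package targets subject-pooled binary emotion recognition from
multi-channel EEG in the valence–arousal–dominance model. Inputs follow the
preprocessed DEAP layout: per subject, 40 trials of 63 s recorded at 128 Hz
over the 32 EEG electrodes of the 10–20 montage, each trial paired with
continuous 1–9 self-assessment ratings of valence, arousal, dominance and
liking. A rating below 5 is "low" (0), at or above 5 "high" (1); the rule is
applied independently per dimension, giving three binary classification
problems over the same features. Liking is carried in the containers but is
not a classification target.

## Segmentation

Each trial's first 3 s (the pre-stimulus baseline) are discarded — excluded,
not subtracted, since no baseline-correction step is part of the procedure
being reproduced — and the remaining signal is cut into non-overlapping 3 s
windows, `floor((T − 3)/3)` per trial (20 for a 63 s trial; any shorter tail
is dropped). Every window inherits its trial's binarized labels, so one
subject yields 800 windows and a 32-subject cohort 25,600.

## Band-power features and normalization

Per window and channel the one-sided PSD is estimated with Welch's method —
128-sample (1 s) Hann windows, 50 % overlap, i.e. three averaged
periodograms per 384-sample window; linear units (µV²/Hz), no log
transform — and averaged over the bins of four bands: theta 4–8, alpha
8–15, beta 15–32, gamma 32–45 Hz. Band intervals are half-open `[low, high)`
so the shared edges 8, 15 and 32 Hz are counted once, in the upper band.
That gives 32 × 4 = 128 features per window.

Features are min–max scaled per subject and per channel–band column over
all of that subject's windows, before any train/test split. The default map
is deliberately the *inverted* orientation

    F' = (F_max − F) / (F_max − F_min),

which sends the column maximum to 0 and the minimum to 1. This orientation
is unusual but is retained as the default for fidelity to the procedure the
package reproduces; `orientation="conventional"` restores
`(F − F_min)/(F_max − F_min)`. A degenerate column (`F_max == F_min`) maps
to 0. Computing extrema on the full dataset leaks rank information across
CV folds; `normalize_subject(..., fit_rows=...)` offers a fold-safe variant
(extrema from training rows only, out-of-range values clipped to [0, 1]).

## The multiband feature matrix (MFM)

Each band's 32 normalized features are scattered onto a 9×9 grid laid out
like the scalp seen from above (row 0 anterior, column 0 left); the 49
non-electrode cells keep a fill value of 0. The electrode→cell table is a
package constant (`DEFAULT_MONTAGE`) chosen to respect 10–20 topology —
homologous pairs (F3/F4, T7/T8, O1/O2, …) occupy mirrored columns `c` and
`8 − c` in the same row, midline electrodes sit in column 4. It is an
artifact convention, replaceable wholesale through the `montage` arguments,
since no machine-readable standard fixes the exact cell assignment. The
four grids tile 2×2 — theta top-left, alpha top-right, beta bottom-left,
gamma bottom-right — into the 18×18 MFM; classification is invariant to
this fixed relabeling, so the order is a configuration constant.

## Capsule network

Architecture (model A, the adopted preset):

1. **Conv + ReLU** — 3×3 kernel, stride 1, no padding, 256 filters:
   18×18 → 16×16×256 (valid-convolution side `floor((n−k)/s)+1`).
2. **Primary capsules** — 3×3 conv, stride 2 → 7×7×256, read as 49 spatial
   capsules of 256 dimensions, then squashed. Presets C/F instead group the
   channels into 32 (resp. 16) capsule types of 8 dimensions per position.
3. **Emotion capsules** — one transformation matrix per (primary, class)
   pair (no weight sharing), predictions coupled by 3 iterations of
   routing-by-agreement: logits start at 0, couplings are the softmax of
   the logits over classes, the class input is the coupling-weighted sum of
   predictions, its squash the output, and each logit grows by the
   prediction·output dot product. Class score = capsule norm; the squash
   `v = (‖s‖²/(1+‖s‖²)) · s/‖s‖` keeps norms in (0, 1).
4. **Decoder** — 512 → 1024 → 324 fully connected (ReLU, ReLU, sigmoid)
   reconstructing the flattened MFM from the emotion capsules, with the
   non-target (at evaluation: non-predicted) capsule zero-masked, following
   the routing literature's convention; the sigmoid output matches the
   [0, 1] range of normalized MFMs.

**Loss.** Margin loss per class
`L_e = T_e max(0, m⁺−‖v_e‖)² + λ(1−T_e) max(0, ‖v_e‖−m⁻)²` with
m⁺ = 0.9, m⁻ = 0.1, λ = 0.5, summed over classes and averaged over the
batch, plus a reconstruction term: sum of squared errors to the flattened
input, weighted 0.0005 per element (config-exposed).

**Implementation.** The network is pure NumPy with hand-written forward and
backward passes (im2col convolutions, exact squash/softmax Jacobians) and
an Adam optimizer (lr 10⁻³, β = 0.9/0.999). The backward pass is exact
through *every* routing iteration, including the logit-update path — a
deliberate choice over the common stop-gradient shortcut, because it makes
the whole graph verifiable: the test suite checks analytic gradients
against central finite differences on a small configuration and they agree
to better than 10⁻⁴ relative error. Weight init: fan-in-scaled normals for
convolutions and decoder, truncated normal (sd 0.05) for the capsule
transformation matrices; all randomness flows from the config seed, so a
fit is bit-reproducible. Training the full model A (≈ 2.3 M parameters) on
CPU is feasible but slow; the model-1 preset (32 filters, 16-dim emotion
capsules) trains in seconds per thousand samples and is used for the
self-contained benchmarks.

Defaults elsewhere: 400 epochs, batch 40, 3 routing iterations, 10-fold CV
— the protocol of the study being reproduced; the bundled benchmarks reduce
epochs and dataset size as noted below.

## Evaluation protocol

`kfold_split` shuffles and partitions samples into k near-equal folds
(unstratified, as in the reproduced protocol); `holdout_split` is
stratified 8:1:1 per label. A fresh, seed-derived model is trained per
fold; a fold whose training data degenerates to one class is skipped with
a warning and recorded. Because pooled sample-level splitting places
windows of the same trial on both sides of a split, results are optimistic
relative to trial-grouped splitting; `EvalProtocol(group_by_trial=True)`
provides the leakage-safe variant.

A measurable consequence of that leakage: under segment-level label
permutation the null CV accuracy is not exactly centred at 0.5 — a trial's
permuted-label counts in its train and test windows are hypergeometrically
correlated, and the model memorizes trials — so null runs fluctuate a few
percentage points around chance (observed ≈ 0.49–0.55 across seeds at
n = 1,600). This is a property of the protocol, not a defect of the
permutation test.

## Synthetic benchmark

The generator emulates the preprocessed DEAP layout exactly (40 trials ×
32 channels × 8064 samples, 3 s baseline, ratings in [1, 9]). Per trial and
per affective dimension a latent fair-coin class modulates the amplitude of
a narrowband carrier — order-4 Butterworth band-pass filtered white noise,
unit RMS — on a fixed channel subset: high-arousal trials get ×3 beta
amplitude on frontal channels, high-valence ×3 alpha on parieto-occipital,
high-dominance ×3 gamma on centro-temporal; the low class keeps amplitude
1. The background is gently low-pass-coloured Gaussian noise (sd 1), the
baseline contains background only, and ratings are drawn uniform on [6, 9]
(high) or [1, 4] (low) so binarization at 5 recovers the latent class
exactly; liking is uniform on [1, 9]. A pure-tone carrier mode (sinusoid at
the band centre) exists for spectral-placement unit tests. Determinism: the
random stream is keyed by (config seed, CRC32 of the subject id), so
subjects are independent but every run is bit-reproducible.

With the default ×3 effect the classes are linearly separable from the
band-power features (a logistic model on held-out windows scores ≥ 0.95,
in practice 1.0), which is what makes the capsule-network learnability
benchmark well-posed: 2-fold CV on 1,600 MFMs (2 subjects) with the
model-1 preset reaches mean accuracy ≥ 0.95 within 10 epochs, while the
same run on permuted labels stays at chance.

What the generator does **not** emulate: realistic 1/f spectra, artifacts,
volume-conduction correlation between channels, non-stationarity, or any
genuine relation between EEG and affect. Passing benchmarks therefore
demonstrate that the pipeline's mechanics — segmentation arithmetic,
spectral estimation, topographic mapping, routing, optimization and
evaluation — are correct and that the classifier recovers planted
band-power structure; they say nothing about accuracy on real EEG.

## Numerical choices and degenerate inputs

- Squash and capsule norms guard zero vectors with an additive 10⁻¹² under
  the square root; the squash of the zero vector is the zero vector.
- Half-open band edges avoid double counting; a band edge at or above
  Nyquist is rejected.
- Welch needs at least one full window (128 samples) per segment; shorter
  segments are rejected rather than padded.
- A trial shorter than baseline + one window raises an error naming the
  trial; an empty recording (0 trials) flows through the whole pipeline as
  empty output.
- Ratings are validated to [1, 9] at container boundaries, with the
  offending trial named.
- k-fold with n < k, hold-out with a label rarer than 10 samples, and
  single-class datasets are rejected up front.

## Benchmark problem sizes

The self-contained benchmarks use a full 32-subject synthetic cohort
(25,600 MFMs) for the structural counts, and 2 subjects (1,600 MFMs),
2-fold CV, 10 epochs, batch 40, model-1 preset for the learnability and
null-calibration runs — small enough to run in minutes on one CPU while
still exercising every stage at the real per-subject scale.

## Known limitations

- Full-scale training (model A, 400 epochs, 25,600 MFMs, 10-fold) is
  supported by the code but takes CPU-days in NumPy; the presets and
  protocol objects expose it, the bundled benchmarks do not run it.
- The montage is a declared convention; alternative readings of the
  electrode-to-grid assignment plug in via `montage=`.
- The inverted normalization default follows the reproduced procedure even
  though the conventional orientation is the likelier intent; both are
  one flag apart.
- No early stopping, learning-rate schedule or regularization beyond the
  reconstruction term; none are part of the reproduced protocol.
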