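# Methods

## The generative model behind the synthetic datasets

Every downstream component is exercised on synthetic volumetric-slice
datasets, so the generator's assumptions are the assumptions of the whole
test battery. Each image of subject *s* in class *k*, volume *v*, slice *z*
is

    I(z) = clip( B_ks(z) · exp(σ·N(z) − σ²/2), 0, 1 ),  quantised to 8 bits

with a structural base and a multiplicative speckle factor:

- **class template** — a smooth random field (Gaussian-filtered white noise,
  filter width ≈ image_size/12) with standard deviation `0.15·class_effect`,
  plus a class-dependent mean-intensity offset `0.10·class_effect` spread
  symmetrically around zero. The offset guarantees the class signal is
  learnable even by a mean-intensity threshold, which the tests use as a
  guard against a generator with no class information.
- **subject field** — a smooth field with sd `0.12·subject_effect`,
  spatially centred (zero mean) so that subject identity lives in texture,
  not brightness. This is the component that leaks across a per-image
  split.
- **volume structure** — a smooth field with sd 0.10 that evolves along the
  slice axis as a stationary AR(1) process with per-slice correlation
  `exp(-slice_drift)`. `slice_drift = 0` freezes the structure across the
  volume (with `noise_sigma = 0` the slices are then bit-identical); a
  large drift renders slices structurally independent, which is how the
  leak-free negative-control dataset is built.
- **speckle** — log-normal multiplicative noise of amplitude `noise_sigma`
  whose underlying Gaussian field is carried between adjacent slices by an
  AR(1) with coefficient `noise_share`; a `noise_share` of 0.8 means ~80 %
  of the noise field of slice *z* persists into slice *z+1*, mimicking the
  correlated speckle of coherent imaging.

Pixel values are quantised to 8 bits in memory, so a configuration plus a
seed yields bit-identical data across runs and lossless PNG round-trips.
Entity-level random streams are keyed by (seed, role, class, subject,
volume), so enlarging one level of the hierarchy does not reshuffle the
others.

**Default condition** (the "leaky" study dataset): 2 classes × 10 subjects ×
1 volume × 20 slices of 64×64 pixels, `class_effect = 0.3`,
`subject_effect = 1.5`, `noise_sigma = 0.4`, `noise_share = 0.8`,
`slice_drift = 0.02`. The deliberate choice of a subject appearance five
times stronger than the class signal puts the data in the regime where
slice-wise splitting is genuinely dangerous: a network can saturate the
test set by recognising subjects while true cross-subject generalisation
is only moderate. Mean pairwise image correlations at the default:
adjacent slices ≈ 0.89, same class/different subject ≈ 0.04, cross-class
≈ 0.0 (and ≈ 0.38 for same subject/different volume in multi-volume
configurations) — the ordering the leakage argument rests on, verified
over seed sweeps in the tests.

**Negative control**: `subject_effect = 0`, `noise_share = 0`,
`slice_drift = 5.0` — no subject signature, no shared noise, structurally
independent slices. Under this condition the two split strategies must
agree to within sampling error; the tests assert |Δ mean MCC| < 2 pooled
standard errors.

What the generator does **not** emulate: physically realistic OCT speckle
statistics, the rotation/flip augmentation baked into some published
datasets, anisotropic anatomy, class-dependent image counts, scanner
differences. Passing on synthetic data therefore demonstrates that the
pipeline is correct and that the leakage mechanism behaves as described —
not that any particular real dataset exhibits a particular effect size.

## Split strategies

Both strategies draw a fixed number of test images per class
(default 60 of 200 per class).

- **per-image**: uniform sampling of slices without replacement, per class,
  ignoring identity. Leak-prone by construction.
- **per-volume/subject**: whole units (subjects, or volumes) are drawn per
  class until the accumulated image count reaches the target, then the
  drawn pool is trimmed to the exact count by uniform subsampling *within*
  the drawn units. Slices trimmed away belong to test subjects, so they are
  marked `excluded` and kept out of training; recycling them would
  reintroduce the leak the strategy exists to prevent. The exact-count
  contract mirrors protocols that fix the test size per class while
  respecting subject boundaries.

The repeated-CV plan draws a fresh test set per repeat (seed =
base_seed + repeat) and partitions the remaining pool into k validation
folds — stratified by class over images for per-image plans, partitioning
subjects (balancing subject counts, not image counts, since subjects have
unequal image counts only in real data) for subject-wise plans. Each
(repeat, fold) slot trains on k−1 folds, validates on the held-out fold and
tests on the repeat's test set. Re-drawing the test set each repeat is a
deliberate choice: it makes the between-model spread of test MCC reflect
test-set sampling variability as well as training noise.

The **overlap audit** is the leak meter: the fraction of test images whose
subject ID also occurs among training subject IDs. It is exact, cheap, and
the quantity a practitioner should compute before trusting any pre-split
dataset. It does not detect pixel-level near-duplicates across different
subject IDs.

## The classifier

A deliberately shallow CNN: conv(8 filters, 5×5, same padding) → ReLU →
2×2 max-pool stride 2 → conv(32, 5×5, same) → ReLU → flatten → dense(K) →
softmax, cross-entropy loss, SGD with momentum 0.9, Glorot-uniform
initialisation. Same padding keeps spatial sizes predictable (the flatten
width is (H/2)·(W/2)·32); the parameter count is checked symbolically in
the tests. Convolutions are evaluated as im2col + a single float32 BLAS
matmul; input gradients are computed as a same-padded convolution with the
spatially flipped, channel-transposed kernels, and the first layer skips
its input gradient entirely. The backward pass is verified against central
finite differences.

Two presets:

| knob | desk preset (default) | full-scale preset (`TrainConfig.full_scale()`) |
|---|---|---|
| input size | 64×64 | dataset-native |
| epochs | 8 | 250 |
| batch | 32 | 64 |
| learning rate | 0.005 | 1e-4 |

The desk preset is what the analysis scripts and tests run: at a few
hundred 64×64 training images and single-CPU budgets, eight epochs at
lr 0.005 reach the same qualitative regime (per-image split saturated,
subject-wise split partially generalising) that hundreds of epochs at
lr 1e-4 reach on tens of thousands of full-size images; larger step sizes
occasionally collapse a run into a single-class predictor, so the desk
learning rate is the largest value that trains reliably. The full-scale
preset is retained for runs on real datasets. Problem sizes used by the
shipped experiments: 10 model slots per strategy (2 repeats × 5 folds),
~224 training images per slot.

## Metrics

All scalar metrics derive from one K×K confusion matrix (rows = truth).
Multiclass MCC uses the R_K form; both denominator factors vanishing to
zero (e.g. a single predicted class) returns 0 rather than NaN, so
degenerate classifiers score as chance. Per-class accuracy, precision,
recall and F1 follow the one-vs-rest reductions, with 0 substituted for
0/0. ROC AUC is computed per class one-vs-rest by the Mann–Whitney rank
statistic with midranks for ties (constant scores ⇒ 0.5); classes absent
from the test truth are excluded from the macro mean with a warning.
Aggregation over a CV run pools all (model, class) values for
class-resolved metrics and one value per model for MCC/overall accuracy,
reporting mean and sample standard deviation (n−1). Note that "accuracy"
is reported twice on purpose — the Sokolova per-class (TP+TN)/s form and
the overall trace/s form — because the two coincide only on balanced test
sets.

## The random-label leakage test

Procedure: for every CV slot, randomize the *training* labels (per-image
uniform draws by default; per-subject available — one draw applied to all
of a subject's slices), train from scratch, and compute test MCC against
the *original* labels. Compare the observed MCCs to a Monte-Carlo null of
MCC values from independently drawn random label/prediction pairs matched
to the test-set size and class frequencies (10,000 samples by default),
using a two-tailed one-sample Wilcoxon signed-rank test against the null's
median (the null is slightly discrete and near-symmetric about 0; the
median is its natural location parameter). The logic: on a leak-free
split, a model trained on noise can only perform at chance, so a
systematically non-chance MCC flags information shared between training
and testing data.

The Wilcoxon implementation drops zero differences, midranks ties, and
uses exact enumeration of the 2^n sign assignments (dynamic programming
over doubled ranks, so tied magnitudes stay integral) for n ≤ 25, with the
tie-corrected, continuity-corrected normal approximation above. If every
observed MCC equals the null median the test is undefined and the
experiment reports p = 1 with a note. A second degeneracy needs care:
random-label training frequently collapses every model to a majority-class
predictor with MCC exactly 0, and a signed-rank test on n identical values
would "significantly" detect any sub-resolution offset between that point
mass and the discrete null's median. When all observed MCCs are identical
the experiment therefore reports the two-tailed Monte-Carlo tail
probability of that single value under the null instead, which still flags
a genuinely extreme common value but stays quiet at chance level.

Detection *power* — whether a leaky split reliably drives p below
threshold at desk scale — is left as an empirical question; the shipped
tests verify the type-I side (on leak-free splits, p ≥ 0.05 in ≥ 90 % of
20 seeded runs) and the calibration of the null (|mean| < 0.005 at
10,000 samples).

## Numerical and design notes

- All randomness flows through integer seeds into `numpy` PCG64 streams;
  training is bit-reproducible on a fixed platform (float32 arithmetic, no
  threading nondeterminism in the path).
- Loader conventions: filenames are parsed from the right (class labels may
  contain hyphens); folder-derived subject IDs are namespaced by class to
  prevent cross-class ID collisions in audits; slice order follows
  numeric-aware natural sort; images are standardised to grayscale [0,1]
  at a configurable size (default 128×128) with bilinear resizing.
- Pre-split ("kermany-like") layouts do not expose volumes, so the loader
  sets volume_id = subject_id; subject-level audits are unaffected.
- Strategy failures inside an experiment are isolated and logged so a long
  run still yields the other strategies' results.

## Known limitations

- The synthetic speckle is a statistical stand-in, not an optical model;
  effect sizes measured on synthetic data do not transfer to any real
  dataset.
- The audit detects leakage only through shared subject IDs — identical or
  near-identical images under different IDs (e.g. augmentation leakage)
  are out of scope.
- The desk-scale CNN preset is tuned for demonstrating the split effect,
  not for state-of-the-art classification.
- The exact Wilcoxon branch costs O(n²·max-rank) via the DP; it is capped
  at n = 25 where the normal approximation is already accurate to < 0.02.
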