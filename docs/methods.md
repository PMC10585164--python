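# Methods

## The compound loss

`lobeseg` trains a binary segmentation network with

FGD-BCEL = (GDL)^α + β · BCE,

where GDL is the two-class generalized Dice term
1 − 2·Σ_l ω_l Σ_n r_ln p_ln / Σ_l ω_l Σ_n (r_ln + p_ln) with per-class
weights ω_l = 1/(Σ_n r_ln)², α = 0.75 and β = 0.7 by default, and BCE is the
pixel-mean binary cross-entropy. Both class sums run over foreground
(r_n, p_n) and background (1 − r_n, 1 − p_n). The inverse-squared class
volume makes a pixel of the scarce class worth roughly (n_bg/n_fg)² times a
background pixel inside the Dice ratio, which is what keeps gradient signal
alive at foreground fractions of a few percent and below. The focal exponent
α < 1 *amplifies* the gradient of the Dice term as it approaches 0 (unlike
classical focal exponents > 1, which damp easy examples); it is implemented
exactly as specified, with no reinterpretation. The BCE term carries no
per-class weights by default — β alone sets its contribution — but optional
class weights are exposed (`FGDBCELParams.bce_weights`).

Numerical choices, applied identically in the reference (numpy) and training
(autodiff) paths:

* one smoothing constant ε (default 1e-6) added to the numerator and
  denominator of every Dice-type ratio;
* probabilities clipped to [clip_eps, 1 − clip_eps] (default 1e-7, the Keras
  convention) before logarithms;
* the gradient of x^α floors its base at 1e-12, so a perfect prediction does
  not produce an infinite focal derivative;
* class sums pool over the whole training batch by default
  (`lobeseg.losses.batch_loss(per_image=True)` gives the per-slice variant;
  the GDL class weights then differ on heterogeneous batches).

Baseline losses follow the field's conventions: Dice loss on the foreground
class only; Tversky with fp/fn weights 0.3/0.7 (constrained to sum to 1);
focal Tversky with γ = 0.75. The Tversky/focal-Tversky hyperparameters are
the conventional defaults from their source formulations and are fully
configurable. Limit identities — α=1, β=0 reduces the compound loss to GDL;
γ=1 reduces FTL to TL; fp=fn=0.5 reduces TL to DL — are enforced by tests
(the last one to one float64 ulp, since the two formulas sum in different
orders).

## Metrics

DSC, JSC, PPV and SE are computed from exact pixel confusion counts. The
Hausdorff distance is max(h(X,Y), h(Y,X)) with h the farthest
nearest-neighbour distance over *all* foreground pixel coordinates (a
boundary-only variant is behind a flag), scaled by the pixel spacing when
given — so HD is in millimetres with spacing, pixel units without. The fast
path uses a KD-tree and is tested for exact equality against the O(|X||Y|)
all-pairs evaluation. Degenerate slices follow an explicit policy: when
prediction and reference are both empty the overlap metrics return 1 by
default ("both-empty-is-perfect", configurable); HD is undefined on an empty
mask, raises when called directly, and such slices carry NaN in per-slice
reports and are excluded from the HD mean/SD. Aggregation is per-slice
across the test set with the sample SD (ddof = 1); per-subject aggregation
can be had by grouping the per-slice table, which is also the box-plot data.

## Preprocessing and augmentation

The slice preparation chain is HU conversion (raw·slope + intercept from the
scanner header), window/level at WW 160 / WL 80 (clip HU to [0, 160], then
map linearly to [0, 1] — the post-window scaling is chosen so windowing and
normalization compose cleanly), CLAHE (clip limit 0.01, 8×8 tiles — unstated
in the source protocol, configurable), and min-max normalization to [0, 1]
with constant images mapping to zeros. Augmentation samples one affine
transform per copy — rotation ±15°, isotropic zoom [0.9, 1.1], shear ±8°,
horizontal flip with probability 0.5 — and applies it identically to image
(bilinear) and mask (nearest neighbour, so labels stay exactly {0, 1}); the
whole sequence is reproducible from the spec's seed. The ranges are chosen
as typical mild CT augmentation magnitudes; only the augmentation *outcome*
(an expanded training set) is fixed by the protocol being emulated.

## Network and training

The model is the classic 4-level U-Net: encoder blocks of two 3×3
convolutions (ReLU) + 2×2 max pooling, a two-convolution bottleneck, decoder
blocks of a stride-2 3×3 transposed convolution (implemented as zero-
insertion upsampling followed by a 3×3 convolution), skip concatenation and
two 3×3 convolutions, and a 1×1 sigmoid head. All convolutions use zero
("same") padding, so skips concatenate without cropping and output shape
equals input shape; input sides must be divisible by 2^depth. Channel widths
double per level from `base_filters` (64 at full 512×512 scale; 8 in the
desk-scale runs). No batch normalization. The whole network runs on the
package's own numpy reverse-mode autodiff engine (`lobeseg.nn`): same-padded
odd-kernel convolution via sliding-window views and BLAS tensordot, with
gradients computed as correlations with rotated kernels.

Training uses Adam (β₁ 0.9, β₂ 0.999; the optimizer is not named in the
emulated protocol, Adam is the field's default for U-Nets) with a
continuously decayed learning rate lr₀ · rate^(step/steps) (staircase decay
behind a flag). The published full-scale schedules are kept verbatim in
`FULL_SCALE_TRAIN_CONFIGS` (batch 2, 120 epochs, per-loss rates 3e-4…2e-3,
decay rate 0.96 every 400–600 steps); at desk scale all arms share one
reduced schedule by default, since the per-loss rates were tuned at 512×512.
Weights are He-normal from the run seed. Predictions binarize at p ≥ 0.5.
Desk-scale schedules additionally use a short linear learning-rate warmup
(about three epochs): Adam's moment estimates are uncalibrated over the
first steps, and on severely imbalanced masks those early effectively-large
updates can push the network into the all-background basin from which
neither the clipped cross-entropy nor the saturated Dice gradients recover.
Warmup removes this seed-dependent failure without changing the schedule
thereafter; the full-scale published schedules are kept verbatim.

**Output-bias initialization.** The 1×1 head's bias is initialised to the
logit of an expected foreground prior (default 0.01) rather than 0. With a
0.5 initial output on masks whose foreground is far below 1%, the first
epochs of any loss drive every logit strongly negative; once probabilities
cross the clipping bound the cross-entropy gradient is masked and the
Dice-type gradients vanish with the sigmoid's slope, and training cannot
recover. Starting at the class prior removes that collapse mode for every
arm symmetrically. Set `UNetConfig.head_bias_prior=None` for a zero bias.

## The phantom

Real planning-CT cohorts of this kind are private, so the generator emulates
the *statistical* structure the losses target, not CT physics: a bright
elliptical skull ring, a smoothly textured brain interior (Gaussian-filtered
noise), and two lateral lobe-like foreground regions — randomly rotated and
eccentric superellipses — whose pixels are shifted by `lobe_contrast`
(default +0.18 on the [0,1] scale, mild enough that the task needs learned
context, strong enough to be learnable at 64–128 px). Default study
conditions: 128×128 slices, 20 subjects × 12 slices, per-slice foreground
fraction 0.5–3% on mid-lobe slices (cohort-wide below 5%, typically ~1.5%),
15% pole slices with 1–8 foreground pixels, pixel noise SD 0.03. Slices are
deterministic in (seed, subject, slice). The subject-level split is a seeded
random 7:1:2 partition (sizes round(0.7n)/round(0.1n)/remainder; 70 subjects
give 49/7/14); pole-heavy subjects distribute across partitions in
expectation, verified by a pooled chi-square test over seeds.

What passing on the phantom does and does not show: the phantom reproduces
the class-imbalance geometry (small bilateral blobs, few-pixel poles, skull
distractor) but not CT noise physics, anatomical shape variability, observer
variability in reference masks, or 3-D continuity between slices. Phantom
results therefore validate the *mechanics* of the losses, metrics and
training loop, not clinical segmentation accuracy; the published patient-
data metric values are out of reach by construction.

## Desk-scale run sizes

All training-based checks are sized for one CPU with the numpy engine
(~0.17 s per 128×128 image forward+backward at base_filters 8):

* stability: 20-epoch runs of all five losses on a 10-slice subset of the
  default phantom's training split, base_filters 4 — asserts finite losses
  throughout;
* recovery: 128×128 phantom, 10 subjects × 5 slices (35 training slices),
  base_filters 8, 32 epochs at lr 2e-3 with 54 warmup steps — test DSC must
  exceed the 0.70
  adequacy threshold; mid-lobe slices typically reach DSC 0.9+, with the
  cohort mean pulled down by few-pixel pole slices;
* imbalance: 64×64 phantom at foreground fraction 0.30–0.45% (below 0.5%),
  30% pole slices, 18 epochs at lr 1e-3, paired seeds — pole-slice
  sensitivity of the compound loss must exceed the plain-BCE arm's by a
  clear margin. The comparison is made at an epoch budget where the
  unweighted baseline still lags; with much longer training plain BCE also
  eventually learns this phantom, so the claim is about sample-efficiency
  under imbalance, not impossibility.

## Known limitations

* Binary (two-class) task only; no boundary-based losses; no 3-D variants.
* The autodiff engine implements exactly the ops this network needs; it is
  not a general-purpose framework (no strided convolution other than the
  pool/upsample pair, no batch norm).
* Training reproducibility is bitwise given a seed on one platform;
  different BLAS builds may differ in the last float digits, which is why
  stochastic assertions carry margins.
* HD units follow the supplied pixel spacing; without spacing they are pixel
  units.
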