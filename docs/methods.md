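# Methods

`marginseg` implements a margin-aware pipeline for segmenting superficial
tumors in B-mode ultrasound, in the intra-operative setting where the
transducer rests on the resection surface of an excised specimen. Row 0 of
every image is the cut surface; the clinically decisive quantity is the
*top margin* — the distance from that surface to the shallowest tumor
pixel. This note records the models, the parameter choices, and the
numerical decisions behind them.

## Losses

**Generalized Dice (GenDice).** For a two-channel ground truth `g`
(background k=1, tumor k=2) and foreground probabilities `p`
(`p_1 = 1 − p_2`):

    GenDice = 1 − 2 Σ_k w_k Σ_n g_kn p_kn / Σ_k w_k Σ_n (g_kn + p_kn),
    w_k = 1 / ((Σ_n g_kn)² + ε)

The inverse-squared-area weights counter foreground/background imbalance.
`ε = 1e-8` (configurable) keeps empty classes finite; an empty class also
triggers a warning because its weight is then 1/ε.

**Gradient-weighted Dice (GWDice).** A depth gradient is applied to the
tumor channel before the overlap is computed. With `minM`/`maxM` the
global top/bottom tumor rows, the weight at row `x` inside the tumor is

    w(x) = ((x − maxM) / (maxM − minM))²

— 1 at the shallowest row, 0 at the deepest, quadratic in normalized
depth; a single-row tumor takes the limit value 1. The loss is

    GWDice = 1 − 2 Σ_k w_k Σ_n g_kn t_kn p_kn / Σ_k w_k Σ_n (t_kn + p_kn)

with `t` equal to `g` on the background channel. The asymmetry (numerator
weighted by `t`, denominator accumulating raw `p`) means probability mass
anywhere inflates the denominator while only overlap with heavily weighted
shallow pixels earns credit.

**Weight-profile variants and the training default.** The weight profile
is configurable as `t = scale · (b + (1 − b) · w)`. Two profiles matter:

* `b=0, scale=1` — the pure quadratic 1→0 profile. This is the
  `gradient_weight_mask` default and what the loss-oracle tests pin down.
* `b=0.5, scale=2` — the 2→1 profile: bottom-of-tumor pixels keep their
  ordinary Dice weight, top pixels count double.

The **training harness defaults to the 2→1 profile**. The reason is a
structural property of the 1→0 profile we found while validating the
optimizer: because the foreground weights integrate to roughly a third of
the tumor area while every unit of predicted probability still enters the
denominator at full weight, the all-background prediction can attain a
*lower* loss than the perfect prediction (on our phantoms, ≈0.34 vs
≈0.35 for typical lesion sizes), and gradient descent reliably collapses
into it. The 2→1 profile keeps every tumor pixel at least at its GenDice
weight, so the perfect prediction dominates and training is stable while
the top emphasis is retained. Both profiles remain exposed;
`TrainConfig(gw_baseline=0.0, gw_scale=1.0)` restores the quadratic one.

Both losses return analytic gradients with respect to the probability
map (validated against central finite differences at step 1e-4 to 1e-3).

## Margin metric and evaluation

The tumor-margin error is `|minRow(truth) − minRow(pred)| · s_row` in mm,
with `s_row` the row spacing. The topmost pixel is global, not
per-column. Conventions where the definition is silent:

* empty prediction: no margin exists; the measurement is flagged and
  penalized with the worst realizable error (true top row to image
  bottom), keeping test-set averages defined;
* empty ground truth: an error — there is no margin to measure;
* Dice of two empty masks is 1, one empty mask 0;
* AUC is pooled pixel-wise over all images of a method (one ROC per
  method), computed with scikit-learn's `roc_curve`;
* binarization is `p ≥ threshold`, so threshold 0 keeps everything.

Pixel spacing is never implied by the image files; the default derives
from the acquisition geometry — 30 mm imaging depth over 344 raw rows
(≈0.0872 mm/px), becoming ≈0.1172 mm/px after crop-to-top-half and resize
to 128². Every mm value in a report records the spacing used. The
threshold sweep evaluates Dice and margin error at every threshold and
exposes both optima; the two generally differ (a faint shallow rim is
included only at low thresholds, at the price of false positives
elsewhere), which is the trade-off the sweep exists to expose.

## Pre-processing and augmentation

Crop to the top half (floor on odd heights), bilinear resize to 128×128
(nearest-neighbor for masks, re-binarized at 0.5), per-image min-max
normalization to [0,1] (a constant image normalizes to zeros with a
warning); spacing is rescaled by old/new size per axis. Training-time
augmentation samples independently per epoch: left-right mirror with
probability 1/2, rotation uniform in ±5°, gamma correction
`P_out = P_in^γ` with γ uniform in [0.8, 1.2]. Mirroring is about the
*vertical axis*: a top-bottom flip would move the transducer surface to
the image bottom and silently invalidate both the depth-weighted loss and
the margin metric, so it is opt-in only. All augmentation is driven by an
explicit seed and byte-reproducible.

## Post-processing

Predictions keep their largest connected component (8-connected by
default, configurable to 4), then undergo morphological closing with a
discrete disk of radius 3 px (pixels at Euclidean distance ≤ r). Order is
fixed: component selection first, closing second. Area ties between
components are broken by raster-scan order (the component containing the
lexicographically smallest pixel wins), making results bit-reproducible.

## Phantom generator

The generator is statistical, not acoustic — no wave propagation. Its
contract is to reproduce the features the rest of the pipeline depends
on, with study-scale geometry:

* cohort geometry: 74 patients, 1–3 frames each (patient-wise splits in
  121/28/30 proportions, no patient spanning splits); lesion margin depth
  6.4 ± 3.7 mm; lesion diameter 41 ± 19 mm truncated to the field of
  view; per-patient geometry shared across frames up to small jitter;
* a hypoechoic lesion: a radially perturbed ellipse (low-order Fourier
  boundary noise) inserted with a diffuse edge (Gaussian blur of the
  indicator) at 0.55–0.65 of the background echo;
* layered background strata, depth attenuation `exp(−0.045 · depth_mm)`,
  and multiplicative spatially correlated Rayleigh speckle;
* an exact binary mask; the mask's realized top row is pinned to the
  sampled margin depth (±1 px), so the margin distribution is exact by
  construction.

**Margin distribution.** Naively truncating N(6.4, 3.7²) to the 15 mm
post-crop field of view shrinks the realized sd by ~16%. The sampler is
therefore a truncated normal whose pre-truncation parameters are
moment-matched (root-finding on the truncated-normal moments) so the
*realized* mean/sd equal the cohort values; infeasible requests (an sd no
distribution on the interval can reach) fail loudly at spec construction.

**Texture difficulty.** Lesion contrast, edge blur and speckle amplitude
are set so that desk-scale models reach test Dice ≈ 0.75–0.9 rather than
saturating near 1.0 — tumor boundaries in B-mode are diffuse, and a
generator on which every model is perfect cannot exercise loss or
ensemble comparisons. Two texture domains ("source" standing in for
breast ultrasound, "target" for colorectal) differ in speckle amplitude
(0.35 vs 0.50), contrast (0.55 vs 0.65) and boundary roughness (0.05 vs
0.12 of radius), giving transfer learning a measurable gap (a two-sample
test on high-pass variance separates the domains).

**What the phantoms do not model:** refraction, shadowing, reverberation,
anisotropic PSFs, real anatomical context, pathology-realistic lesion
morphology. Passing trends on phantoms demonstrate that the machinery
behaves as designed, not that clinical-scale performance is reproduced.

## Networks and training

The segmentation models are compact two-resolution encoder-decoders
written directly in numpy with hand-derived backpropagation (im2col
convolutions, average pooling, nearest upsampling, skip concatenation,
sigmoid head), sized for minute-scale CPU training on 64² phantoms. Five
*variants* — base width 8/12/16 channels, with and without an extra
bottleneck convolution, distinct init seeds — stand in for five
independently designed architectures; everything downstream only assumes
models emit probability maps. End-to-end parameter gradients are verified
against finite differences in the test suite.

Training uses Adam (lr 1e-3 scratch), batches of 2–4 images, per-epoch
augmentation, and selects the epoch with the best validation Dice at
threshold 0.5 without post-processing (post-processing is reserved for
final evaluation). Fine-tuning loads a source-domain checkpoint, freezes
nothing, and scales the learning rate by 0.1. Checkpoints are `.npz`
arrays with a JSON sidecar carrying the full configuration; training logs
are CSV (epoch, split, loss name, value). A non-finite loss aborts with a
diagnostic rather than training through NaNs.

**Desk-scale experiment budgets** (the protocols in
`marginseg.experiments`): 64×64 phantoms at 0.2344 mm/px row spacing;
source pre-training 20 epochs; the transfer comparison uses a matched
12-epoch budget per arm — transfer learning is a scarcity technique, and
with a long enough budget scratch training catches up, which is itself
visible in the harness; the loss comparison trains both arms 40 epochs
(near convergence at this scale); the ensemble study fine-tunes all five
variants 15 epochs and evaluates on 30 held-out phantoms never seen by
any model or optimizer.

## Ensemble fusion

Four strategies over the five models' probability maps: unweighted
averaging, weighted averaging, voting (tumor iff ≥ `vote_count` binarized
maps agree), and a pixel-level logistic-regression combiner (five
coefficients + intercept — auditable and fast; the kind is configurable
in principle but only the logistic combiner is built in). All fusion
parameters are optimized on the validation split only: output threshold
on a 0.01 grid, model weights on a step-0.1 simplex grid (step 0.2 in the
desk-scale study to bound its cost), vote count 1..M with a shared
per-model threshold grid. The "balanced" criterion maximizes
`mean Dice − λ · margin_mm / margin_ref` with λ=1 and margin_ref=1 mm —
the resection margin used clinically — putting both terms on comparable
scales. Ties deterministically keep the most uniform / lowest-threshold
candidate.

## Known limitations

* The numpy networks are orders of magnitude smaller than clinical-scale
  architectures; absolute Dice/margin numbers are not comparable to
  GPU-trained systems, only directions of effects.
* The margin metric uses the global topmost pixel; a single
  false-positive speck above the tumor dominates it, which is why the
  largest-component step precedes measurement in the standard pipeline.
* The balanced fusion criterion is a fixed scalarization; a Pareto sweep
  would expose the full trade-off.
* Phantom realism is statistical; see the generator section for the
  explicit exclusion list.
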