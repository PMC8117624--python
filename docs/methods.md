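# Methods

`dualae` implements unsupervised lesion segmentation by reconstruction:
shallow sparse autoencoders are trained *only on normal appearance*, so a
trained model reproduces normal image content well and anomalous content
poorly; the reconstruction residual is then segmented. This note documents
the model, the numerical choices, the synthetic data the package is tested
on, and the limits of what those tests show.

## Model

### Directional patches

Each 2D grayscale slice (intensities in [0, 1], optional brain mask) is
decomposed into horizontal 16×64 and vertical 64×16 windows flattened to
1024-vectors. The two elongated orientations capture longer-range context
along each axis than a square patch of equal area. Both orientations share
one nominal anchor grid (stride 16 px by default), so row *k* of the
horizontal patch matrix and row *k* of the vertical matrix describe the
same neighbourhood and can be paired in latent space; windows are clamped
inward at the image border (duplicate windows at clamped borders are kept
so the pairing stays 1:1). Images are recomposed by arithmetic-mean
overlap compositing, which is unbiased and seam-free; the extract →
reassemble round trip reproduces the input exactly up to float64 addition
(≲1e-13; pixels whose coverage count is not a power of two incur ~1-ulp
rounding in the mean).

### Normalization

One global (mean, std) pair is pooled over *all* entries of all training
patches of both orientations (population convention), so the two latent
spaces share a scale. Because the decoder is a logistic sigmoid with range
(0, 1) while standardized data are not, the standardized training range is
then mapped linearly onto [0.1, 0.9]. Both steps are exactly invertible;
the round trip is tested to 1e-10.

### Sparse autoencoder

Each orientation has one single-hidden-layer autoencoder with logistic
sigmoid on both layers:

    z = σ(W₁x + b₁),  x̂ = σ(W₂z + b₂)

trained with the sparse mean-square-error loss

    L = (1/n) Σᵢ ‖xᵢ − x̂ᵢ‖² + β Σⱼ KL(ρ ‖ ρ̂ⱼ) + λ (‖W₁‖²F + ‖W₂‖²F)

where ρ̂ⱼ is the mean activation of hidden unit *j* over the batch,
KL(ρ‖ρ̂) = ρ ln(ρ/ρ̂) + (1−ρ) ln((1−ρ)/(1−ρ̂)), β = 1, ρ = 0.05 and
λ = 0.001 by default. The reconstruction term sums squared error over the
1024 patch entries and averages over patches — the convention of the
MATLAB-family sparse autoencoder this loss is modelled on, and the scale at
which the default learning rate of 1e-3 is effective. ρ̂ is clamped to
[1e-8, 1−1e-8] (with a warning) when a unit saturates. Analytic gradients
are verified against central finite differences to <1e-5 relative error.

The per-patch anomaly score is deliberately different from the training
loss: it is the mean *absolute* (l1) deviation between a patch and its
reconstruction. The squared error drives optimization; the l1 residual
scores anomalies.

**Hyperparameters.** Hidden width ∈ {64, 128, 256} (default 128; the
acceptance experiments use 64); β = 1 and λ = 0.001 are the toolbox
defaults; ρ = 0.05 is the sparse-autoencoder toolbox convention (no
published value exists for it). Two independent primary models are trained
(horizontal, vertical) with per-network seeds derived from one master seed.

**Optimizers.** `TrainConfig.algorithm` selects:

* `"scg"` (default): full-batch scaled conjugate gradient (Møller's
  algorithm) — the trainer used by the toolbox family this model follows.
  A CG method with a Levenberg-Marquardt-style scale replacing the line
  search; deterministic, no optimizer hyperparameters. `max_epochs` bounds
  the iterations (200 in the desk-scale experiments, 4000 at full scale).
* `"sgd"`: minibatch SGD, batch 256, classical momentum 0.9 (set 0 for
  plain SGD), initial learning rate 1e-3 halved every `max_epochs/4`
  epochs. Kept as the classical stochastic alternative; at
  desk-scale budgets it underfits relative to SCG (patch MSE ~21 vs ~7
  after 200 epochs/iterations on identical data), which is why it is not
  the default.

**Initialization.** Weights uniform ±1/√fan_in (seeded). Biases start
statistically neutral: the decoder bias at logit of the per-feature
training mean and the encoder bias at logit(ρ), so initial reconstructions
match the data mean and the KL term starts near zero.

### Auxiliary encoder and SVD latent fusion

A third autoencoder of the same architecture runs on the concatenated
per-anchor latent pairs [z_h ‖ z_v]; its latents Z′ supplement the primary
latents, and the mean l1 distance between z_h and z_v is reported as the
alignment loss (requires equal latent widths). The stacked matrix
F = [Z_h | Z_v | Z′] is column-centered and truncated by SVD; by
Eckart–Young this is the least-squares-optimal fixed-rank representation.
The rank is either fixed or chosen as the smallest r whose retained
squared-singular-value energy reaches a threshold (default 0.95).

Two bases are supported (`FusionConfig.basis`):

* `"corpus"` (default): the basis is fitted once on the *training* latents;
  at inference, a test image's latents are projected onto it. Directions of
  variation absent from normal training appearance are thereby removed —
  this is the anomaly-suppression mechanism. A per-image SVD can instead
  retain a strong anomaly's own high-variance directions, which defeats the
  purpose; it remains available as `"image"`.
* Ablation switches `enable_aux` / `enable_svd` disable each stage for
  controlled comparisons.

The overall training objective is reported as the plain sum of the stage
losses (two encoder sparse-MSE losses, two decoder reconstruction losses,
the auxiliary encoder loss, the SVD truncation error √Σ_{i>r} σᵢ², and the
l1 image reconstruction loss); the sum is diagnostic — stages are trained
sequentially, not jointly, and no gradient flows through the SVD.

### Reconstruction and segmentation

Inference per image: extract → normalize → encode (h, v) → auxiliary
encode → fuse/project latents → decode (h, v) → denormalize → reassemble
each orientation → average the two reassembled images → clip to [0, 1].

Candidate anomaly pixels come from binarization and image subtraction, in
one of three modes:

* `"residual"` (default): subtract the reconstruction from the input and
  binarize the absolute difference. The binarization level is calibrated on
  the normal training corpus — mean + 3·std of the pooled within-brain
  training residuals (the σ-multiplier is configurable; 2.5–3.5 behave
  equivalently on the packaged phantoms) — falling back to the difference
  image's own mean grey level when no calibration exists.
* `"xor"` / `"bright"`: binarize input and reconstruction separately at
  their mean grey levels (within the brain mask) and take the class-map
  disagreement, or only input-bright/reconstruction-dark pixels.

The default was chosen by an oracle experiment: with a *perfect* normal
reconstruction (the identical phantom regenerated without anomalies), the
class-map XOR reading attains mean DSC ≈ 0.5 on the packaged phantoms —
an anomaly overlying bright tissue never flips its mean-threshold class —
while subtract-then-binarize attains DSC 1.0. Likewise, a per-image mean
threshold on the residual is scale-free and marks ~1/3 of any *normal*
image; the corpus-calibrated level is what makes the false-positive rate
meaningful. Both alternatives remain implemented and tested.

Before thresholding, the brain mask is eroded by 6 px (configurable):
reconstruction error concentrates in a thin rim at the skull-stripping
boundary (ring 99th-percentile residual ≈ 0.44 vs ≈ 0.16 in the interior
on the packaged phantoms), and excluding the rim mirrors common practice
after skull stripping. Metric evaluation still uses the full brain mask.

Post-processing: 8-connected component labelling (4-connectivity
available), removal of components below `min_area` (64 px at 256×256,
scaled with image area), then hole filling of the survivors — in that
order, so filled specks cannot sneak past the area filter. The final mask
is monotone in `min_area` and idempotent under re-post-processing.

### Metrics

DSC = 2TP/(FP + 2TP + FN), PPV = TP/(TP + FP), Sensitivity = TP/(TP + FN),
computed over the brain mask. When both masks are empty DSC is defined as
1.0 (needed for all-normal images); PPV/Sensitivity are NaN with a warning.
Pixel-score AUC uses the Mann–Whitney rank statistic with midrank ties,
identical to trapezoidal ROC integration (tested to 1e-10).

## Synthetic phantoms

The generator emulates skull-stripped 2D brain MRI with exactly the
properties this method depends on:

* **Shared anatomy.** All images drawn with one `anatomy_seed` share a
  smooth two-class tissue template (levels base ± contrast/2, default
  0.5 ± 0.09, partial-volume blurred) plus a fine shared texture — a
  learnable normal appearance, as across real subjects of one modality.
  Each image adds its own small smooth intensity variation (std 0.02), the
  unlearnable inter-subject component.
* **Bimodal tissue intensity**, which is what makes mean-grey-level
  binarization meaningful on real T1-like images.
* **Compact bright anomalies**: jittered filled ellipses (semi-axis 8–16 px
  at 256², default two per image) offset by +0.3 with re-rolled local
  texture, placed non-overlapping and fully inside the brain; pixel-level
  ground truth is returned. An optional bright skull annulus (off by
  default) exists to reproduce the known skull/tumor confusion failure
  mode.

Identical specs (including seeds) give bit-identical images; corpus
generation derives per-image seeds as corpus seed + index.

What the phantoms do **not** model: real anatomical geometry (gyri,
ventricles), acquisition noise and bias fields (deliberately excluded —
noise handling is deliberately out of scope), multi-contrast
acquisition, 3D continuity, and tumor heterogeneity (rim enhancement,
edema). Passing the packaged experiments therefore demonstrates that the
*mechanism* works — normal appearance is learned, anomalies yield elevated
residuals, and the segmentation recovers them — not that the published
clinical accuracy would be reproduced on BRATS/HCP data.

## Experiment sizes

The packaged experiments are desk-scale: 10 normal training phantoms at
256×256 (≈2,560 patches per orientation), hidden width 64, 200 SCG
iterations, evaluated on 5 held-out anomalous and 5 held-out normal
phantoms; the fusion ablation uses 128² phantoms, hidden width 32, 80
iterations, paired over 5 seeds. Full-scale settings (hidden 128–256,
4,000 epochs, ~195k patches) are configuration, not code, changes.

## Numerical choices and degenerate inputs

* Zero pooled patch variance (constant training data) raises a
  degenerate-data error; saturated mean activations are clamped in the KL
  term with a warning; non-finite training loss aborts with the epoch and
  step size.
* Latents reconstructed by fusion inversion/projection are clipped to
  (0, 1) at 1e-7 for sigmoid-decoder compatibility.
* An all-constant latent matrix cannot be fused (degenerate error); a
  requested rank above min(n, width) raises a rank error.
* Ties in AUC scores use midranks; component labelling defaults to
  8-connectivity; flattening is row-major with 0-based (row, col)
  coordinates and half-open windows.
* Serialization uses one-line JSON headers plus raw float64 blocks;
  save → load round trips are bit-exact.

## Known limitations

* The phantom's shared-anatomy assumption is stronger than inter-subject
  similarity in real cohorts; real-data performance depends on registration
  quality and anatomical variability that the phantoms idealize.
* The corpus-calibrated residual threshold assumes the training corpus is
  representative of test-time normal appearance; domain shift would
  require recalibration.
* Stagewise training only; no end-to-end gradient through the SVD.
* 2D slices only; anomalies darker than both tissue classes are detected
  by the residual (and `"xor"`) modes but not by `"bright"`.
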