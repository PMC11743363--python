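# Methods

## Proxy attention

The operator mediates query–key interaction through two small agent sets
pooled from the N spatial tokens (laid out on a rows×cols patch grid):

1. **Global path.** Agents A₁ = pool(Q) aggregate over all keys/values,
   `V_A = softmax(A₁Kᵀ/√d) V`, then the queries broadcast over the
   agents, `O = softmax(QA₁ᵀ/√d) V_A`. Both softmax factors are
   row-stochastic, so every output row is a convex combination of value
   rows.
2. **Local path.** A second agent set A₂ = pool(K) serves as keys for a
   direct attention `softmax(QA₂ᵀ/√d) V_pool`, added elementwise to the
   global-path output. As written the local step is dimensionally
   inconsistent (n_a keys against N values); we resolve it by pooling V
   with the same operator and target grid as A₂, which preserves the
   local-feature intent while making the product well defined.

Cost: aggregation, broadcast and local path are each two N×n_a×d matrix
products, 6·N·n_a·d multiplies total versus 2·N²·d for full softmax
attention; pooling cost is excluded from the model by convention.

Design choices in the operator, all open in the source description:

- **Pooling** is per-embedding-dimension max (mean available) over the
  2-D patch grid, not the flat raster sequence — 1-D windows would mix
  spatially distant rows. Window boundaries use the even partition
  `floor(i·r/t)`: identical to ceil-division windows when the target
  divides the source, and never empty otherwise (literal ceil windows
  can produce an empty trailing window, e.g. 4 rows into 3 groups).
  Max-pool ties are resolved by value, so tie order is irrelevant; in
  the backward pass tied positions split the gradient evenly.
- **Path combination** is a literal elementwise sum; no learned gate, no
  ½ averaging.
- **Scale** is 1/√d_head in both steps of both paths.
- **Bias.** A learnable additive logit matrix per encoder block and step
  (n_a×(N+1) for aggregation, (N+1)×n_a for broadcast), zero-initialized
  and shared across heads; both are independently switchable and are
  bilinearly resampled along the token axis when the input resolution
  changes. Whether the bias belongs to the aggregation step, the
  broadcast step, or both was an open design point; implementing both
  with zero init makes either ablation a no-op at initialization.
- **Class token** is excluded from pooling and participates unchanged:
  the aggregation step attends over all N+1 keys/values, and the local
  path's pooled key/value sets get the class row prepended.
- **Softmax** subtracts the rowwise maximum before exponentiation.

A loop-based dense reference (`dense_oracle`, N ≤ 256) materializes every
intermediate with explicit per-element Python loops; the vectorized
operator must match it to 1e-5 max absolute difference, and does to
~1e-15 in practice.

## Backbone

Standard ViT layout: non-overlapping patches (default 16×16 at 256×256,
hence N = 256), linear embedding, learnable class token, learnable
position embeddings, E pre-norm residual encoder blocks
(`x += MHA(LN(x)); x += MLP(LN(x))`), final LayerNorm, linear head,
softmax. Defaults follow the reference recipe (patch 16, depth 12,
256×256, 5 or 2 classes); E and H are freely configurable for the
ablation grid (E, H ∈ {2,4,8}).

- Pre-norm ordering was chosen because it is the stable convention for
  deep ViTs; the source description shows Norm blocks without fixing
  their position relative to the residuals.
- Norm = LayerNorm over the embedding dimension; MLP = two linear layers
  with exact (erf-based) GELU and hidden width 4·d_model.
- The classification head reads the class token by default; a
  mean-pooled-patch head is available behind `mean_pool_head` (see
  "Desk-scale settings").
- Position embeddings are bilinearly resampled (align-corners
  convention) when the input resolution changes; the class-token row
  passes through unchanged. The resampling is the identity on the
  source grid and preserves constant fields exactly.
- Initialization: truncated normal (σ = 0.02, clipped at ±2σ) for
  projections, zeros for biases, ones for norm gains.
- Inputs are standardized per channel with mean/std fitted on the
  training split and stored in the checkpoint. This is the usual ViT
  preprocessing; without it the all-positive pixel range makes
  short-budget optimization needlessly hard.
- Loss: categorical negative log-likelihood −Σᵢ yᵢ log y′ᵢ with
  predictions clipped to [1e-12, 1]. The printed form of this objective
  in the source description lacks the minus sign and is labelled
  "binary" while summing over C classes; we implement the standard
  positive, minimized categorical form.

Everything runs on an in-repo reverse-mode autodiff engine over float64
NumPy arrays (`proxyvit.autodiff`): broadcasting arithmetic, batched
matmul, stable softmax, GELU, reductions, grid pooling, and an Adam
optimizer (β = (0.9, 0.999), weight decay 0). Engine gradients are
validated against central finite differences operator-by-operator and
through the full attention operator (relative error < 1e-3 required,
~1e-10 observed).

## Metrics

Accuracy, sensitivity, specificity and precision are exact confusion-
count ratios; F1 is the harmonic mean 2PS/(P+S). Zero denominators yield
NaN with a `RuntimeWarning`, never a silent 0. G-mean is √(a·b) of a
rate pair: published screening tables use it inconsistently — some match
√(precision·sensitivity), others √(sensitivity·specificity) — so both
pairs are exposed (`g_mean_ps`, `g_mean_ss`) and neither is declared
canonical. AUC is the tie-corrected Mann–Whitney rank statistic (ties
count ½; multi-class is the unweighted one-vs-rest mean). Weighted F1 is
the support-weighted mean of per-class one-vs-rest F1 (undefined classes
contribute 0 with a warning). Weighted kappa uses quadratic distance
weights w_ij = (i−j)²/(C−1)² by default — the ordinal-grading
convention — with linear weights behind a flag; expected agreement comes
from the marginal product. Display rounding is half-up to one decimal in
percent, matching published table formatting.

## Synthetic data

`synthetic.generate_image` renders a fundus surrogate: reddish-orange
disc (circular field of view; everything outside the inscribed disc is
exactly black), low-frequency intensity noise (coarse uniform field,
bilinearly upsampled, amplitude 0.08), 2–6 dark quadratic-Bézier vessel
strokes, and three lesion surrogates whose counts are Poisson with
grade-proportional rates: bright dots (λ = 2·grade, radius 1–2 px,
+0.4 luminance), yellow blobs (λ = 1.5·grade, radius 2–5 px, RGB shift
(+0.15, +0.25, −0.10)), dark blobs (λ = 1·max(0, grade−1), radius
2–5 px, −0.5 luminance). Grade 0 images contain no lesions by
construction; expected burden is non-decreasing in grade. Default class
probabilities follow the APTOS2019 grade distribution
(1805/370/999/193/295 of 3662). Each image draws from an independent
generator seeded by (dataset seed, image index), so generation is
reproducible and order-independent; written datasets
(`images/<id>.png` + `labels.csv`) are byte-identical across reruns.

What passing tests show — and do not. The generator proves the pipeline
end-to-end: labels are learnable, determinism holds, metrics and
saliency run. It does not claim photographic realism: no vessel-tree
anatomy, no optic disc or macula, no camera artefacts, no inter-grader
label noise. Results on it say nothing quantitative about clinical
performance.

## Pipeline

- **Folds:** deterministic stratified k-fold (shuffled, seeded); if the
  smallest class has fewer than k members, plain shuffled folds with a
  warning.
- **Augmentation:** rotation uniform in ±20°, horizontal/vertical flips
  with p = 0.5, central zoom in [0.9, 1.1]; output re-masked to the
  circular field of view and clipped to [0, 1]; labels never change.
  Ranges are config-overridable defaults.
- **Minority emphasis:** instance sampling weights (1/f_c)^α, with α
  solved (Brent) so the minority class is oversampled by the requested
  factor relative to its natural frequency; the attainable maximum is
  1/f_min and larger requests are clamped with a warning. Sampled
  instances are augmented on the fly.
- **Training:** Adam (lr default 1e-5 per the reference recipe, epochs
  default 500), per-epoch train/val loss and accuracy log, best
  checkpoint by validation accuracy, non-finite loss aborts with a
  diagnostic. Checkpoints are an .npz weight file plus a JSON config
  sidecar; loading verifies shapes.
- **Grad-CAM:** target activations are an encoder block's multi-head
  attention output on the patch tokens (class token dropped), default
  the last block; channel weights are the spatial mean of the gradient
  of the target-class log-probability; weighted sum, ReLU, bilinear
  upsampling to image size, min-max normalization. A constant map
  (common with the mean-pooled head, whose patch gradients are nearly
  uniform) returns all zeros with a warning; the class-token head gives
  more structured maps.

Determinism: all randomness (label draws, image rendering, fold
shuffling, batch sampling, augmentation, weight init) flows from
user-provided seeds through `numpy` `SeedSequence` streams; identical
config + seed reproduces splits, batches, weights and metrics bit-for-
bit.

## Desk-scale settings

Unit tests and the acceptance script exercise a deliberately small
configuration chosen to keep a full run in seconds on one CPU: 32×32
images, patch 8 (16 tokens), d = 32, E = H = 2, 300 images (200 train /
100 held-out), 5 epochs, batch 8. At this budget (125 optimizer steps)
two settings matter and are the package's own defaults for desk-scale
runs: per-channel input standardization (above) and the mean-pooled
head with Adam lr 3e-3 — the class-token head needs substantially more
steps before its readout becomes input-sensitive, and the reference
recipe's lr 1e-5 is matched to 500-epoch training, not 5. With these,
held-out accuracy beats the majority baseline by 15–35 points across
generator seeds.

## Known limitations

- No GPU path and float64 only: full-scale (256×256, depth-12,
  500-epoch) training is supported in form but not in practice; the
  recipe is exercised at toy scale.
- The local path's value pooling is one reasonable resolution of an
  underdetermined operator description; alternatives (e.g. letting A₂
  aggregate over K, V first) are not implemented.
- Dropout (inverted, on both sub-layer outputs, training only) defaults
  to 0 and is untouched by the desk-scale runs.
- Confidence intervals for metrics are out of scope.
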