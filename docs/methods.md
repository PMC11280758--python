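# Methods

## Problem and model

Tongue-coating segmentation is a binary, pixel-wise classification task on
RGB tongue photographs: each pixel belongs to the coating (positive class)
or the background/tongue body.  What makes it hard is not localization but
boundary ambiguity — the coating is close in colour to the tongue body, its
boundary is fuzzy, and clinically relevant structure is irregular (cracks
through the coating, scalloped tooth-marked body edges, peeled patches).

The network is a hybrid convolution/transformer encoder–decoder:

1. **Encoder.**  A residual bottleneck stem (ResNet-50 geometry: stem at
   stride 2, three bottleneck stages at strides 4/8/16; a fourth stage at
   stride 32 in the optional five-level configuration) extracts a feature
   pyramid.  The deepest map is flattened to one token per spatial cell
   (1×1 patches), given learned position embeddings, and processed by a
   pre-norm ViT-style self-attention stack, capturing long-range
   relationships between tongue regions.  With 224 px inputs the token grid
   is 14×14 (four levels) or 7×7 (five levels).  The three shallowest maps
   (strides 2/4/8, channels 64/256/512 at full width) are the skip
   connections.

2. **Subtraction feature pyramid (SFP).**  Each skip is reduced to 64
   channels by a CBR block (3×3 conv → batch norm → ReLU).  Subtraction
   units `SU(LA, LB) = CBR(|LA − LB|)` are applied to adjacent levels in a
   two-round triangular pyramid (two first-round maps, one second-round
   map), and each level subtracts its accumulated difference sum under a
   learnable scalar: `out_l = F_l − α_l·D_l` (an additive ⊕ mode exists for
   ablation).  `D_l` sums every difference map involving level *l*,
   bilinearly resampled to that level's resolution; the coarser operand of
   each SU is bilinearly upsampled to the finer one's size.  The intent is
   to strip cross-level redundancy from the skips so they carry
   level-specific spatial detail; semantic context is the transformer's
   job.

3. **Visual regional enhancer (VRE).**  Each SFP output passes through two
   learnable-visual-center (LVC) units in series (parallel and single-LVC
   arrangements are config options).  An LVC holds K codewords `b_k` with
   smoothing factors `s_k`; pixels are softly assigned by
   `a_ik = softmax_k(−s_k‖x_i−b_k‖²)`, the weighted residuals
   `a_ik (x_i − b_k)` are batch-normalized, rectified and averaged over the
   pixel axis (the BRM step), summed over codewords, linearly mapped and
   squashed by a sigmoid into per-channel gates `w ∈ (0,1)^C` that scale
   the input map.  A final 1×1 convolution projects each level back to its
   decoder width (512/256/64, deep→shallow).

4. **Decoder.**  From the transformer output: a CBR bridge, then 2×
   upsampling stages (transposed convolution by default, bilinear
   optionally), each concatenating the matching skip and applying two CBR
   blocks; a final 2× stage and a 1×1 head give two logit planes at input
   resolution.  Ties in the argmax resolve to background.

## Objective

`Loss = w1·CE + w2·Dice + w3·Focal` with trainable mixing weights
initialised to (0.3, 0.4, 0.3).  CE treats pixels uniformly; soft Dice
(smoothing 1.0, computed on the coating probability plane only) counters
class imbalance; focal loss (γ = 2, no α-balancing by default) concentrates
training on hard boundary pixels.

Because the total is *linear* in the weights, each `w_i` receives exactly
its component's value as gradient.  Component losses are non-negative, so
raw weights decrease monotonically under gradient descent, cross zero, and
the objective then becomes unbounded below (we measured the total reaching
−924 in 200 steps, with the segmentation destroyed).  The default
parametrization therefore maps three free logits through a softmax scaled
to the initial sum, keeping the mixture a convex combination that starts
exactly at (0.3, 0.4, 0.3) and remains fully trainable.  The raw linear
form stays available (`LossWeights(constraint="none")`) and is what the
loss-algebra tests use, since the identity ∂Loss/∂w_i = component_i is
literal only there.

## Training protocol

Adam with learning rate 0.01, β₁ = 0.9 (the protocol's "momentum"),
β₂ = 0.999, weight decay 1e-4, batch size 6, no learning-rate schedule;
224×224 inputs normalized to roughly [−1, 1] ((x/255 − 0.5)/0.5).  Training
folds are augmented with horizontal flips and random rotations up to ±25°
(the rotation range is our choice, config-exposed); masks are rotated with
nearest-neighbour interpolation and stay hard binary.  Five-fold
cross-validation partitions sample ids by a seeded shuffle into folds whose
sizes differ by at most one; fold metrics are micro-pooled over pixels by
default (per-image macro averaging is a flag), and across-fold standard
deviations use the population convention (divide by k).

After the optimization loop, `Trainer.fit` re-estimates every batch-norm
layer's running statistics over the training data (momentum 1/k on the k-th
forward pass, i.e. an exact average of batch statistics; no parameter
updates).  Without this, evaluation-mode normalization lags the
fast-moving weights: in the overfitting experiment the gap was dice 0.9997
(training mode) vs 0.92 (evaluation mode), and recalibration removes it.

Pretrained encoder weights are supported only as a local checkpoint path
(`pretrained_path`); all tests and reported numbers use random
initialization.

## Synthetic data

The generator emulates the structure of clinical tongue photographs
without reproducing them: a vertically elongated ellipse (the tongue body)
on a dark background; a coating region formed by thresholding
low-frequency Gaussian noise inside the rim-eroded body, with the
threshold chosen so the coating covers a target fraction of the body area
(default 0.6, hit to within ±0.1 before removals); body and coating
colours are close (pinkish body, pale coating) with per-channel jitter;
optional cracks (random walks cut through the coating as background-class
curves), peel patches (elliptical deletions) and tooth marks (inward
sinusoidal scallops of the body rim); Gaussian blur of the colour image
softens all boundaries while the label stays hard binary — the ambiguity
lives in the pixels, as it does in annotated clinical data.  Every sample
derives from `(spec, seed, index)` through an independent RNG stream, so
datasets are bit-reproducible and order-independent.

What it does not emulate: real coating texture and papillae, specular
highlights, saliva, illumination variation, capture-device colour calibration,
or anatomical variability.  Passing tests therefore demonstrate that the
pipeline is correct and trainable, not that the reported clinical accuracy
transfers.

## Numerical and design choices

* **Autodiff engine.**  All networks run on an in-package reverse-mode
  autodiff engine over numpy arrays (`coatseg.nn`): conv / transposed conv
  via im2col–col2im adjoint pairs, a fused standardization primitive with
  the closed-form batch-norm adjoint, bilinear resizing as a separable
  linear operator (its transpose is the gradient), softmax/log-softmax with
  analytic backward.  Gradients are verified against central finite
  differences and closed forms in the test suite.  Interior gradients are
  freed during backpropagation unless a tensor is explicitly retained
  (GradCAM retains the last convolutional activation).
* **SFP readings.**  "Level by level, many times" is realized as the
  minimal triangular pyramid over three skips (two rounds).  Whether D_l
  should include only round-1 differences is not determinate; we include
  the round-2 map in every level's sum and the structure is localized in
  one function (`SFP.sfp_forward`) should the other reading be wanted.
  α_l is initialised to 0, making the module an exact identity at step 0 —
  training starts from vanilla skip connections, which also gives a crisp
  testable property.  Each SU owns its CBR parameters; one scalar α per
  level.
* **LVC readings.**  K = 64 codewords by default (8 in the tiny config);
  codewords ~ N(0, 1/√C), factors start at 1.  The BRM "mean" is taken
  over the N = H·W pixel axis after a batch norm shared across codewords;
  the per-codeword C-vectors are then summed over K.  The skip stream is
  64-channel after SFP while the decoder consumes 512/256/64, so the
  enhancer ends in a 1×1 restoring projection; in the SFP-only ablation a
  bare 1×1 convolution plays that role, keeping decoder geometry identical
  across ablations (and parameter counts strictly increasing
  baseline → +SFP → +SFP+VRE).
* **Zero-denominator metrics.**  A ratio 0/0 scores 1.0 (empty prediction
  vs empty truth), anything/0 otherwise 0.0.
* **Determinism.**  All randomness flows from explicit
  `numpy.random.Generator` streams seeded from configuration; there is no
  global RNG use, so generate → train → evaluate is bit-reproducible.

## Problem sizes used in tests and the acceptance script

The oracle and formula checks run at small tensor sizes (N ≤ 64, C ≤ 16,
K ≤ 8 for the codebook; three-level pyramids at 16/8/4 px).  The
trainability experiment uses the tiny configuration (stem 8, stage widths
4/8/16/32, one bottleneck per stage, 1 transformer layer, hidden 32,
decoder 32/16/8, K = 8) on eight 64×64 synthetic images for 200 full-batch
Adam steps; the determinism experiment uses four 32×32 images for 10 steps.
These sizes were chosen so the whole suite runs on a single CPU core;
the architecture checks still exercise the full 224 px geometry.

## Known limitations

* The engine is single-threaded numpy; full-size (ResNet-50 + ViT-Base)
  training is out of reach — the default configuration is provided for
  completeness and geometry checks, not desk-scale training.
* The "region-dependent" flavour of the Dice loss cited in the source
  literature is not reproducible from its description; standard soft Dice
  is implemented.
* Colour statistics of the synthetic tongues are plausible, not estimated
  from data; they are fully config-exposed.
* GradCAM uses the last decoder convolution block; other layers are not
  currently exposed as CAM targets.
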