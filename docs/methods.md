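# Methods

## The model

`dualseg` implements a dual-branch encoder-decoder for 2D medical image
segmentation.  Two encoders look at the same image:

* a **CNN stream** of three hierarchical stages (output strides 4, 8, 16)
  built from deep-split blocks: the input is divided into `K` channel
  groups, each refined by strided conv+BN+ReLU blocks, the groups are
  reweighted by a softmax **fusion attention** across branches, passed
  through a bank of squeeze-excitation channel gates, and re-projected to
  the stage width by a 1x1 convolution;
* a **Transformer stream** with the same pyramid geometry, whose blocks sum
  three attention operators before a pre-norm MLP:
  `Y = Z + MLP(LN(Z))`, `Z = Y_E + lambda1 * Y_S + lambda2 * Y_C`, with
  `lambda1 = 0.6`, `lambda2 = 0.4`:
  * **efficient self-attention** `Y_E`: single-head scaled-dot-product
    attention whose key and value sequences are reshaped from `N` tokens to
    `N/R` (each carrying `C*R` features) and linearly mapped back to `C`,
    shrinking the attention matrix to `N x N/R`;
  * **spatial self-attention** `Y_S`: non-overlapping window partition
    (symmetric zero padding), multi-head attention with scale `1/sqrt(d)`
    and a learnable relative-position bias table of size `(2w-1)^2` per
    head (zero-initialized);
  * **channel self-attention** `Y_C`: attention across channels (tokens
    become the reduction axis) with a learnable per-head temperature
    `alpha`, initialized to `sqrt(d_head)` and clamped at `1e-4`; the
    softmax normalizes over the query-channel axis, so every output channel
    is a convex mixture of value channels.
  The spatial and channel operators are each fused with a depth-wise 3x3
  **local branch** through two gated interactions: a spatial gate
  (`sigmoid` of a two-layer point-wise conv bottleneck, ratio 8) and a
  channel gate (`sigmoid` of a two-FC bottleneck on the pooled map).

At every decoder stage the two skip maps are fused by **directional
attention**: four directional poolings (row means, column maxima, and the
two 90-degree-rotation-derived reversed means) are resampled to a common
length, concatenated as channels, mixed by 1x1 conv + BN + hard-swish, and
split into two sigmoid gate vectors `s_h` (one per row) and `s_w` (one per
column).  Their broadcast product is a rank-1 spatial attention map `A`
that multiplies the fused features pixel-wise.  The refined skip joins the
upsampled decoder state, is processed by two parallel conv paths, and the
paths are merged by **bidirectional cross-attention** (queries of each path
attend keys/values of the other, concat, 1x1 projection, residual from the
path average).  A 1x1 head on the stride-4 decoder output plus bilinear
x4 upsampling produces logits at input resolution.

Ablation toggles expose the module ladder used to attribute performance:
plain U-shaped CNN -> +deep-split conv -> +transformer branch ->
+multi-scale skips -> +directional fusion -> +cross-attention.

## Numerical backend

The network is built on numpy + HIPS `autograd`: parameters live in nested
dicts of float32 arrays, convolutions are im2col gathers followed by BLAS
matmuls, and training uses reverse-mode differentiation of the whole loss
with a hand-rolled Adam.  Mutable batch-norm running statistics (momentum
0.1, eps 1e-5) are updated outside the autograd tape.  `tanh`-form sigmoid
and a clipped-tanh GELU avoid overflow in saturated gates.  Everything is
deterministic given the seeds; two single-threaded runs with the same seed
produce bit-identical histories and predictions.

## Design choices at genuinely open points

* **Split semantics.**  The deep-split block divides features into channel
  groups (not spatial tiles); stage resolution is reduced by strided convs
  (two stride-2 blocks in the stem, one per later stage).
* **Fusion attention scoring.**  Each branch's global-average-pooled
  context is scored by a *shared* two-FC bottleneck (reduce ratio 4) and
  the scores are softmax-normalized across branches per channel.  The
  shared head makes the operator permutation-equivariant: identical
  branches get exactly `1/K`.  GELU is used in this bottleneck (and the SE
  gates) rather than ReLU: at desk-scale widths a ReLU bottleneck can be
  fully dead at initialization, which would leave its weights untrainable
  and break the model's all-parameters-receive-gradient contract.
* **Saliency concat.**  After fusion, the map is split into `eq3_k = 2`
  channel groups, each passed through `eq3_n = 2` independent SE gates; the
  four saliency maps are concatenated and mixed by a 1x1 conv to the stage
  width.  The encoder split count (`split_k = 4`) and the saliency-concat
  counts are independent configuration fields.
* **Rotated poolings.**  Rotating a map by 90/270 degrees and averaging
  along a fixed direction is, read back in the source frame, an
  index-reversed row/column mean; implemented exactly that way so the
  descriptor shapes `(B,C,H,1)` / `(B,C,1,W)` hold for any H, W (not only
  square maps).
* **ESA value reduction.**  The length reduction is applied to values as
  well as keys; with reduced keys alone the attention output would be
  dimensionally inconsistent.
* **Residual around the block MLP** (pre-norm) is added for trainability.
* **Cross-attention formulation and decoder wiring** are this package's
  own (the source architecture describes them only in prose): fused skip ->
  dual conv refinement -> bidirectional cross-attention merge; bottleneck =
  fused stage-3 features.
* **Loss.**  `0.5 * cross-entropy + 0.5 * (1 - soft foreground Dice)`.
* **"Weight growth rate 0.0001"** in the training protocol is read as an
  L2 weight decay of 1e-4, applied inside Adam to matrix/tensor weights
  (not to biases or normalization parameters).
* **Surface metrics.**  Boundaries are mask pixels with a 4-neighbor
  outside the mask; distances use an exact Euclidean distance transform
  with anisotropic spacing.  The maximum symmetric surface distance is the
  symmetric boundary Hausdorff (max of the two directed maxima).  Both
  masks empty gives Dice = IoU = 1; one-sided emptiness yields NaN with a
  warning and the class is dropped from macro averages.

## Synthetic fixtures

The generator emulates the statistical structure the method targets, not
its photometric realism: a large organ-like ellipse (class 1), 1-2 small
lesion-like ellipses (class 2, semi-major axis 4-6 px, pixel area below
`pi * 6^2`), optionally a second organ class touching the first (shared
boundary), class-wise intensities with per-object jitter, Gaussian boundary
blur and additive Gaussian noise.  The mask is the pre-blur geometry.  The
`easy` preset (3 classes, high contrast: background 0.15, organ 0.55,
lesion 0.9; blur sigma 0.7 px; noise sigma 0.03) defines the desk-scale
training conditions; `hard` adds touching organ pairs, low lesion contrast
(0.65 vs 0.55), blur 1.5 and noise 0.08.  What passing tests on these
fixtures show is that the architecture, optimization and evaluation
pipeline are correct and can recover known geometry; they say nothing
about performance on real CT/dermoscopy/X-ray appearance, anatomy priors,
or inter-observer label noise.

## Problem sizes

Desk-scale defaults keep every computation single-core friendly: the
reduced preset uses widths (16, 32, 64), one transformer block per stage,
window 4, reduction R=2, 64x64 images; the end-to-end recovery run trains
on 200 images (50 validation) for at most 30 epochs with early stopping
once validation macro Dice reaches 0.82.  Full-scale defaults (widths
(32, 64, 128), two blocks per stage, window 7, R=4, batch 16, 200 epochs,
Adam lr 3e-4) mirror the published protocol and are exposed in the YAML
configuration.

## Known limitations

* 2D only; volumes are consumed as axial slices (RAS-canonicalized).
* No shifted windows, no learning-rate schedule (constant lr), no deep
  supervision, no test-time augmentation.
* Window attention attends into zero-padding when H or W is not a multiple
  of the window edge (no attention masking).
* The numpy backend is orders of magnitude slower than a GPU framework;
  full-resolution (512x512) training is out of scope.
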