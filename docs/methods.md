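# Methods

## The model

`msa3d` classifies a 3D scalar volume (the intended use case is
T1-weighted structural brain MRI on a fixed 2 mm grid, 91 × 101 × 91
voxels) by fusing two feature streams:

**Multi-view slice subnetworks (MVSSN).** The volume is decomposed into
its sagittal (x), coronal (y) and axial (z) slice stacks, with
M_x + M_y + M_z slices in total. Each 2D slice is mapped to a C = 8
dimensional embedding by a small CNN: three blocks of
conv 3×3 (stride 2, padding 1) → batch-norm → ReLU → max-pool 2×2, with
8/32/64 channels, followed by global average pooling and two fully
connected layers 64 → 128 → 8. Subnets are *independent* per slice by
default (`weight_sharing="independent"`); a `per_view` regime shares one
subnet per view, which is two orders of magnitude smaller at the full
grid and lets all slices of a view pass through as a single batch.

**Slice attention (SAM).** Per view, the embedding matrix
I ∈ R^(M_k×C) yields affinities

    a_ij = exp(I_i · I_j) / Σ_i' exp(I_i' · I_j),

a softmax over the *contributing* index i, so every column of
A ∈ R^(M_k×M_k) sums to 1 (column-stochastic). There are no learned
query/key projections and no 1/√C temperature — the affinity is the raw
embedding dot product. The attended features carry a learnable residual
gate β per view, initialised to 0:

    Ĩ_j = β Σ_i a_ij I_i + I_j .

At β = 0 the module is an exact identity, so the attended model and its
attention-free ablation (MS3D, `use_sam=False`) produce bitwise-identical
outputs for identical weights — a property the tests assert exactly.

**Subject-level 3D CNN (S3D-CNN).** Four blocks of
conv3d → batch-norm → ReLU → max-pool3d with channels 32/128/256/512
(3×3×3 stride-1 convs with 3×3×3 stride-2 pools; the last block uses a
2×2×2 stride-2 conv and a 5×5×5 stride-2 pool), closed by a 3D global
average pool giving a 512-wide subject feature. On the 91 × 101 × 91 grid
the spatial map reaches exactly 1×1×1 before the GAP.

**Fusion and loss.** The flattened attended slice features
((M_x+M_y+M_z)·C values) and the subject feature are concatenated and
classified by FC → ReLU → FC → softmax (hidden width 256). The training
loss is the macro-averaged cross-entropy

    L = −(1/C_cls) Σ_c (1/N) Σ_i [y_i = c] log p_i,c ,

which algebraically equals standard cross-entropy divided by C_cls on
*any* batch (the inner sum collapses); both variants are provided and
share gradients up to that constant.

## Training protocol

SGD with learning rate 0.01, weight decay 0.02, batch size 12, momentum 0
(configurable). Weight decay applies to convolution and FC weight
matrices only — not to biases, batch-norm affine parameters, or the
attention gates β (decaying β would fight its designed growth from 0).
Early stopping monitors a stratified 10% validation split with patience
10 and restores the best-validation weights. All randomness (weight
initialisation, splits, shuffles) derives from a single seed; repeated
runs are bitwise reproducible.

## Implementation notes

No deep-learning framework is used: the package carries a small
reverse-mode autograd engine on NumPy (`msa3d.nn`). Convolution is an
im2col gather (one strided copy per kernel offset) plus one BLAS matmul;
pooling records argmax indices for its backward pass; batch-norm is
composed from differentiable primitives. Gradients are validated against
central finite differences in float64, and the conv3d layer against an
explicit triple-loop reference and `scipy.ndimage.correlate`.

Numerical choices:

* model arithmetic is float32; the loss/metric reference functions are
  float64 (closed-form tests hold to 1e-9);
* softmaxes subtract the per-column maximum before exponentiation;
* the analysis-path `attention_scores` computes dot products by explicit
  multiply-reduce rather than BLAS matmul so identical embeddings give an
  exactly uniform 1/M matrix;
* max-pool windows larger than the incoming map are clipped to it
  (`allow_pool_clip`), letting the published architecture run on small
  phantom grids; with clipping disabled a shape error names the failing
  stage. Note the 4-block subject net still needs ≥ 2 voxels per axis at
  block 4, so very small grids (e.g. 12×14×12) require a 3-block variant;
* `resize_volume` uses align-corners linear interpolation
  (`scipy.ndimage.map_coordinates`), so corner voxels map exactly and a
  linear ramp resamples onto the exact interpolant;
* zero probability on a true class is clamped at 1e-12 with a warning;
* intensity normalisation z-scores the whole volume (constant volumes map
  to zeros); a brain-mask-aware variant belongs in the `preprocess` hook.

Preprocessing is intentionally a stand-in: AC–PC registration, skull
stripping and N3/N4 bias correction are jobs for dedicated neuroimaging
tools, expected to run offline; `preprocess(hook=...)` is the splice
point. The crop/z-score/resample chain here only reproduces the *shape*
of the published pipeline's output.

## The phantom world

`msa3d.phantoms` generates the test bed: an axis-aligned ellipsoidal
"brain" inscribed in the box (intensity 1 plus i.i.d. Gaussian texture,
noise_sd 0.05 by default; background exactly 0) in which class 1 carries
a multiplicative intensity reduction (effect_size 0.8 by default) inside
a smaller lesion ellipsoid (radii 3 voxels on the default 24 × 28 × 24
grid — the model grid's anisotropy at quarter scale). Lesion centres are
jittered ±2 voxels per axis across subjects, emulating modest anatomical
variability. Because the lesion geometry is known, the informative slice
set per view (union of centre ± radius over subjects) is exact ground
truth for attention and saliency checks. Containment of the lesion in the
brain is enforced with the conservative bound ‖normalised centre offset‖
+ max_k(r_k/R_k) ≤ 1.

What the phantoms do **not** emulate: cortical anatomy, spatially
correlated noise, scanner/site effects, deformation-style atrophy. A
green phantom test therefore establishes the *mechanics* of the method
(shapes, gradients, learnability, localization), not clinical
performance.

## Known limitations

* **Attention concentration under easy tasks.** With effect_size 0.8 the
  phantom task is separable within ~2 epochs; once the loss saturates,
  the residual gate β (gradient ∝ loss gradient) stays near 0 and the
  affinity matrix — which has no learnable parameters of its own — never
  comes under training pressure. Measured on lesioned test phantoms, the
  axial attention mass on informative slices then stays near (or below:
  darker lesion slices have *smaller* dot products) the uniform baseline
  rather than concentrating on them. Slice-attention filtering is a
  claim about hard, slowly-converging tasks; this synthetic world cannot
  reproduce it, and the corresponding end-to-end check is expected to
  fail by design of the world, not of the module (whose algebra is
  verified exactly).
* CPU-budget experiments use the `per_view` sharing regime and a narrow
  `SubjectNetConfig.desk_scale()` (16/32/64/128 channels); the published
  widths are verified separately at the printed grid.
* The conv/pool stack assumes single-channel input; multi-modal fusion is
  out of scope.
* Grad-CAM at desk scale taps a 2×2×2 block-3 map in the 3D branch, so
  volume saliency is very coarse (octant resolution) before upsampling.
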