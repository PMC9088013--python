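# msa3d

Fused 2D-slice-attention + 3D-CNN classification of volumetric brain
images, with a synthetic lesion-phantom simulator for end-to-end
validation on a laptop-scale CPU.

## The problem

Dementia classifiers built on structural MRI usually pick one of two
feature scales: whole-brain 3D convolutions (global structure, but subtle
local change is diluted) or per-slice 2D features (local detail, but most
slices are uninformative and the view context is lost). This package
implements a fusion architecture that keeps both:

* **MVSSN** — a small 2D CNN per slice in each of the sagittal, coronal
  and axial views maps every slice to an 8-dimensional embedding;
* **SAM** — a slice attention module turns each view's embeddings
  I ∈ R^(M×C) into a column-stochastic affinity matrix
  `a_ij = exp(I_i·I_j) / Σ_i' exp(I_i'·I_j)` and re-weights slices through
  a learnable residual gate, `Ĩ_j = β Σ_i a_ij I_i + I_j`, with β grown
  from 0 during training;
* **S3D-CNN** — a four-block 3D CNN summarises the whole volume into a
  512-dimensional subject feature;
* a fully connected softmax head classifies the concatenated slice and
  subject features, trained with macro-averaged cross-entropy
  (SGD, lr 0.01, weight decay 0.02, batch 12, early stopping).

Setting `use_sam=False` gives the attention-free ablation (MS3D), which
is bit-identical to the full model while β = 0.

Everything — including convolutions, batch-norm and backprop — runs on a
small NumPy autograd engine inside the package, so there is no GPU or
deep-learning-framework dependency. Volumes are read and written as
NIfTI; real MRI should be registered/skull-stripped/bias-corrected
offline (a `hook` splice point is provided) before the built-in
crop → z-score → resample chain.

Because the real cohorts behind the method are access-controlled, the
package ships a phantom simulator: ellipsoidal "brains" where class 1 has
a known intensity-reduction lesion, giving exact ground truth for which
slices are informative — the basis for attention and Grad-CAM checks.

## Worked example

```python
import numpy as np
from msa3d import attention_scores, apply_attention, attention_mass

rng = np.random.default_rng(0)
emb = rng.standard_normal((5, 8)) * 0.3   # five slice embeddings, C = 8
emb[1] += 2.0; emb[2] += 2.0              # two slices share a strong direction

A = attention_scores(emb)
print(A.sum(axis=0))                      # [1. 1. 1. 1. 1.]
print(attention_mass(A, {1, 2}))          # 0.721  (uniform baseline 0.4)
out = apply_attention(emb, A, beta=0.0)   # exact pass-through at beta = 0
print(np.abs(out - emb).max())            # 0.0
```

Every column of the affinity matrix distributes one unit of influence
over contributing slices; correlated, large-norm embeddings attract mass
(0.721 vs the 0.4 a uniform matrix would give), and the zero gate leaves
features untouched — the model starts as its own ablation.

Training end to end on phantoms (`examples/04_train_and_evaluate.py`,
a few CPU-minutes):

```text
trained 15 epochs; train loss 0.469 -> 0.011
test metrics: {'ACC': 1.0, 'SEN': 1.0, 'SPE': 1.0, 'AUC': 1.0, 'F1': 1.0}
axial attention mass on lesion slices: 0.290 (uniform baseline 0.458)
```

The separable phantom task is solved perfectly; note that the attention
mass does *not* concentrate on lesion slices here — once the loss
saturates the gate β receives no gradient, a documented limitation of
easy synthetic worlds (see `docs/methods.md`).

The other scripts in `examples/` cover simulation with ground truth,
NIfTI preprocessing and slice decomposition, and Grad-CAM saliency
checked against the simulator's lesion masks.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch: simulates 120 training and 60
test phantoms, trains the fused model, prints the five test metrics, the
axial attention mass against ground truth, and the Grad-CAM
lesion-localization count, then writes its JSON output to `--out`.
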