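"""The fused two-branch classifier (MSA3D) and its attention-free ablation.

A volume is processed twice: slice-wise (MVSSN embeddings, optionally
re-weighted by the slice attention module) and as a whole (3D subject
branch).  The flattened slice features and the subject feature are
concatenated and classified by a two-layer fully connected head with a
softmax output.

``use_sam=False`` gives the MS3D ablation: the attention module is skipped
entirely.  Because the attention gate beta is initialised to 0 and the
attention term enters residually, MS3D and MSA3D produce *identical*
outputs for identical weights until beta moves — the ablation is the
model's own initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mvssn import SliceNetConfig, ViewBank
from .nn import Linear, Module, Tensor, concat, no_grad, softmax
from .s3dcnn import SubjectNet, SubjectNetConfig
from .sam import SliceAttention

__all__ = ["FusionConfig", "MSA3D", "save_checkpoint", "load_checkpoint"]

VIEW_KEYS = ("x", "y", "z")


@dataclass(frozen=True)
class FusionConfig:
    """Classifier-head and ablation settings."""

    hidden: int = 256
    n_classes: int = 2
    use_sam: bool = True              # False = MS3D ablation
    loss_variant: str = "macro_eq5"   # or "standard_ce"

    def __post_init__(self):
        if self.hidden < 1 or self.n_classes < 2:
            raise ValueError("hidden must be >= 1 and n_classes >= 2")
        if self.loss_variant not in ("macro_eq5", "standard_ce"):
            raise ValueError("loss_variant must be 'macro_eq5' or 'standard_ce'")


class MSA3D(Module):
    """Multi-view slice attention + 3D CNN fusion classifier.

    Parameters
    ----------
    input_shape : (D, H, W) volume grid the model is built for.
    slice_cfg, subject_cfg, fusion_cfg : architecture settings.
    seed : controls all weight initialisation.
    """

    def __init__(self, input_shape: tuple[int, int, int],
                 slice_cfg: SliceNetConfig = SliceNetConfig(),
                 subject_cfg: SubjectNetConfig = SubjectNetConfig(),
                 fusion_cfg: FusionConfig = FusionConfig(),
                 seed: int = 0):
        super().__init__()
        self.input_shape = tuple(int(s) for s in input_shape)
        self.slice_cfg = slice_cfg
        self.subject_cfg = subject_cfg
        self.fusion_cfg = fusion_cfg
        rng = np.random.default_rng(seed)

        d, h, w = self.input_shape
        self.view_x = ViewBank(d, slice_cfg, rng=rng)
        self.view_y = ViewBank(h, slice_cfg, rng=rng)
        self.view_z = ViewBank(w, slice_cfg, rng=rng)
        self.sam_x = SliceAttention()
        self.sam_y = SliceAttention()
        self.sam_z = SliceAttention()
        self.subject = SubjectNet(subject_cfg, rng=rng)

        c = slice_cfg.embedding_dim
        self.slice_feature_dim = (d + h + w) * c
        fusion_in = self.slice_feature_dim + subject_cfg.feature_dim
        self.fc1 = Linear(fusion_in, fusion_cfg.hidden, rng=rng)
        self.fc2 = Linear(fusion_cfg.hidden, fusion_cfg.n_classes, rng=rng)

    # ------------------------------------------------------------------
    def _view_banks(self):
        return {"x": (self.view_x, self.sam_x), "y": (self.view_y, self.sam_y),
                "z": (self.view_z, self.sam_z)}

    @staticmethod
    def _view_slices(x: Tensor, key: str) -> Tensor:
        """(N, D, H, W) -> (N, M_k, a, b) slice stack for view ``key``."""
        if key == "x":
            return x
        if key == "y":
            return x.swapaxes(1, 2)
        return x.swapaxes(1, 3).swapaxes(2, 3)  # (N, W, D, H)

    def forward(self, x: Tensor, *, return_attention: bool = False,
                return_activations: bool = False):
        """(N, D, H, W) volumes -> (N, n_classes) logits.

        With ``return_attention`` also returns {view: (N, M_k, M_k)}
        attention arrays (empty for the MS3D ablation).  With
        ``return_activations`` additionally returns the Grad-CAM tap
        activations (keys "subject", "x", "y", "z") with retained grads.
        """
        if x.shape[1:] != self.input_shape:
            raise ValueError(f"expected volumes of shape {self.input_shape}, "
                             f"got {x.shape[1:]}")
        n = x.shape[0]
        slice_feats = []
        attention: dict[str, np.ndarray] = {}
        activations: dict[str, object] = {}
        for key, (bank, sam) in self._view_banks().items():
            emb, act = bank.forward_with_activations(
                self._view_slices(x, key), retain=return_activations)
            activations[key] = act
            if self.fusion_cfg.use_sam:
                emb, attn = sam(emb)
                attention[key] = attn.data
            slice_feats.append(emb.reshape(n, -1))
        f3d, act3d = self.subject.forward_with_activation(
            x.reshape(n, 1, *self.input_shape), retain=return_activations)
        activations["subject"] = act3d
        fused = concat(slice_feats + [f3d], axis=1)
        logits = self.fc2(self.fc1(fused).relu())
        out = (logits,)
        if return_attention:
            out += (attention,)
        if return_activations:
            out += (activations,)
        return out if len(out) > 1 else logits

    # ------------------------------------------------------------------
    def predict_proba(self, volumes: np.ndarray) -> np.ndarray:
        """Class probabilities for an (N, D, H, W) array (inference mode)."""
        self.eval()
        with no_grad():
            logits = self.forward(Tensor(np.asarray(volumes, dtype=np.float32)))
            probs = softmax(logits, axis=1)
        return probs.data

    def attention_matrices(self, volume: np.ndarray) -> dict[str, np.ndarray]:
        """Per-view attention matrices for a single (D, H, W) volume."""
        self.eval()
        with no_grad():
            _, attn = self.forward(
                Tensor(np.asarray(volume, dtype=np.float32)[None]),
                return_attention=True)
        return {k: a[0] for k, a in attn.items()}

    def fuse_and_classify(self, slice_features: np.ndarray,
                          subject_feature: np.ndarray) -> np.ndarray:
        """Classify pre-computed features; returns a probability vector."""
        fs = np.asarray(slice_features, dtype=np.float32).ravel()
        f3 = np.asarray(subject_feature, dtype=np.float32).ravel()
        expected = self.slice_feature_dim + self.subject_cfg.feature_dim
        if fs.size + f3.size != expected:
            raise ValueError(
                f"feature lengths {fs.size}+{f3.size} do not match the head "
                f"input {expected}")
        with no_grad():
            h = Tensor(np.concatenate([fs, f3])[None])
            probs = softmax(self.fc2(self.fc1(h).relu()), axis=1)
        return probs.data[0]


def save_checkpoint(model: Module, path: str | Path, meta: dict | None = None):
    """Persist weights (npz container with a JSON manifest entry)."""
    import json
    state = model.state_dict()
    manifest = json.dumps({"keys": sorted(state), "meta": meta or {}})
    np.savez(path, __manifest__=np.frombuffer(manifest.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(model: Module, path: str | Path) -> dict:
    import json
    with np.load(path) as data:
        state = {k: data[k] for k in data.files if k != "__manifest__"}
        manifest = json.loads(bytes(data["__manifest__"]).decode())
    model.load_state_dict(state)
    return manifest.get("meta", {})
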