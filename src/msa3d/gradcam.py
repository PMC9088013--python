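"""Grad-CAM saliency for the 3D branch and the per-slice 2D subnets.

The class-activation map of a conv layer is the ReLU-rectified,
channel-weighted sum of its activations, with channel weights equal to the
spatial average of the target-class score's gradient at that layer:

    w_c = mean_xyz dS_target / dA_c ,   CAM = ReLU( sum_c w_c * A_c )

The score is the *full* model's pre-softmax logit for the target class, so
gradients reflect both branches and the attention path.  Maps are linearly
upsampled to the input grid and max-normalised to [0, 1] when non-zero.
Target layers: the third block's rectified output in the 3D branch, and
the last conv block's rectified output in each slice subnet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MSA3D
from .nn import Tensor
from .volume_io import Volume, resize_volume

__all__ = ["SaliencyMap", "gradcam_3d", "gradcam_slices", "save_mosaic"]

_VIEW_KEY = {"x": "x", "y": "y", "z": "z",
             "sagittal": "x", "coronal": "y", "axial": "z"}


@dataclass(frozen=True)
class SaliencyMap:
    """Non-negative saliency grid aligned to the input volume."""

    data: np.ndarray
    target_class: int
    source: str  # "3d" or "slice-view-<k>"

    def __post_init__(self):
        if (self.data < 0).any():
            raise ValueError("saliency must be non-negative")


def _cam_from(act: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """activations/gradients (C, *spatial) -> rectified, normalised CAM."""
    spatial_axes = tuple(range(1, act.ndim))
    weights = grad.mean(axis=spatial_axes)
    cam = np.maximum((weights[(...,) + (None,) * len(spatial_axes)] * act).sum(0), 0.0)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def _upsample(cam: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Linear upsampling of a 2D or 3D map via the volume resampler."""
    vol = cam if cam.ndim == 3 else cam[..., None]
    tgt = shape if cam.ndim == 3 else (*shape, 1)
    out = resize_volume(Volume(vol.astype(np.float64)), tgt).data
    return out if cam.ndim == 3 else out[..., 0]


def _backprop_score(model: MSA3D, data: np.ndarray, target_class: int):
    model.eval()
    x = Tensor(data[None])
    logits, acts = model.forward(x, return_activations=True)
    score = logits[:, int(target_class)].sum()
    score.backward()
    return acts


def gradcam_3d(model: MSA3D, volume, target_class: int) -> SaliencyMap:
    """Volume-level saliency from the subject branch's third conv block."""
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float32)
    acts = _backprop_score(model, data, target_class)
    act = acts["subject"]
    if act.grad is None or not np.isfinite(act.grad).all() \
            or not np.isfinite(act.data).all():
        raise FloatingPointError(
            "non-finite activations/gradients; is the model trained?")
    cam = _cam_from(act.data[0], act.grad[0])
    return SaliencyMap(_upsample(cam, data.shape), int(target_class), "3d")


def gradcam_slices(model: MSA3D, volume, target_class: int,
                   view: str) -> list[SaliencyMap]:
    """Per-slice saliency stack (length M_k) for one view, in slice order."""
    if view not in _VIEW_KEY:
        raise ValueError(f"unknown view {view!r}; use x/y/z or "
                         "sagittal/coronal/axial")
    key = _VIEW_KEY[view]
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float32)
    acts = _backprop_score(model, data, target_class)
    act = acts[key]
    axis = "xyz".index(key)
    slice_shape = tuple(s for i, s in enumerate(data.shape) if i != axis)
    maps = []
    if isinstance(act, list):           # independent subnets: one tensor each
        per_slice = [(a.data[0], a.grad[0] if a.grad is not None
                      else np.zeros_like(a.data[0])) for a in act]
    else:                               # shared subnet: (M, ch, h, w) batch
        grad = act.grad if act.grad is not None else np.zeros_like(act.data)
        per_slice = [(act.data[i], grad[i]) for i in range(act.data.shape[0])]
    for i, (a, g) in enumerate(per_slice):
        cam = _cam_from(a, g)
        maps.append(SaliencyMap(_upsample(cam, slice_shape), int(target_class),
                                f"slice-view-{key}"))
    return maps


def save_mosaic(maps: list[SaliencyMap], path,
                slices: list[np.ndarray] | None = None, ncols: int = 8) -> None:
    """Write a PNG mosaic of per-slice saliency maps (optionally overlaid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    n = len(maps)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(1.6 * ncols, 1.6 * nrows))
    flat = np.atleast_1d(axes).ravel()
    for ax in flat:
        ax.axis("off")
    for i, sal in enumerate(maps):
        cam = sal.data if isinstance(sal, SaliencyMap) else sal
        if slices is not None:
            flat[i].imshow(slices[i].T, cmap="gray", origin="lower")
            flat[i].imshow(cam.T, cmap="jet", alpha=0.45, origin="lower")
        else:
            flat[i].imshow(cam.T, cmap="jet", origin="lower")
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)
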