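"""Subject-level 3D CNN branch (S3D-CNN).

Four conv3d -> batch-norm -> ReLU -> max-pool3d blocks followed by a 3D
global average pool produce one feature vector per subject.  The published
layout (channels 32/128/256/512, 3x3x3 stride-1 convs with 3x3x3 stride-2
pools, then a 2x2x2 stride-2 conv and a 5x5x5 stride-2 pool) reduces the
91 x 101 x 91 input grid to a 1x1x1x512 map; GAP makes the feature width
independent of the surviving spatial extent, so smaller grids work too
(pool windows clip to the map when necessary).

``conv3d_reference`` is the deliberately naive triple-loop convolution
used as an independent oracle for the vectorised implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm, ConvNd, GlobalAvgPool, MaxPoolNd, Module, ReLU,
                 Sequential, Tensor)

__all__ = ["SubjectNetConfig", "SubjectNet", "conv3d_reference", "subject_forward"]


@dataclass(frozen=True)
class SubjectNetConfig:
    """Per-block (kernel, conv stride, conv padding, channels, pool kernel,
    pool stride) of the subject network."""

    blocks: tuple = (
        # (conv_kernel, conv_stride, conv_pad, out_channels, pool_kernel, pool_stride)
        (3, 1, 1, 32, 3, 2),
        (3, 1, 1, 128, 3, 2),
        (3, 1, 1, 256, 3, 2),
        (2, 2, 0, 512, 5, 2),
    )
    allow_pool_clip: bool = True

    @property
    def feature_dim(self) -> int:
        return self.blocks[-1][3]

    @staticmethod
    def desk_scale() -> "SubjectNetConfig":
        """Narrow variant (16/32/64/128) for CPU-budget phantom experiments."""
        return SubjectNetConfig(blocks=(
            (3, 1, 1, 16, 3, 2),
            (3, 1, 1, 32, 3, 2),
            (3, 1, 1, 64, 3, 2),
            (2, 2, 0, 128, 5, 2),
        ))


class SubjectNet(Module):
    """Whole-volume 3D CNN -> subject feature vector."""

    def __init__(self, cfg: SubjectNetConfig = SubjectNetConfig(), *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        layers: list[Module] = []
        in_ch = 1
        for b, (k, s, p, out_ch, pk, ps) in enumerate(cfg.blocks, start=1):
            layers += [
                ConvNd(in_ch, out_ch, k, ndim=3, stride=s, padding=p, rng=rng,
                       name=f"subject-net block {b} conv"),
                BatchNorm(out_ch),
                ReLU(),
                MaxPoolNd(pk, ndim=3, stride=ps, allow_clip=cfg.allow_pool_clip,
                          name=f"subject-net block {b} max-pool"),
            ]
            in_ch = out_ch
        self.features = Sequential(*layers)
        self.gap = GlobalAvgPool()

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, D, H, W) -> (N, feature_dim)."""
        return self.gap(self.features(x))

    @property
    def gradcam_layer_index(self) -> int:
        """Index (into the feature Sequential) of block 3's ReLU output."""
        return 4 * 2 + 2  # block 3 = layers 8..11; ReLU at 10

    def forward_with_activation(self, x: Tensor,
                                retain: bool = True) -> tuple[Tensor, Tensor]:
        """Forward pass that also returns block 3's rectified activation."""
        act = None
        for i, layer in enumerate(self.features):
            x = layer(x)
            if i == self.gradcam_layer_index:
                act = x.retain_grad() if retain else x
        return self.gap(x), act


def conv3d_reference(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Single-channel valid 3D convolution by explicit triple summation.

    u(x,y,z) = sum_dx sum_dy sum_dz F(x+dx, y+dy, z+dz) * W(dx,dy,dz)

    (cross-correlation form, matching how CNN "convolution" layers slide a
    kernel).  Quadratically slower than the im2col path by design: this is
    the oracle the fast path is tested against, not a user-facing op.
    """
    f = np.asarray(volume, dtype=np.float64)
    w = np.asarray(kernel, dtype=np.float64)
    if f.ndim != 3 or w.ndim != 3:
        raise ValueError("volume and kernel must both be 3D")
    if any(kw > fs for kw, fs in zip(w.shape, f.shape)):
        raise ValueError(f"kernel {w.shape} larger than input {f.shape}")
    out_shape = tuple(fs - kw + 1 for fs, kw in zip(f.shape, w.shape))
    out = np.zeros(out_shape)
    for x in range(out_shape[0]):
        for y in range(out_shape[1]):
            for z in range(out_shape[2]):
                acc = 0.0
                for dx in range(w.shape[0]):
                    for dy in range(w.shape[1]):
                        for dz in range(w.shape[2]):
                            acc += f[x + dx, y + dy, z + dz] * w[dx, dy, dz]
                out[x, y, z] = acc
    return out


def subject_forward(volume, net: SubjectNet) -> np.ndarray:
    """Inference helper: one Volume (or 3D array) -> subject feature vector."""
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float32)
    net.eval()
    from .nn import no_grad
    with no_grad():
        out = net(Tensor(data[None, None]))
    return out.data[0]
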