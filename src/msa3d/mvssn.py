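"""Multi-view slice sub-networks (MVSSN).

Every 2D slice of the volume — in each of the sagittal, coronal and axial
views — is mapped to a C-dimensional embedding by a small CNN: three
conv(3x3, stride 2) -> batch-norm -> ReLU -> max-pool(2x2) blocks with
8/32/64 channels, global average pooling, then FC 64->128->C with C = 8.

Two weight-sharing regimes are supported: ``independent`` (one subnet per
slice, the default) and ``per_view`` (one subnet shared by all slices of a
view — two orders of magnitude fewer parameters at the full grid, and much
faster since all slices of a view go through as one batch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm, ConvNd, GlobalAvgPool, Linear, MaxPoolNd, Module,
                 ModuleList, ReLU, Sequential, Tensor)

__all__ = ["SliceNetConfig", "SliceNet", "ViewBank", "slice_forward", "view_forward"]


@dataclass(frozen=True)
class SliceNetConfig:
    """Layer widths of one slice subnet."""

    conv_channels: tuple[int, int, int] = (8, 32, 64)
    kernel_size: int = 3
    conv_stride: int = 2
    pool_size: int = 2
    hidden: int = 128
    embedding_dim: int = 8          # C, the per-slice feature channels
    weight_sharing: str = "independent"   # or "per_view"
    allow_pool_clip: bool = True

    def __post_init__(self):
        if self.weight_sharing not in ("independent", "per_view"):
            raise ValueError("weight_sharing must be 'independent' or 'per_view'")


class SliceNet(Module):
    """One 2D slice -> embedding network."""

    def __init__(self, cfg: SliceNetConfig = SliceNetConfig(), *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng()
        layers: list[Module] = []
        in_ch = 1
        for b, out_ch in enumerate(cfg.conv_channels, start=1):
            layers += [
                ConvNd(in_ch, out_ch, cfg.kernel_size, ndim=2,
                       stride=cfg.conv_stride, padding=1, rng=rng,
                       name=f"slice-net block {b} conv"),
                BatchNorm(out_ch),
                ReLU(),
                MaxPoolNd(cfg.pool_size, ndim=2, allow_clip=cfg.allow_pool_clip,
                          name=f"slice-net block {b} max-pool"),
            ]
            in_ch = out_ch
        self.features = Sequential(*layers)
        self.gap = GlobalAvgPool()
        self.fc1 = Linear(in_ch, cfg.hidden, rng=rng)
        self.fc2 = Linear(cfg.hidden, cfg.embedding_dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) -> (N, C) embeddings."""
        return self.forward_with_activation(x)[0]

    def forward_with_activation(self, x: Tensor, retain: bool = False):
        """Also return the last conv block's rectified output (Grad-CAM tap)."""
        act = None
        layers = self.features._list
        h = x
        for i, layer in enumerate(layers):
            h = layer(h)
            if i == len(layers) - 2:  # ReLU output of the last block
                act = h.retain_grad() if retain else h
        emb = self.fc2(self.fc1(self.gap(h)).relu())
        return emb, act


class ViewBank(Module):
    """The slice subnets of one view, honouring the sharing regime."""

    def __init__(self, n_slices: int, cfg: SliceNetConfig, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.n_slices = n_slices
        rng = rng or np.random.default_rng()
        if cfg.weight_sharing == "per_view":
            self.nets = ModuleList([SliceNet(cfg, rng=rng)])
        else:
            self.nets = ModuleList([SliceNet(cfg, rng=rng) for _ in range(n_slices)])

    def forward(self, slices: Tensor) -> Tensor:
        """(N, M, H, W) slice stack -> (N, M, C) embeddings."""
        return self.forward_with_activations(slices)[0]

    def forward_with_activations(self, slices: Tensor, retain: bool = False):
        """Embeddings plus the per-slice Grad-CAM tap activations.

        The activation is a single (N*M, ch, h, w) tensor under per-view
        sharing, or a list of M (N, ch, h, w) tensors for independent nets.
        """
        n, m = slices.shape[:2]
        if m != self.n_slices:
            raise ValueError(f"expected {self.n_slices} slices per view, got {m}")
        if self.cfg.weight_sharing == "per_view":
            flat = slices.reshape(n * m, 1, *slices.shape[2:])
            emb, act = self.nets[0].forward_with_activation(flat, retain=retain)
            return emb.reshape(n, m, self.cfg.embedding_dim), act
        pairs = [self.nets[i].forward_with_activation(
            slices[:, i].reshape(n, 1, *slices.shape[2:]), retain=retain)
            for i in range(m)]
        from .nn import concat
        emb = concat([e.reshape(n, 1, self.cfg.embedding_dim) for e, _ in pairs],
                     axis=1)
        return emb, [a for _, a in pairs]


def slice_forward(s: np.ndarray, net: SliceNet) -> np.ndarray:
    """Embed a single 2D slice (inference helper)."""
    s = np.asarray(s, dtype=np.float32)
    out = net(Tensor(s[None, None]))
    return out.data[0]


def view_forward(slices: list[np.ndarray], nets: list[SliceNet]) -> np.ndarray:
    """Embed an ordered slice stack with per-slice nets -> (M, C) matrix.

    Row i is ``slice_forward(slices[i], nets[i])``; with a single shared net
    pass a one-element list and it is reused for every slice.
    """
    if len(nets) not in (1, len(slices)):
        raise ValueError(
            f"need one net per slice ({len(slices)}) or a single shared net, "
            f"got {len(nets)}")
    if len(nets) == 1:
        nets = [nets[0]] * len(slices)
    return np.stack([slice_forward(s, net) for s, net in zip(slices, nets)])
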