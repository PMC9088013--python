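"""Neural-network layers on top of the autograd engine.

Convolution is implemented as an im2col gather (one strided copy per kernel
offset — at most 27 for a 3x3x3 kernel) followed by a single BLAS matmul;
the backward pass scatters through the same offsets.  The same machinery
serves 2D slice networks and the 3D subject network.

Max-pooling windows may be *clipped* to the available spatial extent
(``allow_clip``): a 5x5x5 window on a 2x2x2 map degrades to 2x2x2.  This is
what lets one architecture run both on the full 91x101x91 grid and on
desk-scale phantom grids.  With clipping disabled a :class:`ShapeError`
names the failing stage instead.
"""

from __future__ import annotations

import itertools

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "ShapeError", "Module", "ModuleList", "Sequential",
    "ConvNd", "MaxPoolNd", "BatchNorm", "Linear", "ReLU", "GlobalAvgPool",
]


class ShapeError(ValueError):
    """Raised when a feature map is too small for a layer's window."""


# ---------------------------------------------------------------------------
# module container machinery
# ---------------------------------------------------------------------------

class Module:
    """Base class with parameter registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        object.__setattr__(self, "training", True)
        for m in self._modules.values():
            m.train()
        return self

    def eval(self):
        object.__setattr__(self, "training", False)
        for m in self._modules.values():
            m.eval()
        return self

    # checkpointing ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.array(value, dtype=params[name].dtype)
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        self._modules[str(len(self._list))] = module
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self._list = list(layers)
        for i, m in enumerate(self._list):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self._list:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------

def _tupled(v, n: int) -> tuple[int, ...]:
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v),) * n


def _offset_slices(offset, out_shape, stride):
    return tuple(slice(o, o + (so - 1) * st + 1, st)
                 for o, so, st in zip(offset, out_shape, stride))


def _im2col(xp: np.ndarray, kernel, stride, out_shape):
    """Gather windows: (N, C, *Spad) -> (N, C * prod(kernel), prod(out))."""
    n, c = xp.shape[:2]
    offsets = list(itertools.product(*(range(k) for k in kernel)))
    pk = len(offsets)
    pout = int(np.prod(out_shape))
    cols = np.empty((n, c, pk, pout), dtype=xp.dtype)
    for i, off in enumerate(offsets):
        view = xp[(slice(None), slice(None)) + _offset_slices(off, out_shape, stride)]
        cols[:, :, i] = view.reshape(n, c, pout)
    return cols.reshape(n, c * pk, pout), offsets


def _col2im(dcols: np.ndarray, xp_shape, kernel, stride, out_shape, offsets):
    n, c = xp_shape[:2]
    pout = int(np.prod(out_shape))
    dcols = dcols.reshape(n, c, len(offsets), pout)
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i, off in enumerate(offsets):
        view = dxp[(slice(None), slice(None)) + _offset_slices(off, out_shape, stride)]
        view += dcols[:, :, i].reshape(view.shape)
    return dxp


class ConvNd(Module):
    """N-dimensional convolution (cross-correlation), batch-norm-free.

    Parameters are initialised Kaiming fan-in with zero bias.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size, *,
                 ndim: int, stride=1, padding=0, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ndim = ndim
        self.kernel_size = _tupled(kernel_size, ndim)
        self.stride = _tupled(stride, ndim)
        self.padding = _tupled(padding, ndim)
        self.name = name
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(self.kernel_size))
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, (out_channels, in_channels, *self.kernel_size))
            .astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        xd = x.data
        n = xd.shape[0]
        spatial = xd.shape[2:]
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        xp = np.pad(xd, pad) if any(self.padding) else xd
        out_shape = tuple((xp.shape[2 + i] - self.kernel_size[i]) // self.stride[i] + 1
                          for i in range(self.ndim))
        if any(s < 1 for s in out_shape):
            raise ShapeError(
                f"{self.name}: input spatial shape {spatial} too small for "
                f"kernel {self.kernel_size} stride {self.stride}")
        cols, offsets = _im2col(xp, self.kernel_size, self.stride, out_shape)
        wmat = w.data.reshape(self.out_channels, -1)
        out = wmat @ cols  # (N, Cout, prod(out))
        out += b.data[None, :, None]
        out = out.reshape(n, self.out_channels, *out_shape)

        def backward(g):
            gm = g.reshape(n, self.out_channels, -1)
            dw = (gm @ cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
            db = gm.sum(axis=(0, 2))
            dcols = wmat.T @ gm
            dxp = _col2im(dcols, xp.shape, self.kernel_size, self.stride,
                          out_shape, offsets)
            if any(self.padding):
                sl = tuple(slice(p, p + s) for p, s in zip(self.padding, spatial))
                dxp = dxp[(slice(None), slice(None)) + sl]
            return dxp, dw, db

        return Tensor._result(out, (x, w, b), backward)


class MaxPoolNd(Module):
    """Max pooling with optional window clipping on small maps."""

    def __init__(self, kernel_size, *, ndim: int, stride=None,
                 allow_clip: bool = True, name: str = "maxpool"):
        super().__init__()
        self.ndim = ndim
        self.kernel_size = _tupled(kernel_size, ndim)
        self.stride = _tupled(stride if stride is not None else kernel_size, ndim)
        self.allow_clip = allow_clip
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        n, c = xd.shape[:2]
        spatial = xd.shape[2:]
        kernel = self.kernel_size
        if any(k > s for k, s in zip(kernel, spatial)):
            if not self.allow_clip:
                raise ShapeError(
                    f"{self.name}: input spatial shape {spatial} smaller than "
                    f"pooling window {kernel}")
            kernel = tuple(min(k, s) for k, s in zip(kernel, spatial))
        out_shape = tuple((spatial[i] - kernel[i]) // self.stride[i] + 1
                          for i in range(self.ndim))
        cols, offsets = _im2col(xd, kernel, self.stride, out_shape)
        cols = cols.reshape(n, c, len(offsets), -1)
        arg = cols.argmax(axis=2)
        out = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0]
        out = out.reshape(n, c, *out_shape)

        def backward(g):
            gm = g.reshape(n, c, -1)
            dcols = np.zeros(cols.shape, dtype=gm.dtype)
            np.put_along_axis(dcols, arg[:, :, None, :], gm[:, :, None, :], axis=2)
            return (_col2im(dcols.reshape(n, c * len(offsets), -1), xd.shape,
                            kernel, self.stride, out_shape, offsets),)

        return Tensor._result(out, (x,), backward)


# ---------------------------------------------------------------------------
# normalisation, linear, activations
# ---------------------------------------------------------------------------

class BatchNorm(Module):
    """Batch normalisation over (batch, *spatial) per channel.

    Train mode uses batch statistics and updates exponential running
    averages (momentum 0.1); eval mode uses the running averages.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32), decay=False)
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32), decay=False)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = (1, self.num_features) + (1,) * (x.ndim - 2)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=axes, keepdims=True)
            count = x.data.size // self.num_features
            unbias = count / max(count - 1, 1)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1).astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (
                unbias * var.data.reshape(-1).astype(np.float32) - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(bshape).astype(x.dtype))
            var = Tensor(self.running_var.reshape(bshape).astype(x.dtype))
            centred = x - mu
        xhat = centred * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(
            rng.normal(0.0, scale, (in_features, out_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32), decay=False)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GlobalAvgPool(Module):
    """Collapse all spatial dimensions to one value per channel."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=tuple(range(2, x.ndim)))
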