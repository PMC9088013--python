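"""Gradient correctness of the autograd engine against finite differences."""

from __future__ import annotations

import numpy as np
import pytest

from msa3d.nn import (BatchNorm, ConvNd, GlobalAvgPool, Linear, MaxPoolNd,
                      Sequential, Tensor, concat, log_softmax, softmax)


def _numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def _check_input_grad(make_output, x: np.ndarray, rtol: float = 1e-5):
    xt = Tensor(x, requires_grad=True)
    out = make_output(xt)
    out.backward()
    num = _numeric_grad(lambda xx: float(make_output(Tensor(xx)).data), x)
    np.testing.assert_allclose(xt.grad, num, rtol=rtol, atol=1e-7)


RNG = np.random.default_rng(7)


@pytest.mark.parametrize("fn", [
    lambda t: (t * t + 2.0 * t).sum(),
    lambda t: (t.exp() + (t * t + 1.0).log()).mean(),
    lambda t: t.relu().sum(),
    lambda t: (t ** 3).sum(axis=1).mean(),
    lambda t: softmax(t, axis=1).sum(axis=0)[1],
    lambda t: -(log_softmax(t, axis=1)[:, 0]).sum(),
    lambda t: (t.reshape(6, 2).transpose((1, 0)) @ t.reshape(6, 2)).sum(),
], ids=["poly", "exp-log", "relu", "pow-reduce", "softmax", "log-softmax",
        "matmul"])
def test_elementwise_and_reduction_grads(fn):
    x = RNG.standard_normal((3, 4)) + 0.1
    _check_input_grad(fn, x)


def test_broadcast_add_mul_grads():
    a = RNG.standard_normal((3, 1, 4))
    b = RNG.standard_normal((5, 1))
    at, bt = Tensor(a, requires_grad=True), Tensor(b, requires_grad=True)
    ((at * bt + bt) ** 2).sum().backward()
    na = _numeric_grad(lambda aa: float((((Tensor(aa) * bt) + bt) ** 2).sum().data), a)
    nb = _numeric_grad(lambda bb: float((((at * Tensor(bb)) + Tensor(bb)) ** 2)
                                        .sum().data), b)
    np.testing.assert_allclose(at.grad, na, rtol=1e-5, atol=1e-8)
    np.testing.assert_allclose(bt.grad, nb, rtol=1e-5, atol=1e-8)


def test_batched_matmul_grad():
    a = RNG.standard_normal((2, 3, 4))
    b = RNG.standard_normal((2, 4, 3))
    at = Tensor(a, requires_grad=True)
    bt = Tensor(b, requires_grad=True)
    (at @ bt).sum().backward()
    na = _numeric_grad(lambda aa: float((Tensor(aa) @ bt).sum().data), a)
    np.testing.assert_allclose(at.grad, na, rtol=1e-5, atol=1e-8)


def test_concat_and_getitem_grads():
    a = RNG.standard_normal((3, 2))
    b = RNG.standard_normal((2, 2))

    def out(at):
        c = concat([at, Tensor(b)], axis=0)
        return (c[1:4, :] ** 2).sum()

    _check_input_grad(out, a)


@pytest.mark.parametrize("ndim,stride,padding", [
    (2, 1, 0), (2, 2, 1), (3, 1, 1), (3, 2, 0),
])
def test_conv_gradients(ndim, stride, padding):
    """Input and weight gradients of the im2col convolution."""
    rng = np.random.default_rng(11)
    spatial = (7, 6) if ndim == 2 else (6, 5, 6)
    conv = ConvNd(2, 3, 3 if ndim == 2 else 2, ndim=ndim, stride=stride,
                  padding=padding, rng=rng)
    conv.weight.data = conv.weight.data.astype(np.float64)
    conv.bias.data = conv.bias.data.astype(np.float64)
    x = rng.standard_normal((2, 2, *spatial))

    def scalar(xx):
        return float((conv(Tensor(xx)) ** 2).sum().data)

    xt = Tensor(x, requires_grad=True)
    (conv(xt) ** 2).sum().backward()
    np.testing.assert_allclose(xt.grad, _numeric_grad(scalar, x),
                               rtol=1e-5, atol=1e-7)

    w = conv.weight.data.copy()

    def scalar_w(ww):
        conv.weight.data = ww
        return float((conv(Tensor(x)) ** 2).sum().data)

    conv.weight.data = w
    conv.weight.grad = None
    (conv(Tensor(x)) ** 2).sum().backward()
    gw = conv.weight.grad
    conv_grad_num = _numeric_grad(scalar_w, w)
    conv.weight.data = w
    np.testing.assert_allclose(gw, conv_grad_num, rtol=1e-5, atol=1e-7)


@pytest.mark.parametrize("kernel,stride", [(2, 2), (3, 2)])
def test_maxpool_gradient(kernel, stride):
    rng = np.random.default_rng(3)
    x = rng.standard_normal((2, 2, 7, 6))
    pool = MaxPoolNd(kernel, ndim=2, stride=stride)
    _check_input_grad(lambda t: (pool(t) ** 2).sum(), x)


def test_batchnorm_gradient_train_mode():
    rng = np.random.default_rng(5)
    bn = BatchNorm(3)
    bn.gamma.data = rng.standard_normal(3)
    bn.beta.data = rng.standard_normal(3)
    x = rng.standard_normal((4, 3, 5))

    def out(t):
        bn.running_mean[:] = 0  # keep running-stat side effects out of f(x)
        bn.running_var[:] = 1
        return (bn(t) ** 3).sum()

    _check_input_grad(out, x, rtol=1e-4)


def test_linear_gap_pipeline_gradient():
    rng = np.random.default_rng(9)
    net = Sequential(GlobalAvgPool())
    lin = Linear(3, 2, rng=rng)
    lin.weight.data = lin.weight.data.astype(np.float64)
    lin.bias.data = lin.bias.data.astype(np.float64)
    x = rng.standard_normal((2, 3, 4, 4))
    _check_input_grad(lambda t: (lin(net(t)) ** 2).sum(), x)


def test_no_grad_blocks_tape():
    from msa3d.nn import no_grad
    x = Tensor(np.ones(3), requires_grad=True)
    with no_grad():
        y = (x * 2.0).sum()
    assert not y.requires_grad and y._backward is None
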