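"""Minimal 1-D convolutional neural-net engine on numpy.

Implements exactly the pieces the surrogate models need — grouped/depthwise
1-D convolution, batch normalization, hard-swish / hard-sigmoid / ReLU /
sigmoid activations, squeeze-and-excitation, inverted-residual blocks, a
global-pool + dense head, the Adam optimizer and a cosine-annealing learning
rate schedule — with hand-written backward passes.  All layers cache their
forward activations, so a module instance processes one batch at a time.

Gradients are exercised against central finite differences in the test
suite; everything is float64 and seeded, so training is deterministic up to
platform floating point.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """Trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: composable forward/backward with parameter discovery."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for attr in vars(self).values():
            if isinstance(attr, Module):
                mods.extend(attr.modules())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    """Grouped 1-D convolution; ``groups == in_channels`` gives depthwise."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide both channel counts")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.groups = groups
        self.padding = kernel // 2
        cg = in_channels // groups
        og = out_channels // groups
        self.weight = Parameter(_he_init(rng, (groups, og, cg, kernel), cg * kernel), "conv.w")
        self.bias = Parameter(np.zeros(out_channels), "conv.b") if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride]
        lout = win.shape[2]
        win_g = win.reshape(n, self.groups, c // self.groups, lout, self.kernel)
        out = np.einsum("ngclk,gock->ngol", win_g, self.weight.value, optimize=True)
        out = out.reshape(n, self.out_channels, lout)
        if self.bias is not None:
            out += self.bias.value[None, :, None]
        self._cache = (win_g, xp.shape, x.shape, lout)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        win_g, xp_shape, x_shape, lout = self._cache
        n = grad.shape[0]
        g = self.groups
        grad_g = grad.reshape(n, g, self.out_channels // g, lout)
        self.weight.grad += np.einsum("ngol,ngclk->gock", grad_g, win_g, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2))
        gwin = np.einsum("ngol,gock->ngclk", grad_g, self.weight.value, optimize=True)
        gwin = gwin.reshape(n, self.in_channels, lout, self.kernel)
        gxp = np.zeros(xp_shape)
        s = self.stride
        for k in range(self.kernel):
            gxp[:, :, k : k + s * (lout - 1) + 1 : s] += gwin[:, :, :, k]
        p = self.padding
        return gxp[:, :, p : p + x_shape[2]]


class BatchNorm1d(Module):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        m = shape[0] * shape[2]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        if not self.training:
            return dxhat * inv_std[None, :, None]
        t1 = dxhat.sum(axis=(0, 2), keepdims=True)
        t2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / m) * (m * dxhat - t1 - xhat * t2)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Module):
    def forward(self, x):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


def _hard_sigmoid(x: np.ndarray) -> np.ndarray:
    return np.clip(x + 3.0, 0.0, 6.0) / 6.0


def _hard_sigmoid_grad(x: np.ndarray) -> np.ndarray:
    return ((x > -3.0) & (x < 3.0)) / 6.0


class HardSigmoid(Module):
    def forward(self, x):
        self._x = x
        return _hard_sigmoid(x)

    def backward(self, grad):
        return grad * _hard_sigmoid_grad(self._x)


class HardSwish(Module):
    """x * relu6(x + 3) / 6 — the cheap swish variant of mobile backbones."""

    def forward(self, x):
        self._x = x
        return x * _hard_sigmoid(x)

    def backward(self, grad):
        x = self._x
        return grad * (_hard_sigmoid(x) + x * _hard_sigmoid_grad(x))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features), "fc.w")
        self.bias = Parameter(np.zeros(out_features), "fc.b")

    def forward(self, x):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class GlobalAvgPool1d(Module):
    def forward(self, x):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class SqueezeExcite(Module):
    """Channel re-weighting: global pool -> bottleneck MLP -> hard-sigmoid gate."""

    def __init__(self, channels: int, reduction: int = 4, rng: np.random.Generator | None = None):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden, channels, rng)
        self.gate = HardSigmoid()

    def forward(self, x):
        pooled = x.mean(axis=2)
        s = self.gate(self.fc2(self.relu(self.fc1(pooled))))
        self._cache = (x, s)
        return x * s[:, :, None]

    def backward(self, grad):
        x, s = self._cache
        gx = grad * s[:, :, None]
        gs = (grad * x).sum(axis=2)
        gpooled = self.fc1.backward(self.relu.backward(self.fc2.backward(self.gate.backward(gs))))
        return gx + gpooled[:, :, None] / x.shape[2]


class Sequential(Module):
    def __init__(self, layers: Sequence[Module]):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class InvertedResidual(Module):
    """Expand (1x1) -> depthwise conv -> optional SE -> project (1x1).

    A skip connection is added when the block keeps both channel count and
    stride 1, as in the mobile inverted-bottleneck design.
    """

    def __init__(
        self,
        in_channels: int,
        expand_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        se: bool,
        activation: str,
        rng: np.random.Generator | None = None,
    ):
        act = HardSwish if activation == "hswish" else ReLU
        layers: list[Module] = []
        if expand_channels != in_channels:
            layers += [Conv1d(in_channels, expand_channels, 1, rng=rng), BatchNorm1d(expand_channels), act()]
        layers += [
            Conv1d(expand_channels, expand_channels, kernel, stride, groups=expand_channels, rng=rng),
            BatchNorm1d(expand_channels),
            act(),
        ]
        if se:
            layers.append(SqueezeExcite(expand_channels, rng=rng))
        layers += [Conv1d(expand_channels, out_channels, 1, rng=rng), BatchNorm1d(out_channels)]
        self.body = Sequential(layers)
        self.use_residual = stride == 1 and in_channels == out_channels

    def forward(self, x):
        out = self.body(x)
        return out + x if self.use_residual else out

    def backward(self, grad):
        gin = self.body.backward(grad)
        return gin + grad if self.use_residual else gin


# -- losses -----------------------------------------------------------------

def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    pred = pred.ravel()
    diff = pred - np.asarray(target, dtype=float).ravel()
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).reshape(-1, 1)


def bce_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-12) -> tuple[float, np.ndarray]:
    """Binary cross entropy on probabilities and its gradient."""
    p = np.clip(pred.ravel(), eps, 1.0 - eps)
    y = np.asarray(target, dtype=float).ravel()
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    grad = ((p - y) / (p * (1.0 - p)) / p.size).reshape(-1, 1)
    return loss, grad


# -- optimization -----------------------------------------------------------

class Adam:
    """Adaptive-moment-estimation optimizer with bias correction."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self._m, self._v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CosineAnnealingLR:
    """Learning rate decaying from ``lr_max`` to ``lr_min`` over one cosine cycle."""

    def __init__(self, lr_max: float, total_epochs: int, lr_min: float = 0.0):
        self.lr_max = lr_max
        self.lr_min = lr_min
        self.total_epochs = max(1, total_epochs)

    def lr_at(self, epoch: int) -> float:
        frac = min(epoch, self.total_epochs) / self.total_epochs
        return self.lr_min + 0.5 * (self.lr_max - self.lr_min) * (1.0 + math.cos(math.pi * frac))
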