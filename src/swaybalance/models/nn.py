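"""Minimal NumPy neural-network engine for the two small CNN classifiers.

The architectures involved are a single (depth-wise grouped) convolution
block followed by two fully-connected layers, so a compact hand-rolled
engine with explicit backprop is both sufficient and fully deterministic
on CPU.  Layers follow a uniform contract: ``forward(x, training)``,
``backward(grad)``, with learnable arrays in ``params`` and matching
gradients in ``grads``.

All computation is float64 internally for reproducibility of gradient
checks; batch sizes are small enough that speed is not a concern.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "GroupedConv1d",
    "GroupedConv2d",
    "MaxPool1d",
    "MaxPool2d",
    "ReLU",
    "BatchNorm",
    "Flatten",
    "Dense",
    "Dropout",
    "SequentialNet",
    "Adam",
    "softmax",
    "cross_entropy_with_softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_softmax(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits.

    ``y`` holds integer class indices in [0, n_classes).
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[np.arange(n), y] + eps)))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class GroupedConv1d(Layer):
    """1-D convolution with separate filters per channel group (depth-wise grouping).

    Input (N, C, T); output (N, F_total, T - K + 1) where the filter budget is
    split evenly across groups.  Groups never mix at this layer.
    """

    def __init__(
        self,
        groups: Sequence[Sequence[int]],
        n_filters: int,
        kernel: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.groups = [tuple(g) for g in groups]
        if n_filters % len(self.groups) != 0:
            raise ValueError("n_filters must divide evenly across channel groups")
        self.fpg = n_filters // len(self.groups)
        self.kernel = kernel
        self.weights = []
        self.biases = []
        for g in self.groups:
            w = _he_normal(rng, (self.fpg, len(g), kernel), fan_in=len(g) * kernel)
            b = np.zeros(self.fpg)
            self.weights.append(w)
            self.biases.append(b)
            self.params += [w, b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        outs = []
        self._windows = []
        for g, w, b in zip(self.groups, self.weights, self.biases):
            xg = x[:, g, :]
            win = np.lib.stride_tricks.sliding_window_view(xg, self.kernel, axis=2)
            self._windows.append(win)
            outs.append(np.einsum("nctk,fck->nft", win, w, optimize=True) + b[None, :, None])
        return np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        to = grad.shape[2]
        for i, (g, w) in enumerate(zip(self.groups, self.weights)):
            gslice = grad[:, i * self.fpg : (i + 1) * self.fpg, :]
            win = self._windows[i]
            self.grads[2 * i][...] = np.einsum("nctk,nft->fck", win, gslice, optimize=True)
            self.grads[2 * i + 1][...] = gslice.sum(axis=(0, 2))
            dxg = np.zeros((x.shape[0], len(g), x.shape[2]))
            for k in range(self.kernel):
                dxg[:, :, k : k + to] += np.einsum("nft,fc->nct", gslice, w[:, :, k], optimize=True)
            dx[:, g, :] += dxg
        return dx


class GroupedConv2d(Layer):
    """2-D analogue of :class:`GroupedConv1d` with square kernels."""

    def __init__(
        self,
        groups: Sequence[Sequence[int]],
        n_filters: int,
        kernel: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.groups = [tuple(g) for g in groups]
        if n_filters % len(self.groups) != 0:
            raise ValueError("n_filters must divide evenly across channel groups")
        self.fpg = n_filters // len(self.groups)
        self.kernel = kernel
        self.weights = []
        self.biases = []
        for g in self.groups:
            w = _he_normal(
                rng, (self.fpg, len(g), kernel, kernel), fan_in=len(g) * kernel * kernel
            )
            b = np.zeros(self.fpg)
            self.weights.append(w)
            self.biases.append(b)
            self.params += [w, b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        outs = []
        self._windows = []
        k = self.kernel
        for g, w, b in zip(self.groups, self.weights, self.biases):
            xg = x[:, g, :, :]
            win = np.lib.stride_tricks.sliding_window_view(xg, (k, k), axis=(2, 3))
            self._windows.append(win)
            outs.append(
                np.einsum("nchwij,fcij->nfhw", win, w, optimize=True)
                + b[None, :, None, None]
            )
        return np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        dx = np.zeros_like(x)
        ho, wo = grad.shape[2], grad.shape[3]
        k = self.kernel
        for idx, (g, w) in enumerate(zip(self.groups, self.weights)):
            gslice = grad[:, idx * self.fpg : (idx + 1) * self.fpg, :, :]
            win = self._windows[idx]
            self.grads[2 * idx][...] = np.einsum("nchwij,nfhw->fcij", win, gslice, optimize=True)
            self.grads[2 * idx + 1][...] = gslice.sum(axis=(0, 2, 3))
            dxg = np.zeros((x.shape[0], len(g), x.shape[2], x.shape[3]))
            for i in range(k):
                for j in range(k):
                    dxg[:, :, i : i + ho, j : j + wo] += np.einsum(
                        "nfhw,fc->nchw", gslice, w[:, :, i, j], optimize=True
                    )
            dx[:, g, :, :] += dxg
        return dx


class MaxPool1d(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, t = x.shape
        to = t // self.size
        self._in_shape = x.shape
        xr = x[:, :, : to * self.size].reshape(n, c, to, self.size)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, t = self._in_shape
        to = grad.shape[2]
        dxr = np.zeros((n, c, to, self.size))
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=3)
        dx = np.zeros((n, c, t))
        dx[:, :, : to * self.size] = dxr.reshape(n, c, to * self.size)
        return dx


class MaxPool2d(Layer):
    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.size
        ho, wo = h // s, w // s
        self._in_shape = x.shape
        xr = (
            x[:, :, : ho * s, : wo * s]
            .reshape(n, c, ho, s, wo, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, ho, wo, s * s)
        )
        self._argmax = xr.argmax(axis=4)
        return xr.max(axis=4)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        s = self.size
        ho, wo = grad.shape[2], grad.shape[3]
        dxr = np.zeros((n, c, ho, wo, s * s))
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=4)
        dx = np.zeros((n, c, h, w))
        dx[:, :, : ho * s, : wo * s] = (
            dxr.reshape(n, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * s, wo * s)
        )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature axis (axis 1).

    Works for both (N, F) dense activations and (N, C, ...) conv maps.
    Running statistics are tracked for inference mode.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def _reshape(self, v: np.ndarray, ndim: int) -> np.ndarray:
        shape = [1] * ndim
        shape[1] = -1
        return v.reshape(shape)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(i for i in range(x.ndim) if i != 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._m = x.size // x.shape[1]
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - self._reshape(mean, x.ndim)) * self._reshape(self._inv_std, x.ndim)
        self._training = training
        return self._reshape(self.gamma, x.ndim) * self._xhat + self._reshape(self.beta, x.ndim)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        nd = grad.ndim
        self.grads[0][...] = (grad * self._xhat).sum(axis=self._axes)
        self.grads[1][...] = grad.sum(axis=self._axes)
        dxhat = grad * self._reshape(self.gamma, nd)
        if not self._training:
            return dxhat * self._reshape(self._inv_std, nd)
        m = self._m
        sum_dxhat = dxhat.sum(axis=self._axes)
        sum_dxhat_xhat = (dxhat * self._xhat).sum(axis=self._axes)
        return (
            self._reshape(self._inv_std, nd)
            / m
            * (
                m * dxhat
                - self._reshape(sum_dxhat, nd)
                - self._xhat * self._reshape(sum_dxhat_xhat, nd)
            )
        )


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = _he_normal(rng, (n_in, n_out), fan_in=n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Dropout(Layer):
    """Inverted dropout; a no-op in inference mode.  Mask randomness comes
    from the generator handed to :meth:`SequentialNet.forward`."""

    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        assert self.rng is not None, "dropout requires an rng in training mode"
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class SequentialNet:
    """A plain layer stack ending in logits (softmax applied by the loss)."""

    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out, axis=0)

    # -- parameter snapshots ------------------------------------------------
    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        k = 0
        for p in self.params:
            p[...] = state[k]
            k += 1
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[k].copy()
                layer.running_var = state[k + 1].copy()
                k += 2


class Adam:
    """Adam optimizer with (coupled) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
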