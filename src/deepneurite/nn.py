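"""Minimal seeded neural-network core backing the reference classifiers.

A compact, dependency-free implementation of the handful of layers the
toolbox needs — 2D valid convolution (im2col), 2×2 max pooling, ReLU and
dense layers — trained with Adam. Everything is a pure function of the
inputs and the integer seed: initialisation, shuffling and optimisation
draw from one ``numpy.random.Generator``, so retraining with the same
seed reproduces parameters bit for bit.

The networks here are deliberately small (CPU-trainable in seconds on
10^3–10^4 patches). Heavier architectures can be swapped in behind the
classifier contract in :mod:`deepneurite.patch_classifier`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "MaxPool2", "ReLU", "Flatten", "Dense", "Network", "Adam",
           "softmax", "cross_entropy_grad", "build_cnn"]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # caches for backward
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid 2D convolution, stride 1, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        fan_in = in_ch * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.ksize = ksize
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        # x: (N, C, H, W)
        k = self.ksize
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,Ho,Wo,k,k)
        N, C, Ho, Wo = win.shape[:4]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N, Ho * Wo, C * k * k)
        self._cols, self._xshape, self._hw = cols, x.shape, (Ho, Wo)
        out = cols @ self.W.T + self.b  # (N, Ho*Wo, F)
        return out.transpose(0, 2, 1).reshape(N, self.out_ch, Ho, Wo)

    def backward(self, g):
        N, F, Ho, Wo = g.shape
        k = self.ksize
        g2 = g.reshape(N, F, Ho * Wo).transpose(0, 2, 1)  # (N, P, F)
        self.dW[...] = np.einsum("npf,npc->fc", g2, self._cols)
        self.db[...] = g2.sum(axis=(0, 1))
        dcols = g2 @ self.W  # (N, P, C*k*k)
        dcols = dcols.reshape(N, Ho, Wo, self.in_ch, k, k)
        dx = np.zeros(self._xshape)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dx


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x):
        N, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : H2 * 2, : W2 * 2]
        r = xc.reshape(N, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(N, C, H2, W2, 4)
        self._idx = r.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        N, C, H, W = self._xshape
        H2, W2 = H // 2, W // 2
        dr = np.zeros((N, C, H2, W2, 4))
        np.put_along_axis(dr, self._idx[..., None], g[..., None], axis=-1)
        dx = np.zeros(self._xshape)
        dx[:, :, : H2 * 2, : W2 * 2] = (
            dr.reshape(N, C, H2, W2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H2 * 2, W2 * 2)
        )
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class Network:
    """A feed-forward stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p[...] = s

    def predict_batched(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        if len(x) == 0:
            n_out = self.layers[-1].b.shape[0] if isinstance(self.layers[-1], Dense) else 0
            return np.zeros((0, n_out))
        outs = [self.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n


def conv_output_dim(k: int, conv_sizes=(3, 3)) -> int:
    """Spatial dim after the conv/pool trunk used by :func:`build_cnn`."""
    d = k
    for cs in conv_sizes:
        d = (d - cs + 1) // 2
    return d


def build_cnn(k: int, n_out: int, rng: np.random.Generator,
              channels=(8, 16), hidden: int = 32) -> Network:
    """Reference architecture: two conv(3×3)+ReLU+pool blocks, then two
    dense layers. ``n_out`` is the logit/embedding width."""
    d = k
    layers: list[Layer] = []
    in_ch = 1
    for ch in channels:
        layers += [Conv2D(in_ch, ch, 3, rng), ReLU(), MaxPool2()]
        d = (d - 2) // 2
        in_ch = ch
    if d < 1:
        raise ValueError(f"patch size {k} too small for the conv trunk")
    layers += [Flatten(), Dense(in_ch * d * d, hidden, rng), ReLU(),
               Dense(hidden, n_out, rng)]
    return Network(layers)
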