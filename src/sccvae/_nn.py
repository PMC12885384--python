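"""Minimal feed-forward layers with hand-written backpropagation.

The model's neural components are small multilayer perceptrons; this module
implements them directly on numpy arrays with explicit forward caches and
reverse-mode gradients, plus an Adam optimizer. Gradients accumulate into
``Param.grad`` so a layer can be applied several times per step (e.g. the
decoder on both the control and the perturbed branch).

Correctness of every backward pass is pinned by finite-difference checks in
the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Param", "Dense", "MLP", "GaussianEncoder", "Adam"]


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        W = np.zeros((n_in, n_out)) if zero_init else _glorot(rng, n_in, n_out)
        self.W = Param(W)
        self.b = Param(np.zeros(n_out))

    def forward(self, x: np.ndarray):
        return x @ self.W.value + self.b.value, x

    def backward(self, g: np.ndarray, cache: np.ndarray) -> np.ndarray:
        self.W.grad += cache.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]


LEAK = 0.1


def _act(h: np.ndarray) -> np.ndarray:
    return np.where(h > 0, h, LEAK * h)


def _act_grad(a: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation output
    return np.where(a > 0, 1.0, LEAK)


class MLP:
    """Dense -> leaky-ReLU -> ... -> Dense (linear output), with an optional
    input->output linear skip path.

    The skip path lets the network express a dominant linear map exactly
    (normalized expression responds near-linearly to latent shifts); the
    leaky-ReLU body adds nonlinear corrections without saturating — a
    bounded activation would flatten (and stop gradients in) the regions
    far from the control cloud where strongly perturbed cells live.
    """

    def __init__(
        self,
        sizes: Sequence[int],
        rng: np.random.Generator,
        zero_init_last: bool = False,
        skip: bool = False,
        residual_body: bool = False,
    ):
        # residual_body: zero-init the body's output layer (skip keeps its
        # init), so the linear path learns the dominant map first and the
        # body only fits residual curvature — off-manifold inputs (strong
        # shifts) then keep the linear response instead of losing the
        # body's share of the signal
        self.layers = []
        for i in range(len(sizes) - 1):
            last = i == len(sizes) - 2
            zero = (zero_init_last or residual_body) and last
            self.layers.append(Dense(sizes[i], sizes[i + 1], rng, zero_init=zero))
        self.skip = Dense(sizes[0], sizes[-1], rng, zero_init=zero_init_last) if skip and len(sizes) > 2 else None

    def forward(self, x: np.ndarray):
        caches = []
        h = x
        for i, layer in enumerate(self.layers):
            h, c = layer.forward(h)
            if i < len(self.layers) - 1:
                h = _act(h)
                caches.append((c, h))  # keep activation output for its derivative
            else:
                caches.append((c, None))
        if self.skip is not None:
            s, sc = self.skip.forward(x)
            h = h + s
            caches.append(sc)
        return h, caches

    def backward(self, g: np.ndarray, caches) -> np.ndarray:
        g_out = g
        if self.skip is not None:
            self.skip.backward(g_out, caches[-1])
            caches = caches[: len(self.layers)]
        for i in range(len(self.layers) - 1, -1, -1):
            c, act = caches[i]
            g = self.layers[i].backward(g, c)
            if i > 0:
                # g is gradient w.r.t. the activation output of layer i-1
                g = g * _act_grad(caches[i - 1][1])
        if self.skip is not None:
            g = g + g_out @ self.skip.W.value.T
        return g

    @property
    def params(self) -> list[Param]:
        ps = [p for layer in self.layers for p in layer.params]
        if self.skip is not None:
            ps.extend(self.skip.params)
        return ps


class GaussianEncoder:
    """MLP trunk with (mean, log-variance) heads for a diagonal posterior.

    Both heads are zero-initialized so an untrained encoder maps any input
    to mean 0 and log-variance 0 (the standard-normal prior).
    """

    def __init__(self, n_in: int, hidden: Sequence[int], n_out: int, rng: np.random.Generator, skip: bool = False):
        self.trunk = MLP([n_in, *hidden], rng)
        self.head_mu = Dense(hidden[-1], n_out, rng, zero_init=True)
        self.head_lv = Dense(hidden[-1], n_out, rng, zero_init=True)
        # linear input->mean skip so the posterior mean is not bounded by
        # tanh saturation of the trunk
        self.skip_mu = Dense(n_in, n_out, rng, zero_init=True) if skip else None

    def forward(self, x: np.ndarray):
        h, trunk_caches = self.trunk.forward(x)
        h = _act(h)
        mu, c_mu = self.head_mu.forward(h)
        lv, c_lv = self.head_lv.forward(h)
        sc = None
        if self.skip_mu is not None:
            s, sc = self.skip_mu.forward(x)
            mu = mu + s
        return mu, lv, (trunk_caches, h, c_mu, c_lv, sc)

    def backward(self, g_mu: np.ndarray, g_lv: np.ndarray, cache) -> np.ndarray:
        trunk_caches, h, c_mu, c_lv, sc = cache
        g = self.head_mu.backward(g_mu, c_mu) + self.head_lv.backward(g_lv, c_lv)
        g = g * _act_grad(h)
        g = self.trunk.backward(g, trunk_caches)
        if self.skip_mu is not None:
            self.skip_mu.backward(g_mu, sc)
            g = g + g_mu @ self.skip_mu.W.value.T
        return g

    @property
    def params(self) -> list[Param]:
        ps = [*self.trunk.params, *self.head_mu.params, *self.head_lv.params]
        if self.skip_mu is not None:
            ps.extend(self.skip_mu.params)
        return ps


class Adam:
    """Adam with optional per-parameter-group learning rate and decoupled
    weight decay (set via ``add_group``)."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._lr = {}
        self._wd = {}

    def add_group(self, params: Sequence[Param], lr: float | None = None, weight_decay: float = 0.0) -> None:
        for p in params:
            if lr is not None:
                self._lr[id(p)] = lr
            if weight_decay:
                self._wd[id(p)] = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p in self.params:
            lr = self._lr.get(id(p), self.lr)
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            p.value -= lr * (p.m / corr1) / (np.sqrt(p.v / corr2) + self.eps)
            wd = self._wd.get(id(p))
            if wd:
                p.value -= lr * wd * p.value
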