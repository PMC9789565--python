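"""Minimal fully-connected networks with explicit backpropagation.

The counterfactual engine needs gradients that flow across several networks
in one update (critic -> actor, decoder -> actor, encoder -> decoder ->
actor), so ``forward`` returns an explicit cache and ``backward`` returns
both parameter gradients and the gradient with respect to the input.  All
state is numpy; optimisation is Adam.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a ** 2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(float)),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda a: a * (1.0 - a)),
}


class MLP:
    """Fully-connected network; Glorot-initialised, explicit-cache API."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 hidden: str = "tanh", out: str = "identity"):
        if len(sizes) < 2:
            raise TrainingError("MLP needs at least input and output sizes")
        self.sizes = list(sizes)
        self.hidden = hidden
        self.out = out
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def _activation(self, layer: int) -> tuple:
        name = self.out if layer == self.n_layers - 1 else self.hidden
        return _ACTIVATIONS[name]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns (output, cache); cache holds the input and activations."""
        h = np.atleast_2d(np.asarray(x, dtype=float))
        cache = [h]
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            act, _ = self._activation(layer)
            h = act(h @ w + b)
            cache.append(h)
        return h, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache: list[np.ndarray], grad_out: np.ndarray
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backpropagate ``grad_out`` (dL/d output) through the cached pass.

        Returns (dL/d input, [dW1, db1, dW2, db2, ...]).
        """
        grads: list[np.ndarray] = []
        g = np.atleast_2d(np.asarray(grad_out, dtype=float))
        for layer in range(self.n_layers - 1, -1, -1):
            _, dact = self._activation(layer)
            g = g * dact(cache[layer + 1])
            grads.append(g.sum(axis=0))              # db
            grads.append(cache[layer].T @ g)         # dW
            g = g @ self.weights[layer].T
        grads.reverse()
        return g, grads

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        return out


class Adam:
    """Adam optimiser over a fixed list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            if not np.all(np.isfinite(g)):
                raise TrainingError(f"non-finite gradient at step {self.t}")
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
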