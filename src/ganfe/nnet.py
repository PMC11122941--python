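"""Minimal feed-forward neural-network engine.

Dense layers, ReLU/LeakyReLU/sigmoid activations, batch normalization and an
Adam optimizer with L2-style weight decay, all in numpy with hand-written
backpropagation. Every network in this package (adversarial pair, prediction
MLP, embedding autoencoder) is built from these pieces, so training is fully
deterministic given a `numpy.random.Generator` and runs on a single CPU.

Layers are stateful: `forward` caches what `backward` needs, so a layer
instance must not be shared between models or called re-entrantly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "BatchNorm",
    "Sequential",
    "Adam",
    "bce_loss_and_grad",
]

EPS = 1e-12


class Layer:
    """Base class; subclasses implement forward/backward and expose params."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; empty for parameter-free layers."""
        return []


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init; fine for both ReLU and sigmoid-terminated stacks here
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out):
        self.dW[...] = self._x.T @ grad_out
        self.db[...] = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, self.alpha * grad_out)


class Sigmoid(Layer):
    def forward(self, x, training):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, grad_out):
        return grad_out * self._out * (1.0 - self._out)


class BatchNorm(Layer):
    """Batch normalization over the batch axis with running statistics.

    Training mode normalizes with batch moments and updates the running
    estimates; eval mode uses the running estimates, which makes frozen
    evaluation deterministic and independent of batch composition.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training):
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._batch_stats = training and x.shape[0] > 1
        return self.gamma * self._xhat + self.beta

    def backward(self, grad_out):
        self.dgamma[...] = (grad_out * self._xhat).sum(axis=0)
        self.dbeta[...] = grad_out.sum(axis=0)
        gx = grad_out * self.gamma
        if not self._batch_stats:
            return gx * self._istd
        n = grad_out.shape[0]
        # full batch-statistics gradient
        return (self._istd / n) * (
            n * gx - gx.sum(axis=0) - self._xhat * (gx * self._xhat).sum(axis=0)
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    # --- checkpoint helpers -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = []
        for layer in self.layers:
            for p, _ in layer.params():
                arrays.append(p)
            if isinstance(layer, BatchNorm):
                arrays.append(layer.running_mean)
                arrays.append(layer.running_var)
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match architecture")
        for dst, src in zip(own, arrays):
            if dst.shape != np.asarray(src).shape:
                raise ValueError("checkpoint array shape mismatch")
            dst[...] = src


class Adam:
    """Adam with L2 weight decay added to the gradient (coupled form)."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def bce_loss_and_grad(p: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross entropy and its gradient w.r.t. the probabilities.

    Probabilities at exactly 0 or 1 are clamped to [EPS, 1-EPS] before the
    logs so a saturated sigmoid cannot produce infinities.
    """
    p = np.clip(p, EPS, 1.0 - EPS)
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    grad = (p - y) / (p * (1.0 - p)) / p.size
    return loss, grad
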