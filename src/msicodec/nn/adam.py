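"""Adam optimizer with L2 weight decay (decay added to the raw gradient)."""

from __future__ import annotations

import numpy as np

from .layers import Sequential


class Adam:
    def __init__(self, model: Sequential, learning_rate: float = 1e-3,
                 weight_decay: float = 1e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        self.model = model
        self.lr = learning_rate
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for key, layer, name in self.model.parameter_items():
            grad = layer.grads[name]
            if self.weight_decay and name not in ("b", "beta"):
                grad = grad + self.weight_decay * layer.params[name]
            if key not in self._m:
                self._m[key] = np.zeros_like(grad)
                self._v[key] = np.zeros_like(grad)
            self._m[key] = b1 * self._m[key] + (1 - b1) * grad
            self._v[key] = b2 * self._v[key] + (1 - b2) * grad**2
            m_hat = self._m[key] / bc1
            v_hat = self._v[key] / bc2
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
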