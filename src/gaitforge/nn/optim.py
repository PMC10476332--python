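"""Per-parameter adaptive optimizers over Sequential models."""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .layers import Sequential


class _Optimizer:
    def __init__(self, model: Sequential, lr: float) -> None:
        self.model = model
        self.lr = lr
        self.t = 0
        self._state: List[Dict[str, Dict[str, np.ndarray]]] = [
            {k: self._init_state(v) for k, v in layer.params.items()}
            for layer in model.layers
        ]

    def _init_state(self, p: np.ndarray) -> Dict[str, np.ndarray]:
        raise NotImplementedError

    def _update(self, p, g, state) -> None:
        raise NotImplementedError

    def step(self) -> None:
        """Apply the gradients currently stored in each layer."""
        self.t += 1
        for layer, states in zip(self.model.layers, self._state):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                self._update(p, g, states[k])


class Adam(_Optimizer):
    def __init__(self, model, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        super().__init__(model, lr)

    def _init_state(self, p):
        return {"m": np.zeros_like(p), "v": np.zeros_like(p)}

    def _update(self, p, g, st):
        st["m"] = self.beta1 * st["m"] + (1 - self.beta1) * g
        st["v"] = self.beta2 * st["v"] + (1 - self.beta2) * g**2
        m_hat = st["m"] / (1 - self.beta1**self.t)
        v_hat = st["v"] / (1 - self.beta2**self.t)
        p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class RMSProp(_Optimizer):
    def __init__(self, model, lr=0.001, rho=0.9, eps=1e-7):
        self.rho, self.eps = rho, eps
        super().__init__(model, lr)

    def _init_state(self, p):
        return {"v": np.zeros_like(p)}

    def _update(self, p, g, st):
        st["v"] = self.rho * st["v"] + (1 - self.rho) * g**2
        p -= self.lr * g / (np.sqrt(st["v"]) + self.eps)
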