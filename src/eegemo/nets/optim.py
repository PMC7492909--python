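"""Adadelta and Adam, matching the common framework defaults.

Both update every trainable parameter in place from the gradients the most
recent backward pass left on the layers.  Hyperparameters beyond the
learning rate use the conventional defaults (Adadelta rho 0.95, Adam betas
0.9/0.999, epsilon 1e-7) and are recorded in configuration snapshots.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .network import Network


class Optimizer:
    def __init__(self, lr: float) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self._slots: Dict[Tuple[int, str], Dict[str, np.ndarray]] = {}

    def _slot(self, key: Tuple[int, str], arr: np.ndarray, names) -> Dict[str, np.ndarray]:
        if key not in self._slots:
            self._slots[key] = {n: np.zeros_like(arr) for n in names}
        return self._slots[key]

    def step(self, network: Network) -> None:
        raise NotImplementedError

    def hyperparameters(self) -> Dict[str, float]:
        raise NotImplementedError


class Adadelta(Optimizer):
    def __init__(self, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.rho = rho
        self.eps = eps

    def step(self, network: Network) -> None:
        for i, name, grad in network.grad_items():
            param = network.layers[i].params[name]
            s = self._slot((i, name), param, ("acc_g", "acc_d"))
            s["acc_g"] *= self.rho
            s["acc_g"] += (1.0 - self.rho) * grad * grad
            delta = np.sqrt(s["acc_d"] + self.eps) / np.sqrt(s["acc_g"] + self.eps) * grad
            s["acc_d"] *= self.rho
            s["acc_d"] += (1.0 - self.rho) * delta * delta
            param -= self.lr * delta

    def hyperparameters(self):
        return {"optimizer": "adadelta", "lr": self.lr, "rho": self.rho, "eps": self.eps}


class Adam(Optimizer):
    def __init__(
        self, lr: float = 0.001, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7
    ) -> None:
        super().__init__(lr)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._t = 0

    def step(self, network: Network) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for i, name, grad in network.grad_items():
            param = network.layers[i].params[name]
            s = self._slot((i, name), param, ("m", "v"))
            s["m"] *= self.beta1
            s["m"] += (1.0 - self.beta1) * grad
            s["v"] *= self.beta2
            s["v"] += (1.0 - self.beta2) * grad * grad
            param -= self.lr * (s["m"] / b1t) / (np.sqrt(s["v"] / b2t) + self.eps)

    def hyperparameters(self):
        return {
            "optimizer": "adam",
            "lr": self.lr,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "eps": self.eps,
        }
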