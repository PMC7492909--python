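"""Central-finite-difference gradient verification.

The independent oracle for the analytic backward passes: perturb every
parameter by +/- eps, evaluate the scalar loss, and compare the resulting
numeric gradient to the one backpropagation produced.  Only meaningful on
small networks (the cost is two loss evaluations per parameter).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .network import Network


def finite_difference_grads(
    network: Network, loss_fn: Callable[[], float], eps: float = 1e-5
) -> np.ndarray:
    """Numeric gradient of ``loss_fn()`` w.r.t. every network parameter."""
    flat = network.get_flat_params().copy()
    grad = np.empty_like(flat)
    for j in range(flat.size):
        orig = flat[j]
        flat[j] = orig + eps
        network.set_flat_params(flat)
        up = loss_fn()
        flat[j] = orig - eps
        network.set_flat_params(flat)
        down = loss_fn()
        flat[j] = orig
        grad[j] = (up - down) / (2.0 * eps)
    network.set_flat_params(flat)
    return grad


def relative_gradient_error(analytic: np.ndarray, numeric: np.ndarray) -> float:
    """max_j |a_j - n_j| / max(1e-8, |a_j| + |n_j|), the usual gradcheck metric."""
    denom = np.maximum(1e-8, np.abs(analytic) + np.abs(numeric))
    return float(np.max(np.abs(analytic - numeric) / denom))
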