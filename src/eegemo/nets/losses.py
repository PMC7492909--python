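"""Crossentropy losses and the sparse-autoencoder penalty.

Conventions fixed here and relied on everywhere else:

- predicted probabilities are clipped to [EPS, 1 - EPS] before any log;
- binary crossentropy averages over every element (samples x units), the
  Keras convention, so a scalar target/prediction pair gives the textbook
  value (-log 0.5 = ln 2 at p = 0.5);
- categorical crossentropy averages the per-sample term -sum_c y_c log p_c
  over samples;
- the sparsity penalty is the Bernoulli KL divergence
  KL(rho || rho_hat_j) = rho log(rho/rho_hat_j)
                       + (1 - rho) log((1 - rho)/(1 - rho_hat_j)),
  summed over hidden units, with per-unit mean activations rho_hat clipped
  into (EPS, 1 - EPS) first so rectified activations stay in the KL domain.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def binary_crossentropy(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean over all elements of -[y log p + (1-y) log(1-p)]."""
    y = np.asarray(y, dtype=float)
    p = _clip(np.asarray(yhat, dtype=float))
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.shape}")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def categorical_crossentropy(y: np.ndarray, yhat: np.ndarray, atol: float = 1e-5) -> float:
    """Mean over samples of -sum_c y_c log p_c for one-hot rows y."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    p = np.atleast_2d(np.asarray(yhat, dtype=float))
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {p.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=atol):
        raise ValueError("prediction rows must lie on the probability simplex")
    return float(-np.mean(np.sum(y * np.log(_clip(p)), axis=1)))


def mean_activation(h: np.ndarray, clip: bool = True) -> np.ndarray:
    """Per-unit mean activation rho_hat over a (batch, units) matrix."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[0] < 1 or h.size == 0:
        raise ValueError("empty batch")
    rho_hat = h.mean(axis=0)
    return _clip(rho_hat) if clip else rho_hat


def kl_bernoulli(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    """KL divergence between Bernoulli(rho) and Bernoulli(rho_hat), elementwise."""
    rho_hat = np.asarray(rho_hat, dtype=float)
    if not (0.0 < rho < 1.0) or np.any(rho_hat <= 0.0) or np.any(rho_hat >= 1.0):
        raise ValueError("rho and rho_hat must lie strictly inside (0, 1)")
    return rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))


def sparse_cost(recon_loss: float, rho_hat: np.ndarray, rho: float, beta: float) -> float:
    """Total autoencoder cost: reconstruction loss + beta * sum_j KL."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return float(recon_loss)
    return float(recon_loss + beta * kl_bernoulli(rho, rho_hat).sum())
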