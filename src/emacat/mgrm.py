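"""Forward computations of the multidimensional graded response model (MGRM).

The MGRM drives everything downstream: category probabilities for response
simulation and likelihoods, and per-item Fisher information for D-optimal
item selection and the precision-based stopping rule.

Model.  For an item with discrimination vector a (length m) and strictly
decreasing intercepts d_1 > ... > d_4, the boundary ("at or above category
k+1") probabilities follow cumulative logits

    P*_k(theta) = logistic(a . theta + d_k),   k = 1..K-1,

with P*_0 = 1 and P*_K = 0, and category probabilities
p_k = P*_{k-1} - P*_k for k = 1..K (K = 5).  The logistic link uses scaling
constant D = 1 (no 1.7 normal-ogive approximation); parameters calibrated
under a different convention must be rescaled before import.

The expected (Fisher) information of one item is rank <= 1:

    I_j(theta) = g_j(theta) a a^T,
    g_j = sum_k (w_{k-1} - w_k)^2 / p_k,   w_k = P*_k (1 - P*_k),

with w_0 = w_K = 0.  Probabilities are floored at 1e-10 inside information
and log-likelihood computations so extreme theta cannot blow up divisions.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.special import expit

from .bank import ItemBank, ItemParameters, N_CATEGORIES

#: Floor applied to category probabilities inside information and
#: log-likelihood computations.
PROB_FLOOR = 1e-10


def cumulative_probabilities(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """Boundary probabilities (P*_0 .. P*_K), length K + 1."""
    theta = np.asarray(theta, dtype=float)
    x = float(item.a @ theta)
    return np.concatenate(([1.0], expit(x + item.d), [0.0]))


def category_probabilities(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """Probabilities of responses 1..K at ``theta``; sums to 1."""
    cum = cumulative_probabilities(item, theta)
    return np.maximum(-np.diff(cum), 0.0)


def response_loglik(
    bank: ItemBank, responses: Mapping[str, int], theta: np.ndarray
) -> float:
    """Log-likelihood sum over a response map {item_id: category in 1..K}."""
    theta = np.asarray(theta, dtype=float)
    total = 0.0
    for item_id, y in responses.items():
        if not 1 <= y <= N_CATEGORIES:
            raise ValueError(f"response {y} for item {item_id!r} outside 1..{N_CATEGORIES}")
        p = category_probabilities(bank.item(item_id), theta)
        total += float(np.log(max(p[y - 1], PROB_FLOOR)))
    return total


def information_scalar(x: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Scalar information factor g at linear predictor(s) x = a . theta.

    Vectorized over a leading batch axis: ``x`` shape (...,), ``d`` shape
    (..., K-1) or (K-1,).  Returns g with shape (...,).
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    cum = expit(x[..., None] + d)
    shape = x.shape + (1,)
    cum = np.concatenate(
        [np.ones(shape), np.broadcast_to(cum, x.shape + (d.shape[-1],)), np.zeros(shape)],
        axis=-1,
    )
    p = np.maximum(-np.diff(cum, axis=-1), PROB_FLOOR)
    w = cum * (1.0 - cum)  # w_0 = w_K = 0 automatically
    dw = w[..., :-1] - w[..., 1:]
    return np.sum(dw * dw / p, axis=-1)


def item_information(item: ItemParameters, theta: np.ndarray) -> np.ndarray:
    """Expected Fisher information matrix g(theta) a a^T (m x m, PSD, rank <= 1)."""
    theta = np.asarray(theta, dtype=float)
    g = float(information_scalar(np.array(item.a @ theta), item.d))
    return g * np.outer(item.a, item.a)


def total_information(bank: ItemBank, item_ids, theta: np.ndarray) -> np.ndarray:
    """Sum of item information over ``item_ids`` at ``theta`` (exact linearity)."""
    theta = np.asarray(theta, dtype=float)
    m = bank.n_domains
    total = np.zeros((m, m))
    for iid in item_ids:
        total += item_information(bank.item(iid), theta)
    return total
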