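"""Scaled forward–backward for small hidden-state spaces.

Both HMMs in this package (HBD tract detection, archaic local ancestry) use
hand-parameterized chains with position-dependent transition matrices —
transition probabilities depend on the genetic distance between consecutive
observations — so a fixed-matrix HMM library does not apply. The chains are
short (thousands of steps, 2–3 states), so a plain scaled recursion in
float64 is both exact enough and fast enough.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np


def forward_backward(
    emissions: np.ndarray,
    transitions: np.ndarray,
    init: np.ndarray,
) -> Tuple[np.ndarray, float]:
    """Posterior state marginals and log-likelihood.

    Parameters
    ----------
    emissions : (n, K) emission likelihoods P(obs_t | state).
    transitions : (n-1, K, K) or (K, K) transition matrices; row-stochastic,
        ``transitions[t, i, j] = P(state_{t+1}=j | state_t=i)``.
    init : (K,) initial state distribution.

    Returns
    -------
    (posteriors, loglik) with posteriors of shape (n, K); rows sum to 1.
    """
    e = np.asarray(emissions, dtype=float)
    n, K = e.shape
    if n == 0:
        return np.zeros((0, K)), 0.0
    T = np.asarray(transitions, dtype=float)
    homogeneous = T.ndim == 2

    alpha = np.empty((n, K))
    scale = np.empty(n)
    a = init * e[0]
    scale[0] = a.sum()
    if scale[0] == 0:
        raise ValueError("zero likelihood at first observation")
    alpha[0] = a / scale[0]
    for t in range(1, n):
        Tt = T if homogeneous else T[t - 1]
        a = (alpha[t - 1] @ Tt) * e[t]
        scale[t] = a.sum()
        if scale[t] == 0:
            raise ValueError(f"zero likelihood at observation {t}")
        alpha[t] = a / scale[t]

    beta = np.empty((n, K))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        Tt = T if homogeneous else T[t]
        beta[t] = (Tt @ (e[t + 1] * beta[t + 1])) / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.log(scale).sum())


def expected_transitions(
    emissions: np.ndarray,
    transitions: np.ndarray,
    init: np.ndarray,
) -> np.ndarray:
    """Expected transition counts xi summed over steps, (K, K).

    Used for one-round EM updates of transition intensities.
    """
    e = np.asarray(emissions, dtype=float)
    n, K = e.shape
    T = np.asarray(transitions, dtype=float)
    homogeneous = T.ndim == 2

    # recompute alpha/beta (duplicated with forward_backward, but keeps the
    # public functions independent and the chains are short)
    alpha = np.empty((n, K))
    scale = np.empty(n)
    a = init * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        Tt = T if homogeneous else T[t - 1]
        a = (alpha[t - 1] @ Tt) * e[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    beta = np.empty((n, K))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        Tt = T if homogeneous else T[t]
        beta[t] = (Tt @ (e[t + 1] * beta[t + 1])) / scale[t + 1]

    xi_sum = np.zeros((K, K))
    for t in range(n - 1):
        Tt = T if homogeneous else T[t]
        xi = (alpha[t][:, None] * Tt) * (e[t + 1] * beta[t + 1])[None, :]
        xi_sum += xi / scale[t + 1]
    return xi_sum
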