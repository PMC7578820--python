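"""Linear-chain CRF primitives: partition function, marginals, Viterbi.

Scores are additive: a path y_1..y_T scores
``sum_t emissions[t, y_t] + sum_t transitions[y_{t-1}, y_t]``.
All functions operate on plain numpy arrays so they can be checked against
exhaustive enumeration at small sizes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "crf_log_partition",
    "viterbi_decode",
    "crf_marginals",
    "path_score",
]


def _check(emissions: np.ndarray, transitions: np.ndarray) -> tuple[int, int]:
    emissions = np.asarray(emissions)
    transitions = np.asarray(transitions)
    if emissions.ndim != 2:
        raise ValueError(f"emissions must be 2-D, got shape {emissions.shape}")
    if emissions.shape[0] == 0:
        raise ValueError("empty sequence")
    k = emissions.shape[1]
    if transitions.shape != (k, k):
        raise ValueError(
            f"transitions shape {transitions.shape} does not match {k} labels"
        )
    return emissions.shape[0], k


def path_score(
    emissions: np.ndarray, transitions: np.ndarray, labels: np.ndarray
) -> float:
    """Additive score of one label sequence."""
    _check(emissions, transitions)
    labels = np.asarray(labels)
    score = float(emissions[np.arange(len(labels)), labels].sum())
    if len(labels) > 1:
        score += float(transitions[labels[:-1], labels[1:]].sum())
    return score


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all label sequences of exp(path score)."""
    T, _ = _check(emissions, transitions)
    alpha = np.asarray(emissions, dtype=float)[0].copy()
    for t in range(1, T):
        alpha = logsumexp(alpha[:, None] + transitions, axis=0) + emissions[t]
    return float(logsumexp(alpha))


def viterbi_decode(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[list[int], float]:
    """Maximal-score label sequence.

    Ties are broken toward the lexicographically smallest label-index
    sequence (computed via a backward max-to-go table and a greedy forward
    pass that prefers the smallest index among maximisers).
    """
    T, K = _check(emissions, transitions)
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    # beta[t, j]: best score of a path suffix starting at t in label j,
    # excluding emissions[t] itself? include it for convenience:
    beta = np.zeros((T, K))
    beta[T - 1] = emissions[T - 1]
    for t in range(T - 2, -1, -1):
        beta[t] = emissions[t] + (transitions + beta[t + 1][None, :]).max(axis=1)
    labels = [int(np.argmax(beta[0]))]  # argmax takes the first (smallest) index
    for t in range(1, T):
        prev = labels[-1]
        labels.append(int(np.argmax(transitions[prev] + beta[t])))
    return labels, float(beta[0].max())


def crf_marginals(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Unary (T, K) and pairwise (T-1, K, K) marginals plus log-partition.

    The unary marginals are the gradient of the log-partition with respect
    to the emissions; the summed pairwise marginals are its gradient with
    respect to the transitions.
    """
    T, K = _check(emissions, transitions)
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    alpha = np.zeros((T, K))
    alpha[0] = emissions[0]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + transitions, axis=0) + emissions[t]
    beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(transitions + (emissions[t + 1] + beta[t + 1])[None, :], axis=1)
    log_z = float(logsumexp(alpha[-1]))
    unary = np.exp(alpha + beta - log_z)
    pairwise = np.zeros((max(T - 1, 0), K, K))
    for t in range(T - 1):
        m = (
            alpha[t][:, None]
            + transitions
            + (emissions[t + 1] + beta[t + 1])[None, :]
            - log_z
        )
        pairwise[t] = np.exp(m)
    return unary, pairwise, log_z
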