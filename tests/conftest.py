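"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive quantities by the most
literal route available (explicit loops, exhaustive enumeration) so they stay
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from netenhance import WeightedNetwork


@pytest.fixture
def random_network_factory():
    """Factory for random symmetric non-negative networks with zero diagonal."""

    def make(n: int, seed: int, density: float = 1.0) -> WeightedNetwork:
        rng = np.random.default_rng(seed)
        W = rng.random((n, n))
        if density < 1.0:
            W[rng.random((n, n)) > density] = 0.0
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        return WeightedNetwork(W)

    return make


# ---------------------------------------------------------------------------
# oracles


def knn_transition_oracle(W: np.ndarray, k: int) -> np.ndarray:
    """Literal top-k-and-normalize: self forced in, ties by ascending index."""
    n = W.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        candidates = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (-W[i, j], j),
        )
        nbrs = [i] + candidates[: k - 1]
        denom = sum(W[i, j] for j in nbrs)
        if denom > 0:
            for j in nbrs:
                P[i, j] = W[i, j] / denom
        else:
            P[i, i] = 1.0
    return P


def localized_dsm_oracle(P: np.ndarray) -> np.ndarray:
    """Direct triple-loop summation of T_ij = sum_k P_ik P_jk / sum_v P_vk."""
    n = P.shape[0]
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(n):
                col = sum(P[v, k] for v in range(n))
                if col > 0:
                    acc += P[i, k] * P[j, k] / col
            T[i, j] = acc
    return T


def entrywise_diffusion_oracle(T: np.ndarray, W: np.ndarray, alpha: float) -> np.ndarray:
    """Verbatim entrywise double-sum update a*sum_kl T_ik W_kl T_lj + (1-a) T_ij.

    The neighborhood restriction of the entrywise form is vacuous: terms with
    a node outside the operator's support vanish because the corresponding
    operator entry is zero, so the full double sum is the literal evaluation.
    """
    n = T.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(n):
                for l in range(n):
                    acc += T[i, k] * W[k, l] * T[l, j]
            out[i, j] = alpha * acc + (1.0 - alpha) * T[i, j]
    return out


def nmi_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Contingency-table NMI (geometric normalization) with explicit loops."""
    n = len(a)
    labels_a = sorted(set(a))
    labels_b = sorted(set(b))
    counts = {(x, y): 0 for x in labels_a for y in labels_b}
    for x, y in zip(a, b):
        counts[(x, y)] += 1
    mi = 0.0
    for x in labels_a:
        for y in labels_b:
            nxy = counts[(x, y)]
            if nxy == 0:
                continue
            nx = sum(counts[(x, yy)] for yy in labels_b)
            ny = sum(counts[(xx, y)] for xx in labels_a)
            mi += (nxy / n) * math.log(n * nxy / (nx * ny))
    h_a = -sum(
        (nx / n) * math.log(nx / n)
        for x in labels_a
        if (nx := sum(counts[(x, y)] for y in labels_b)) > 0
    )
    h_b = -sum(
        (ny / n) * math.log(ny / n)
        for y in labels_b
        if (ny := sum(counts[(x, y)] for x in labels_a)) > 0
    )
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    return mi / math.sqrt(h_a * h_b)


def auroc_oracle(scores: np.ndarray, pos: list[int], neg: list[int]) -> float:
    """Exhaustive positive-negative pair enumeration, ties worth one half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if scores[p] > scores[q]:
                wins += 1.0
            elif scores[p] == scores[q]:
                wins += 0.5
    return wins / (len(pos) * len(neg))
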