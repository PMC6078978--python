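"""Downstream metrics that quantify what denoising buys.

A denoised network is only as good as the analyses it feeds. This module
implements the standard yardsticks: random walk with restart (RWR) label
propagation for node scoring, normalized mutual information (NMI) between
node partitions, top-m retrieval accuracy for labeled similarity networks,
rank-based AUROC, subnetwork edge density, a leave-one-out propagation
harness, and a thin wrapper over Louvain community detection.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.stats import rankdata

from .network import ValidationError, WeightedNetwork

__all__ = [
    "CommunityLabels",
    "PropagationScores",
    "rwr_propagate",
    "nmi",
    "retrieval_accuracy",
    "subnetwork_edge_density",
    "auroc",
    "leave_one_out_auroc",
    "detect_communities",
]


@dataclass
class CommunityLabels:
    """Integer community assignment per node, aligned with a network's node order."""

    assignments: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments)
        if a.ndim != 1:
            raise ValidationError("assignments must be a 1-D integer array")
        self.assignments = a.astype(int)
        if self.node_ids and len(self.node_ids) != a.size:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for {a.size} assignments"
            )

    @property
    def n(self) -> int:
        return self.assignments.size


@dataclass
class PropagationScores:
    """RWR stationary distribution: non-negative per-node scores summing to 1."""

    scores: np.ndarray
    restart_prob: float
    seeds: np.ndarray


def _resolve_nodes(net: WeightedNetwork, nodes: Iterable) -> np.ndarray:
    """Map node ids or integer indices to sorted unique integer indices."""
    out = []
    for x in nodes:
        if isinstance(x, (int, np.integer)):
            if not 0 <= int(x) < net.n_nodes:
                raise ValidationError(f"node index {x} out of range")
            out.append(int(x))
        else:
            out.append(net.index_of(str(x)))
    if not out:
        raise ValidationError("empty node subset")
    return np.unique(out)


def rwr_propagate(
    net: WeightedNetwork,
    seeds: Iterable,
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> PropagationScores:
    """Random walk with restart from a seed set.

    Computes the stationary distribution of
    ``s <- (1 - r) P.T s + r u`` where ``P`` is the row-normalized walk
    matrix of the network and ``u`` is uniform over the seeds. At each step
    the walker follows an edge with probability proportional to its weight
    or teleports back to the seeds with probability ``r``; the stationary
    visitation probability scores each node's relevance to the seed set.
    Zero-degree nodes teleport unconditionally.
    """
    if not 0.0 < restart_prob < 1.0:
        raise ValidationError(f"restart_prob must lie in (0, 1), got {restart_prob}")
    W = net.weights
    d = W.sum(axis=1)
    seed_idx = _resolve_nodes(net, seeds)
    if net.n_nodes == 1:
        # degenerate single-node network: all mass sits on the lone seed
        return PropagationScores(scores=np.array([1.0]), restart_prob=restart_prob, seeds=seed_idx)
    if not np.any(d > 0):
        raise ValidationError("network has no edges; nothing to propagate on")

    n = net.n_nodes
    P = np.zeros_like(W)
    pos = d > 0
    P[pos] = W[pos] / d[pos, None]
    # zero-degree rows: all mass teleports; row of zeros + restart handles it
    u = np.zeros(n)
    u[seed_idx] = 1.0 / seed_idx.size

    s = u.copy()
    r = restart_prob
    for _ in range(max_iter):
        # dangling mass (zero-degree rows) is redirected to the seeds
        dangling = s[~pos].sum()
        s_next = (1.0 - r) * (P.T @ s + dangling * u) + r * u
        if np.abs(s_next - s).sum() < tol:
            s = s_next
            break
        s = s_next
    s = np.clip(s, 0.0, None)
    s /= s.sum()
    return PropagationScores(scores=s, restart_prob=restart_prob, seeds=seed_idx)


def nmi(a: CommunityLabels, b: CommunityLabels, normalization: str = "geometric") -> float:
    """Normalized mutual information between two partitions of the same nodes.

    ``I(a; b)`` from the joint contingency table with natural logarithms,
    normalized by ``sqrt(H(a) * H(b))`` (default) or by the arithmetic mean
    ``(H(a) + H(b)) / 2``. Returns a value in [0, 1]; 1 means the partitions
    agree up to relabeling. Two single-cluster partitions count as a perfect
    match.
    """
    if a.n != b.n:
        raise ValidationError(f"partitions cover {a.n} vs {b.n} nodes")
    if a.node_ids and b.node_ids and a.node_ids != b.node_ids:
        raise ValidationError("partitions are over different node sets")
    if normalization not in ("geometric", "arithmetic"):
        raise ValidationError(f"unknown normalization {normalization!r}")

    n = a.n
    _, ai = np.unique(a.assignments, return_inverse=True)
    _, bi = np.unique(b.assignments, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(contingency, (ai, bi), 1.0)
    pij = contingency / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)

    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])))
    h_a = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    h_b = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))

    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    denom = np.sqrt(h_a * h_b) if normalization == "geometric" else (h_a + h_b) / 2.0
    return float(np.clip(mi / denom, 0.0, 1.0))


def retrieval_accuracy(net: WeightedNetwork, labels: CommunityLabels, top_m: int) -> float:
    """Mean fraction of each query's top-m strongest neighbors sharing its label.

    Every node serves as a query; the other nodes are ranked by descending
    edge weight to the query, ties broken by ascending node index.
    """
    n = net.n_nodes
    if labels.n != n:
        raise ValidationError(f"{labels.n} labels for {n} nodes")
    if not 1 <= top_m <= n - 1:
        raise ValidationError(f"top_m must lie in [1, {n - 1}], got {top_m}")
    W = net.weights
    y = labels.assignments
    hits = np.empty(n)
    for i in range(n):
        w = np.delete(W[i], i)
        others = np.delete(np.arange(n), i)
        order = np.argsort(-w, kind="stable")  # stable: ascending index on ties
        top = others[order[:top_m]]
        hits[i] = np.mean(y[top] == y[i])
    return float(hits.mean())


def subnetwork_edge_density(net: WeightedNetwork, members: Iterable) -> float:
    """Total weight among the members over the number of possible member pairs.

    ``sum_{i<j in members} W_ij / (m * (m - 1) / 2)``; for a fully connected
    unit-weight subnetwork this is 1.
    """
    idx = _resolve_nodes(net, members)
    m = idx.size
    if m < 2:
        raise ValidationError(f"need at least 2 members, got {m}")
    sub = net.weights[np.ix_(idx, idx)]
    total = float(np.triu(sub, k=1).sum())
    return total / (m * (m - 1) / 2.0)


def auroc(
    scores: Sequence[float],
    positives: Iterable[int],
    negatives: Iterable[int] | None = None,
) -> float:
    """Rank-based (Mann–Whitney) AUROC with midrank tie handling.

    The probability that a uniformly drawn positive outscores a uniformly
    drawn negative, ties counting one half. When ``negatives`` is omitted,
    every non-positive node is a negative.
    """
    s = np.asarray(scores, dtype=float)
    pos = np.unique(np.asarray(list(positives), dtype=int))
    if negatives is None:
        neg = np.setdiff1d(np.arange(s.size), pos)
    else:
        neg = np.unique(np.asarray(list(negatives), dtype=int))
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("positives and negatives must both be non-empty")
    if np.intersect1d(pos, neg).size:
        raise ValidationError("positives and negatives must be disjoint")
    both = np.concatenate([s[pos], s[neg]])
    ranks = rankdata(both)  # midranks
    r_pos = ranks[: pos.size].sum()
    n_p, n_n = pos.size, neg.size
    u = r_pos - n_p * (n_p + 1) / 2.0
    return float(u / (n_p * n_n))


def leave_one_out_auroc(
    net: WeightedNetwork,
    positives: Iterable,
    restart_prob: float = 0.5,
    n_negatives: int | None = None,
    seed: int = 0,
) -> float:
    """Leave-one-out propagation benchmark.

    Each positive node is held out in turn; the remaining positives seed an
    RWR, and the held-out node's score is ranked against (optionally
    sampled) negative nodes via AUROC. Returns the mean AUROC over held-out
    positives. Deterministic given ``seed``.
    """
    pos = _resolve_nodes(net, positives)
    if pos.size < 2:
        raise ValidationError("need at least 2 positives for leave-one-out")
    rng = np.random.default_rng(seed)
    all_neg = np.setdiff1d(np.arange(net.n_nodes), pos)
    if all_neg.size == 0:
        raise ValidationError("no negative nodes available")
    aurocs = []
    for p in pos:
        train = pos[pos != p]
        scores = rwr_propagate(net, train, restart_prob).scores
        neg = all_neg
        if n_negatives is not None and n_negatives < all_neg.size:
            neg = rng.choice(all_neg, size=n_negatives, replace=False)
        aurocs.append(auroc(scores, [int(p)], neg))
    return float(np.mean(aurocs))


def detect_communities(
    net: WeightedNetwork,
    seed: int = 0,
    resolution: float = 1.0,
) -> CommunityLabels:
    """Louvain modularity communities of the weighted network (via networkx)."""
    G = nx.from_numpy_array(net.weights)
    parts = nx.community.louvain_communities(G, weight="weight", seed=seed, resolution=resolution)
    assign = np.empty(net.n_nodes, dtype=int)
    for cid, nodes in enumerate(parts):
        assign[list(nodes)] = cid
    return CommunityLabels(assignments=assign, node_ids=list(net.node_ids))
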