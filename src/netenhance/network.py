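"""Core container for undirected weighted networks.

A network over ``n`` nodes is a symmetric, non-negative ``n x n`` weight
matrix together with an ordered list of string node identifiers. Weights are
dimensionless similarity or interaction strengths; a zero entry means "no
edge". All downstream operators (KNN transition matrices, doubly stochastic
diffusion, propagation) consume this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WeightedNetwork", "ValidationError"]

#: asymmetry above this triggers a warning when symmetrizing on construction
SYMMETRY_WARN_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input matrix or label set violates a structural contract."""


def _default_ids(n: int) -> list[str]:
    width = len(str(max(n - 1, 0)))
    return [f"n{str(i).zfill(width)}" for i in range(n)]


@dataclass
class WeightedNetwork:
    """Symmetric non-negative weight matrix with node identifiers.

    Parameters
    ----------
    weights:
        ``n x n`` array of non-negative, finite edge weights. Symmetrized on
        construction via ``(W + W.T) / 2``; asymmetry beyond
        ``SYMMETRY_WARN_TOL`` emits a warning, negatives are a hard error.
    node_ids:
        Ordered unique string identifiers, one per node. Defaults to
        ``n0, n1, ...``.
    """

    weights: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError(f"weight matrix must be square, got shape {W.shape}")
        if W.shape[0] < 1:
            raise ValidationError("network must have at least one node")
        if not np.all(np.isfinite(W)):
            bad = np.argwhere(~np.isfinite(W))[:5]
            raise ValidationError(f"non-finite weights at entries {bad.tolist()}")
        neg = W < 0
        if neg.any():
            bad = np.argwhere(neg)[:5]
            raise ValidationError(
                f"negative weights at entries {bad.tolist()}; "
                "weights must be non-negative"
            )
        asym = np.abs(W - W.T).max() if W.size else 0.0
        if asym > SYMMETRY_WARN_TOL:
            warnings.warn(
                f"input matrix asymmetric (max |W-W.T| = {asym:.3g}); "
                "symmetrizing as (W + W.T)/2",
                stacklevel=2,
            )
        self.weights = (W + W.T) / 2.0
        n = W.shape[0]
        if not self.node_ids:
            self.node_ids = _default_ids(n)
        else:
            self.node_ids = [str(x) for x in self.node_ids]
        if len(self.node_ids) != n:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for {n} nodes"
            )
        if len(set(self.node_ids)) != n:
            raise ValidationError("node ids must be unique")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def degrees(self) -> np.ndarray:
        """Weighted degree of each node, ``d_i = sum_j W_ij``."""
        return self.weights.sum(axis=1)

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise ValidationError(f"unknown node id: {node_id!r}") from None

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.weights.copy(), list(self.node_ids))
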