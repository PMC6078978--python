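"""Readers and writers for networks, labels, seeds, scores and config files.

Three interchangeable network formats are supported:

* ``edgelist`` — TSV ``node_a<TAB>node_b<TAB>weight``, undirected, duplicate
  pairs summed;
* ``dense`` — full matrix TSV with a header row and leading column of node
  ids;
* ``mtx`` — MatrixMarket sparse coordinate text (1-based indices by
  convention; a 0-based variant is accepted via the dialect).

Node identity is string-based and node ids are sorted lexicographically on
read (edge lists), so outputs are stable across runs and platforms. All
readers symmetrize via ``(W + W.T) / 2`` and reject negative weights.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .evaluation import CommunityLabels
from .network import ValidationError, WeightedNetwork

__all__ = [
    "NetworkFileDialect",
    "infer_format",
    "read_network",
    "write_network",
    "read_labels",
    "write_labels",
    "read_seeds",
    "write_scores",
    "read_config",
]

#: weights at or below this are dropped from sparse outputs
SPARSE_ZERO_TOL = 1e-12


@dataclass
class NetworkFileDialect:
    format: str = "edgelist"  # edgelist | dense | mtx
    delimiter: str = "\t"
    indexing: str = "1-based"  # mtx only
    has_header: bool = True  # dense only

    def __post_init__(self) -> None:
        if self.format not in ("edgelist", "dense", "mtx"):
            raise ValidationError(f"unknown network format {self.format!r}")
        if self.indexing not in ("0-based", "1-based"):
            raise ValidationError(f"unknown indexing {self.indexing!r}")


def infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix in (".mat", ".dense"):
        return "dense"
    return "edgelist"


# ---------------------------------------------------------------------------
# network readers


def read_network(path: str | Path, dialect: NetworkFileDialect | None = None) -> WeightedNetwork:
    dialect = dialect or NetworkFileDialect(format=infer_format(path))
    path = Path(path)
    if dialect.format == "edgelist":
        return _read_edgelist(path, dialect)
    if dialect.format == "dense":
        return _read_dense(path, dialect)
    return _read_mtx(path, dialect)


def _read_edgelist(path: Path, dialect: NetworkFileDialect) -> WeightedNetwork:
    edges: list[tuple[str, str, float]] = []
    nodes: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(dialect.delimiter)
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'node_a node_b weight', got {line!r}"
                )
            a, b, w_str = parts
            try:
                w = float(w_str)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric weight {w_str!r}") from None
            if w < 0:
                raise ValidationError(f"{path}:{lineno}: negative weight {w}")
            edges.append((a, b, w))
            nodes.update((a, b))
    if not nodes:
        raise ValidationError(f"{path}: no edges found")
    ids = sorted(nodes)
    idx = {v: i for i, v in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)))
    for a, b, w in edges:  # duplicates (either orientation) summed
        i, j = idx[a], idx[b]
        W[i, j] += w
        if i != j:
            W[j, i] += w
    return WeightedNetwork(W, ids)


def _read_dense(path: Path, dialect: NetworkFileDialect) -> WeightedNetwork:
    try:
        if dialect.has_header:
            df = pd.read_csv(path, sep=dialect.delimiter, index_col=0)
            ids = [str(c) for c in df.columns]
        else:
            df = pd.read_csv(path, sep=dialect.delimiter, header=None)
            ids = []
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{path}: dense matrix parse failure: {exc}") from exc
    W = df.to_numpy(dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"{path}: dense matrix is {W.shape}, expected square")
    return WeightedNetwork(W, ids)


def _read_mtx(path: Path, dialect: NetworkFileDialect) -> WeightedNetwork:
    if dialect.indexing == "1-based":
        try:
            M = mmread(str(path))
        except ValueError as exc:
            raise ValidationError(f"{path}: MatrixMarket parse failure: {exc}") from exc
        W = np.asarray(M.todense() if hasattr(M, "todense") else M, dtype=float)
    else:
        rows, cols, vals, n = _parse_coordinate_0based(path)
        # undirected semantics: each stored entry contributes to both triangles
        W = np.zeros((n, n))
        for i, j, v in zip(rows, cols, vals):
            W[i, j] += v
            if i != j:
                W[j, i] += v
    if W.shape[0] != W.shape[1]:
        raise ValidationError(f"{path}: matrix is {W.shape}, expected square")
    if (W < 0).any():
        raise ValidationError(f"{path}: negative weights in sparse matrix")
    return WeightedNetwork(W)


def _parse_coordinate_0based(path: Path):
    rows, cols, vals = [], [], []
    n = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            parts = line.split()
            if n is None:
                if len(parts) < 2:
                    raise ValidationError(f"{path}:{lineno}: malformed size line {line!r}")
                n = int(parts[0])
                continue
            if len(parts) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 'i j value'")
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative weight {v}")
            rows.append(i)
            cols.append(j)
            vals.append(v)
    if n is None:
        raise ValidationError(f"{path}: empty coordinate file")
    return np.array(rows), np.array(cols), np.array(vals), n


# ---------------------------------------------------------------------------
# network writers


def write_network(net: WeightedNetwork, path: str | Path, dialect: NetworkFileDialect | None = None) -> None:
    dialect = dialect or NetworkFileDialect(format=infer_format(path))
    path = Path(path)
    if dialect.format == "edgelist":
        _write_edgelist(net, path, dialect)
    elif dialect.format == "dense":
        _write_dense(net, path, dialect)
    else:
        _write_mtx(net, path)


def _write_edgelist(net: WeightedNetwork, path: Path, dialect: NetworkFileDialect) -> None:
    W = net.weights
    ids = net.node_ids
    with open(path, "w") as fh:
        for i in range(net.n_nodes):
            for j in range(i + 1, net.n_nodes):
                if W[i, j] > SPARSE_ZERO_TOL:
                    fh.write(f"{ids[i]}{dialect.delimiter}{ids[j]}{dialect.delimiter}{W[i, j]:.10g}\n")


def _write_dense(net: WeightedNetwork, path: Path, dialect: NetworkFileDialect) -> None:
    df = pd.DataFrame(net.weights, index=net.node_ids, columns=net.node_ids)
    df.to_csv(path, sep=dialect.delimiter, float_format="%.12g")


def _write_mtx(net: WeightedNetwork, path: Path) -> None:
    W = net.weights.copy()
    W[np.abs(W) <= SPARSE_ZERO_TOL] = 0.0
    buf = _io.BytesIO()
    mmwrite(buf, coo_matrix(W), symmetry="symmetric", precision=12)
    Path(path).write_bytes(buf.getvalue())


# ---------------------------------------------------------------------------
# labels, seeds, scores, config


def read_labels(path: str | Path, net: WeightedNetwork | None = None) -> CommunityLabels:
    """TSV ``node_id<TAB>label``; aligned to ``net``'s node order when given."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 'node_id label'")
            mapping[parts[0]] = parts[1]
    if net is not None:
        missing = [v for v in net.node_ids if v not in mapping]
        if missing:
            raise ValidationError(f"{path}: missing labels for nodes {missing[:5]}")
        ids = list(net.node_ids)
    else:
        ids = sorted(mapping)
    raw_labels = [mapping[v] for v in ids]
    _, assignments = np.unique(raw_labels, return_inverse=True)
    return CommunityLabels(assignments=assignments, node_ids=ids)


def write_labels(labels: CommunityLabels, path: str | Path) -> None:
    ids = labels.node_ids or [str(i) for i in range(labels.n)]
    with open(path, "w") as fh:
        for v, lab in zip(ids, labels.assignments):
            fh.write(f"{v}\t{lab}\n")


def read_seeds(path: str | Path) -> list[str]:
    """One node id per line."""
    seeds = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                seeds.append(line)
    if not seeds:
        raise ValidationError(f"{path}: no seed nodes found")
    return seeds


def write_scores(node_ids: list[str], scores: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for v, s in zip(node_ids, scores):
            fh.write(f"{v}\t{s:.12g}\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key=value`` config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key=value', got {line!r}")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
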