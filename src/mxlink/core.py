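"""Multiplex data model, adjacency construction and spectral decomposition.

A multiplex network is a set of ``N`` nodes replicated across ``M`` layers,
each layer an undirected, unweighted simple graph on the shared node universe.
Layers are stored as sets of unordered index pairs; adjacency matrices are
built over the full universe, so nodes inactive in a layer contribute zero
rows/columns (the multiplex node count, not the per-layer active count, sets
the matrix dimension).

The structural features of a layer are the eigenvectors of its adjacency
matrix: ``A = sum_k lambda_k x_k x_k^T`` with eigenvalues sorted in
descending algebraic order. "Leading eigenvector" always means the one of
the algebraically largest eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

from .errors import ContractViolation

__all__ = [
    "EdgeSet",
    "MultiplexNetwork",
    "SpectralDecomposition",
    "adjacency",
    "spectral_decompose",
    "node_multiplexity",
    "active_node_count",
]

#: residual / orthonormality tolerance for spectral decompositions
SPECTRAL_TOL = 1e-8


@dataclass(frozen=True)
class EdgeSet:
    """An undirected simple edge set over node indices.

    Edges are unordered pairs ``(i, j)`` normalized to ``i < j``; self-loops
    and duplicates are removed on construction.
    """

    edges: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "EdgeSet":
        norm = set()
        for i, j in pairs:
            i, j = int(i), int(j)
            if i == j:
                continue
            norm.add((i, j) if i < j else (j, i))
        return cls(frozenset(norm))

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    def degrees(self, n: int) -> np.ndarray:
        deg = np.zeros(n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def active_nodes(self) -> frozenset:
        """Indices with degree >= 1."""
        return frozenset(i for e in self.edges for i in e)

    def to_adjacency(self, n: int) -> np.ndarray:
        """Dense symmetric 0/1 adjacency over ``n`` nodes."""
        a = np.zeros((n, n))
        if self.edges:
            idx = np.asarray(sorted(self.edges))
            if idx.min() < 0 or idx.max() >= n:
                raise ContractViolation(
                    f"edge endpoint out of range for universe of size {n}"
                )
            a[idx[:, 0], idx[:, 1]] = 1.0
            a[idx[:, 1], idx[:, 0]] = 1.0
        return a

    def __iter__(self):
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return ((i, j) if i < j else (j, i)) in self.edges


@dataclass(frozen=True)
class MultiplexNetwork:
    """A shared node universe plus ``M`` undirected simple layers.

    Parameters
    ----------
    node_labels : sequence
        External node identifiers; position defines the internal index
        ``0 .. N-1``.
    layers : mapping
        Layer name -> :class:`EdgeSet` over internal indices.  Iteration
        order is the declaration order.
    """

    node_labels: tuple
    layers: dict

    def __post_init__(self):
        n = len(self.node_labels)
        if len(set(self.node_labels)) != n:
            raise ContractViolation("duplicate node labels in universe")
        for name, es in self.layers.items():
            for i, j in es.edges:
                if not (0 <= i < j < n):
                    raise ContractViolation(
                        f"layer {name!r}: edge ({i}, {j}) outside universe of size {n}"
                    )

    @property
    def N(self) -> int:
        return len(self.node_labels)

    @property
    def M(self) -> int:
        return len(self.layers)

    @property
    def layer_names(self) -> tuple:
        return tuple(self.layers)

    def layer(self, name: str) -> EdgeSet:
        try:
            return self.layers[name]
        except KeyError:
            raise KeyError(
                f"unknown layer {name!r}; available: {list(self.layers)}"
            ) from None

    def index_of(self, label: Hashable) -> int:
        try:
            return self._label_index[label]
        except AttributeError:
            object.__setattr__(
                self, "_label_index", {lab: i for i, lab in enumerate(self.node_labels)}
            )
            return self._label_index[label]

    def with_layer(self, name: str, edges: EdgeSet) -> "MultiplexNetwork":
        """Copy of the network with one layer replaced (or added)."""
        layers = dict(self.layers)
        layers[name] = edges
        return MultiplexNetwork(self.node_labels, layers)

    @classmethod
    def from_edge_lists(
        cls,
        layer_edges: Mapping[str, Iterable[tuple[Hashable, Hashable]]],
        node_universe: Sequence[Hashable] | None = None,
    ) -> "MultiplexNetwork":
        """Build from per-layer lists of label pairs.

        The node universe is the union of endpoints across layers (in sorted
        label order) unless given explicitly.
        """
        if node_universe is None:
            seen = set()
            for pairs in layer_edges.values():
                for u, v in pairs:
                    seen.add(u)
                    seen.add(v)
            node_universe = sorted(seen, key=_label_sort_key)
        labels = tuple(node_universe)
        index = {lab: i for i, lab in enumerate(labels)}
        layers = {}
        for name, pairs in layer_edges.items():
            try:
                layers[str(name)] = EdgeSet.from_pairs(
                    (index[u], index[v]) for u, v in pairs
                )
            except KeyError as exc:
                raise ContractViolation(
                    f"layer {name!r} references node {exc.args[0]!r} "
                    "outside the declared universe"
                ) from None
        return cls(labels, layers)


def _label_sort_key(label):
    """Numeric labels sort numerically, everything else as strings."""
    s = str(label)
    try:
        return (0, float(s), s)
    except ValueError:
        return (1, 0.0, s)


@dataclass(frozen=True)
class SpectralDecomposition:
    """Retained eigenpairs of a symmetric adjacency matrix.

    ``eigenvalues[k]`` is the (k+1)-th algebraically largest eigenvalue and
    ``eigenvectors[:, k]`` its unit eigenvector; ``k_used`` pairs are kept.
    Eigenvector signs are arbitrary: every downstream use (absolute cosine
    similarity, outer products) is sign-invariant.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    k_used: int

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]


def adjacency(net: MultiplexNetwork, layer: str) -> np.ndarray:
    """N x N symmetric binary adjacency of one layer over the full universe."""
    return net.layer(layer).to_adjacency(net.N)


def spectral_decompose(a: np.ndarray, k: int | None = None) -> SpectralDecomposition:
    """Symmetric eigendecomposition, retaining the ``k`` leading eigenpairs.

    Parameters
    ----------
    a : ndarray
        Symmetric matrix.
    k : int, optional
        Number of eigenpairs of algebraically largest eigenvalue to keep;
        all ``N`` by default.

    Notes
    -----
    The full decomposition is always computed (``scipy.linalg.eigh``) and
    then truncated, so the retained pairs are exact eigenpairs of ``a``.
    Degenerate eigenvalues keep the solver's orthonormal basis unchanged.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ContractViolation(f"adjacency must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ContractViolation("adjacency matrix must be symmetric")
    n = a.shape[0]
    if k is None:
        k = n
    if not 1 <= k <= n:
        raise ContractViolation(f"k must be in [1, {n}], got {k}")
    w, v = scipy.linalg.eigh(a)
    order = np.argsort(-w, kind="stable")  # descending algebraic order
    w, v = w[order], v[:, order]
    return SpectralDecomposition(w[:k].copy(), v[:, :k].copy(), k)


def node_multiplexity(net: MultiplexNetwork) -> float:
    """Fraction of nodes active (degree >= 1) in more than one layer."""
    if net.M < 2:
        raise ContractViolation("node multiplexity requires at least two layers")
    counts = np.zeros(net.N, dtype=int)
    for es in net.layers.values():
        for i in es.active_nodes():
            counts[i] += 1
    return float(np.count_nonzero(counts >= 2) / net.N)


def active_node_count(net: MultiplexNetwork, layer: str) -> int:
    """Number of nodes with at least one link in the given layer."""
    return len(net.layer(layer).active_nodes())
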