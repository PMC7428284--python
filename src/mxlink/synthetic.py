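"""Synthetic multiplex generators.

Everything the package does can be exercised without downloads: Bernoulli
and fixed-edge-count Erdős–Rényi layers, the duplicated-layer "backup"
duplex (an auxiliary layer that is an untouched copy of the target, the
clean-room setting where reconstruction from the auxiliary should be
perfect), and a correlated duplex whose second layer is a partial rewiring
of the first — a tunable interpolation between identical layers
(rewire_fraction = 0) and independent same-density layers
(rewire_fraction = 1).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from ._seeds import child_seed, rng_for
from .core import EdgeSet, MultiplexNetwork
from .errors import ContractViolation

__all__ = [
    "erdos_renyi",
    "erdos_renyi_gnm",
    "backup_duplex",
    "correlated_duplex",
]


def erdos_renyi(n: int, p: float, seed: int | None = None) -> EdgeSet:
    """Bernoulli G(n, p): each unordered pair is an edge with probability p."""
    if not 0 <= p <= 1:
        raise ContractViolation(f"p must be in [0, 1], got {p}")
    g = nx.fast_gnp_random_graph(
        n, p, seed=None if seed is None else child_seed(seed, "er")
    )
    return EdgeSet.from_pairs(g.edges())


def erdos_renyi_gnm(n: int, m: int, seed: int | None = None) -> EdgeSet:
    """Uniform random m-subset of the n(n-1)/2 pairs (fixed edge count,
    for layers with exact printed link counts)."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ContractViolation(f"m must be in [0, {max_m}] for n={n}, got {m}")
    g = nx.gnm_random_graph(
        n, m, seed=None if seed is None else child_seed(seed, "gnm")
    )
    return EdgeSet.from_pairs(g.edges())


def backup_duplex(edges: EdgeSet, n: int) -> MultiplexNetwork:
    """Duplex of two identical layers, ``target`` and ``backup``.

    In evaluation only the target is split; the backup stays untouched and
    carries complete information about the removed links.
    """
    return MultiplexNetwork(
        tuple(range(n)), {"target": edges, "backup": EdgeSet(edges.edges)}
    )


def correlated_duplex(
    n: int, m: int, rewire_fraction: float, seed: int | None = None
) -> MultiplexNetwork:
    """Duplex whose second layer partially rewires the first.

    Layer ``a`` is G(n, m); layer ``b`` copies it, deletes
    ``round(rewire_fraction * m)`` random edges and adds the same number of
    random non-edges, preserving the edge count. Structural-feature
    similarity between the layers decreases (in expectation) as
    ``rewire_fraction`` rises from 0 (identical) to 1 (independent-like).
    """
    if not 0 <= rewire_fraction <= 1:
        raise ContractViolation(
            f"rewire_fraction must be in [0, 1], got {rewire_fraction}"
        )
    base = erdos_renyi_gnm(n, m, seed=None if seed is None else child_seed(seed, "base"))
    n_rewire = int(np.floor(rewire_fraction * base.m + 0.5))
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    free = [p for p in all_pairs if p not in base.edges]
    if n_rewire > len(free):
        raise ContractViolation(
            f"cannot add {n_rewire} new edges: only {len(free)} non-edges available"
        )
    rng = rng_for(seed, "rewire")
    kept = sorted(base.edges)
    drop_idx = rng.choice(len(kept), size=n_rewire, replace=False) if n_rewire else []
    dropped = {kept[t] for t in drop_idx}
    add_idx = rng.choice(len(free), size=n_rewire, replace=False) if n_rewire else []
    added = {free[t] for t in add_idx}
    second = (base.edges - dropped) | added
    return MultiplexNetwork(
        tuple(range(n)), {"a": base, "b": EdgeSet(frozenset(second))}
    )
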