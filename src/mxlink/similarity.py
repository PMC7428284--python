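"""Structural-feature similarity between multiplex layers.

Two layers are compared through their eigenvectors: the eigen-similarity
matrix ``O`` holds the absolute cosine similarity ``o_kl = |x_k^T y_l|`` of
every eigenvector pair. Because similar substructures need not occupy the
same spectral rank in both layers, rows and columns are matched greedily —
repeatedly take the largest remaining entry and delete its row and column —
and the q statistic is the mean of the N matched values:

    q = tr(P_r O P_c) / N,   0 <= q <= 1,

with q = 1 for identical structural features.

Significance is assessed against Erdős–Rényi null models that replace one
layer (real–random ``LR``, random–real ``RL``) or both (random–random ``RR``)
by ``ER(N, m / (N(N-1)/2))`` draws at the layer's density. The null q is
treated as normal (mean/sd fitted from the samples) and the p-value is the
upper tail ``Pr[Q >= q]``; an add-one empirical tail estimate is reported
alongside as a robustness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

from ._seeds import rng_for
from .core import MultiplexNetwork, SpectralDecomposition, adjacency, spectral_decompose
from .errors import ContractViolation

__all__ = [
    "eigen_similarity",
    "greedy_match",
    "layer_similarity",
    "null_distribution",
    "significance",
    "empirical_p_value",
    "matched_submatrix",
    "Matching",
    "NullStats",
    "SimilarityResult",
    "LayerSimilarity",
]

NULL_MODES = ("LR", "RL", "RR")


@dataclass(frozen=True)
class Matching:
    """Greedy row/column assignment of an eigen-similarity matrix.

    ``pairs[t] = (k, l)`` is the t-th selected (row, column); by construction
    ``matched_values`` is non-increasing. ``row_order``/``col_order`` are the
    implied permutations P_r, P_c (as index arrays): permuting O by them puts
    the matched values on the diagonal in greedy order.
    """

    pairs: tuple
    matched_values: np.ndarray

    @property
    def row_order(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.pairs])

    @property
    def col_order(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.pairs])


@dataclass(frozen=True)
class NullStats:
    """Fitted null distribution of q under ER randomization."""

    mode: str
    samples: np.ndarray
    mean: float
    sd: float

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class SimilarityResult:
    """q statistic plus (optionally) null-model statistics and p-values."""

    q: float
    matching: Matching
    o_matrix: np.ndarray | None = None
    null_stats: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    p_empirical: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)
    alpha: float = 0.05
    layer_pair: tuple | None = None

    def summary(self) -> str:
        lines = []
        pair = f" {self.layer_pair[0]} / {self.layer_pair[1]}" if self.layer_pair else ""
        lines.append(f"Layer structural-feature similarity{pair}")
        lines.append("=" * 58)
        lines.append(f"{'q statistic':<28}{self.q:>12.4f}")
        for mode in NULL_MODES:
            if mode not in self.null_stats:
                continue
            ns = self.null_stats[mode]
            lines.append("-" * 58)
            lines.append(
                f"{'null ' + mode + ' mean (sd)':<28}"
                f"{ns.mean:>12.4f}  ({ns.sd:.4f}, n={ns.n_samples})"
            )
            lines.append(
                f"{'  p-value (normal)':<28}{self.p_values[mode]:>12.3g}"
            )
            lines.append(
                f"{'  p-value (empirical)':<28}{self.p_empirical[mode]:>12.3g}"
            )
            verdict = "yes" if self.significant[mode] else "no"
            lines.append(
                f"{'  significant at ' + format(self.alpha, '.2f'):<28}{verdict:>12}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)


def eigen_similarity(
    d_alpha: SpectralDecomposition, d_beta: SpectralDecomposition
) -> np.ndarray:
    """Absolute pairwise cosine similarity of two eigenvector sets.

    Entry ``(k, l)`` is ``|x_k^T y_l|``, clipped to [0, 1] to absorb
    floating-point overshoot on unit vectors.
    """
    if d_alpha.n != d_beta.n:
        raise ContractViolation(
            f"decompositions live in different dimensions: {d_alpha.n} vs {d_beta.n}"
        )
    o = np.abs(d_alpha.eigenvectors.T @ d_beta.eigenvectors)
    return np.clip(o, 0.0, 1.0)


def greedy_match(o: np.ndarray) -> Matching:
    """Greedy assignment: take the largest remaining entry, delete its row
    and column, repeat N times.

    Ties are broken toward the smallest row index, then smallest column
    index, so the procedure is deterministic. This is the specified
    algorithm, not an optimal-assignment bound.
    """
    o = np.asarray(o, dtype=float)
    if o.ndim != 2 or o.shape[0] != o.shape[1]:
        raise ContractViolation(f"similarity matrix must be square, got {o.shape}")
    n = o.shape[0]
    work = o.copy()
    pairs = []
    values = np.empty(n)
    for t in range(n):
        flat = int(np.argmax(work))  # row-major argmax = smallest row, then column
        r, c = divmod(flat, n)
        values[t] = o[r, c]
        pairs.append((r, c))
        work[r, :] = -np.inf
        work[:, c] = -np.inf
    return Matching(tuple(pairs), values)


def layer_similarity(a_alpha: np.ndarray, a_beta: np.ndarray) -> SimilarityResult:
    """q statistic between two adjacency matrices (all N eigenvectors).

    Passing the same array object for both arguments reuses a single
    decomposition, which makes the self-similarity exactly 1.
    """
    d_alpha = spectral_decompose(a_alpha)
    d_beta = d_alpha if a_beta is a_alpha else spectral_decompose(a_beta)
    return _similarity_from_decompositions(d_alpha, d_beta)


def _similarity_from_decompositions(d_alpha, d_beta) -> SimilarityResult:
    o = eigen_similarity(d_alpha, d_beta)
    match = greedy_match(o)
    q = float(match.matched_values.sum() / o.shape[0])
    return SimilarityResult(q=q, matching=match, o_matrix=o)


def _er_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Dense adjacency of a Bernoulli G(n, p) draw."""
    iu = np.triu_indices(n, 1)
    a = np.zeros((n, n))
    mask = rng.random(len(iu[0])) < p
    a[iu[0][mask], iu[1][mask]] = 1.0
    return a + a.T


def null_distribution(
    n_nodes: int,
    m_alpha: int,
    m_beta: int,
    mode: str,
    a_real: np.ndarray | None = None,
    n_samples: int = 50,
    seed: int | None = None,
) -> NullStats:
    """Sample the null distribution of q under ER randomization.

    Parameters
    ----------
    n_nodes, m_alpha, m_beta :
        Multiplex node count and per-layer edge counts; each randomized layer
        is drawn as Bernoulli ``ER(N, m / (N(N-1)/2))`` at the matching
        density.
    mode : {"LR", "RL", "RR"}
        Which side(s) are randomized: real–random, random–real or
        random–random.
    a_real : ndarray, optional
        Adjacency of the non-randomized layer (required for LR and RL).
    n_samples : int
        Null sample count; 50 by default.
    """
    if mode not in NULL_MODES:
        raise ContractViolation(f"mode must be one of {NULL_MODES}, got {mode!r}")
    if mode in ("LR", "RL") and a_real is None:
        raise ContractViolation(f"mode {mode} needs the non-randomized layer (a_real)")
    n_pairs = n_nodes * (n_nodes - 1) / 2
    p_alpha = m_alpha / n_pairs
    p_beta = m_beta / n_pairs
    if not (0 <= p_alpha <= 1 and 0 <= p_beta <= 1):
        raise ContractViolation("edge counts imply densities outside [0, 1]")

    d_real = None
    if a_real is not None and mode in ("LR", "RL"):
        a_real = np.asarray(a_real, dtype=float)
        if a_real.shape != (n_nodes, n_nodes):
            raise ContractViolation(
                f"a_real has shape {a_real.shape}, expected ({n_nodes}, {n_nodes})"
            )
        d_real = spectral_decompose(a_real)

    rng = rng_for(seed, "null", 0) if seed is not None else np.random.default_rng()
    samples = np.empty(n_samples)
    for s in range(n_samples):
        if mode == "LR":  # alpha real, beta randomized
            d_a = d_real
            d_b = spectral_decompose(_er_adjacency(n_nodes, p_beta, rng))
        elif mode == "RL":  # alpha randomized, beta real
            d_a = spectral_decompose(_er_adjacency(n_nodes, p_alpha, rng))
            d_b = d_real
        else:
            d_a = spectral_decompose(_er_adjacency(n_nodes, p_alpha, rng))
            d_b = spectral_decompose(_er_adjacency(n_nodes, p_beta, rng))
        samples[s] = _similarity_from_decompositions(d_a, d_b).q
    sd = float(np.std(samples, ddof=1)) if n_samples > 1 else 0.0
    return NullStats(mode, samples, float(np.mean(samples)), sd)


def significance(q: float, null: NullStats, alpha: float = 0.05):
    """One-sided upper-tail p-value of q under the fitted normal null.

    Returns ``(p_value, significant)``. A degenerate null (sd = 0) gives
    p = 0 above the mean, 1 below, 0.5 at it.
    """
    if null.sd < 0:
        raise ContractViolation("null sd must be nonnegative")
    if null.sd == 0:
        p = 0.0 if q > null.mean else (1.0 if q < null.mean else 0.5)
    else:
        p = float(norm.sf((q - null.mean) / null.sd))
    return p, bool(p < alpha)


def empirical_p_value(q: float, null: NullStats) -> float:
    """Add-one empirical tail estimate ((#samples >= q) + 1) / (n + 1)."""
    return float((np.count_nonzero(null.samples >= q) + 1) / (null.n_samples + 1))


def matched_submatrix(
    o: np.ndarray, match: Matching, top_fraction: float = 0.10
) -> np.ndarray:
    """Permuted similarity matrix restricted to the best-matched pairs.

    Rows/columns of ``P_r O P_c`` are kept for the ``ceil(top_fraction * N)``
    matched pairs of largest matched value; the diagonal of the result is the
    top matched values in descending order (the heatmap input for visual
    inspection of layer similarity).
    """
    if not 0 < top_fraction <= 1:
        raise ContractViolation(f"top_fraction must be in (0, 1], got {top_fraction}")
    n = o.shape[0]
    n_top = math.ceil(top_fraction * n)
    rows = match.row_order[:n_top]
    cols = match.col_order[:n_top]
    return np.asarray(o)[np.ix_(rows, cols)]


class LayerSimilarity:
    """Model object: structural-feature similarity of two multiplex layers.

    Parameters
    ----------
    network : MultiplexNetwork
    layer_a, layer_b : str
        Layer names; the pair (alpha, beta) being compared.

    Examples
    --------
    >>> res = LayerSimilarity(net, "advice", "discuss").fit(null="RR", seed=0)
    >>> res.q, res.p_values["RR"]
    """

    def __init__(self, network: MultiplexNetwork, layer_a: str, layer_b: str):
        self.network = network
        self.layer_a = layer_a
        self.layer_b = layer_b
        self._a = adjacency(network, layer_a)
        self._b = self._a if layer_b == layer_a else adjacency(network, layer_b)

    def fit(
        self,
        null: str | None = None,
        n_samples: int = 50,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> SimilarityResult:
        """Compute q; optionally sample null models and test significance.

        ``null`` is one of ``"LR"``, ``"RL"``, ``"RR"``, ``"all"`` or None.
        """
        result = layer_similarity(self._a, self._b)
        result.layer_pair = (self.layer_a, self.layer_b)
        result.alpha = alpha
        if null is None or null == "none":
            return result
        modes = NULL_MODES if null == "all" else (null,)
        net = self.network
        m_a = net.layer(self.layer_a).m
        m_b = net.layer(self.layer_b).m
        for i, mode in enumerate(modes):
            a_real = self._a if mode == "LR" else (self._b if mode == "RL" else None)
            ns = null_distribution(
                net.N, m_a, m_b, mode,
                a_real=a_real, n_samples=n_samples,
                seed=None if seed is None else seed + i,
            )
            p, sig = significance(result.q, ns, alpha=alpha)
            result.null_stats[mode] = ns
            result.p_values[mode] = p
            result.p_empirical[mode] = empirical_p_value(result.q, ns)
            result.significant[mode] = sig
        return result
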