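"""Layer reconstruction and multiplex link-prediction scores.

The core operation reconstructs a target layer's adjacency ``A`` in the
eigenbasis of an auxiliary layer: with auxiliary eigenvectors ``x_k``, the
reconstruction ``A~ = sum_k mu_k x_k x_k^T`` that minimizes the squared
Frobenius error has the closed-form coefficients

    mu_k = x_k^T A x_k,

a global minimum (the objective is quadratic with Hessian ``2 I``). When the
auxiliary basis comes from the target layer itself minus a random
perturbation set ``Delta E`` (adjacency ``Delta A``), the coefficients reduce
to first-order-corrected eigenvalues ``mu_k = lambda_k + x_k^T Delta A x_k``
— the structural perturbation method (SPM). Averaging the perturbed
reconstruction over independent perturbation sets gives the SPM score
matrix ``<A~>``.

The layer reconstruction method (LRM) scores a non-observed pair (i, j) of
the target layer as the SPM self term plus the reconstructions contributed
by every auxiliary layer:

    S_ij = <A~_ij(self)> + sum_beta w_beta A~_ij(beta),

with optional global-overlap-rate (GOR) weights ``w_beta`` and an optional
"perturbed" variant that reconstructs random 90% subsamples of the training
edges and averages. Scores are raw and unbounded; all evaluation downstream
is rank-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._seeds import child_seed, rng_for
from .core import (
    EdgeSet,
    MultiplexNetwork,
    SpectralDecomposition,
    adjacency,
    spectral_decompose,
)
from .errors import ConfigurationError, ContractViolation

__all__ = [
    "Reconstruction",
    "PerturbationConfig",
    "MethodConfig",
    "PredictionScores",
    "reconstruct",
    "objective_Z",
    "spm_scores",
    "lrm_scores",
    "perturbed_lrm_scores",
    "perturbed_lrm_gor_scores",
    "gor",
    "randomize_auxiliary",
    "predict_scores",
    "MultiplexLinkPredictor",
    "LinkPredictionResults",
]

METHODS = ("spm", "lrm", "lrm_p", "lrm_pg", "lrm_rand")


@dataclass(frozen=True)
class Reconstruction:
    """Closed-form least-squares reconstruction of one layer in another's
    eigenbasis: ``matrix = sum_k coefficients[k] x_k x_k^T``."""

    coefficients: np.ndarray
    matrix: np.ndarray


@dataclass(frozen=True)
class PerturbationConfig:
    """Random-perturbation settings for the SPM self term.

    ``p_h`` is the fraction of training links removed to form each
    perturbation set; ``iterations`` independent perturbations are averaged.
    """

    p_h: float = 0.1
    iterations: int = 10

    def __post_init__(self):
        if not 0 < self.p_h < 1:
            raise ContractViolation(f"p_h must be in (0, 1), got {self.p_h}")
        if self.iterations < 1:
            raise ContractViolation("iterations must be >= 1")


@dataclass(frozen=True)
class MethodConfig:
    """Configuration of a link-prediction method.

    Parameters
    ----------
    method : {"spm", "lrm", "lrm_p", "lrm_pg", "lrm_rand"}
    k : int or None
        Number of leading eigenvectors used everywhere (None = all).
    auxiliary_layers : sequence of str, optional
        Defaults to every non-target layer.
    layer_weights : mapping, optional
        Fixed per-auxiliary weights; for ``lrm_pg`` the GOR weights are
        computed from the data when not given.
    perturbation : PerturbationConfig
        Governs the SPM self term and the perturbed-LRM averaging loop.
    subsample_fraction : float
        Fraction of training links shown per iteration in the perturbed
        variants (0.9 by default).
    self_term : {"spm", "plain", "none"}
        "plain" reconstructs the training adjacency in its own eigenbasis
        (the unrefined multi-layer sum, kept for completeness); "spm" is the
        default perturbation-averaged self term.
    """

    method: str = "lrm"
    k: int | None = None
    auxiliary_layers: tuple | None = None
    layer_weights: Mapping | None = None
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    subsample_fraction: float = 0.9
    self_term: str = "spm"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ConfigurationError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0 < self.subsample_fraction <= 1:
            raise ContractViolation("subsample_fraction must be in (0, 1]")
        if self.self_term not in ("spm", "plain", "none"):
            raise ConfigurationError(f"unknown self_term {self.self_term!r}")
        if self.layer_weights is not None:
            if any(w < 0 for w in self.layer_weights.values()):
                raise ContractViolation("layer weights must be nonnegative")


@dataclass(frozen=True)
class PredictionScores:
    """Scores on exactly the non-observed pairs ``U - E_T``.

    ``pairs`` is an (n, 2) array of unordered index pairs (i < j, sorted
    lexicographically); ``values[t]`` is the score of ``pairs[t]``.
    """

    pairs: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if len(self.pairs) != len(self.values):
            raise ContractViolation("pairs and values length mismatch")

    @classmethod
    def from_matrix(cls, s: np.ndarray, training: EdgeSet, n: int) -> "PredictionScores":
        iu = np.triu_indices(n, 1)
        pairs = np.column_stack(iu)
        if training.m:
            excl = np.zeros((n, n), dtype=bool)
            idx = np.asarray(sorted(training.edges))
            excl[idx[:, 0], idx[:, 1]] = True
            keep = ~excl[iu]
        else:
            keep = np.ones(len(pairs), dtype=bool)
        return cls(pairs[keep], np.asarray(s, dtype=float)[iu][keep])

    @property
    def entries(self) -> dict:
        return {(int(i), int(j)): float(v) for (i, j), v in zip(self.pairs, self.values)}

    def __getitem__(self, pair):
        i, j = pair
        if i > j:
            i, j = j, i
        try:
            return self._index[(i, j)]
        except AttributeError:
            object.__setattr__(self, "_index", self.entries)
            return self._index[(i, j)]

    def __len__(self):
        return len(self.values)

    def domain(self) -> frozenset:
        return frozenset((int(i), int(j)) for i, j in self.pairs)


def reconstruct(
    a_target: np.ndarray, d_aux: SpectralDecomposition, k: int | None = None
) -> Reconstruction:
    """Least-squares reconstruction of ``a_target`` in an auxiliary eigenbasis.

    Uses the ``k`` leading retained eigenvectors of ``d_aux``; coefficients
    are the closed-form optimum ``mu_k = x_k^T A x_k``.
    """
    a_target = np.asarray(a_target, dtype=float)
    if a_target.shape != (d_aux.n, d_aux.n):
        raise ContractViolation(
            f"target shape {a_target.shape} does not match decomposition dimension {d_aux.n}"
        )
    if k is None:
        k = d_aux.k_used
    if not 1 <= k <= d_aux.k_used:
        raise ContractViolation(
            f"k must be in [1, {d_aux.k_used}] (retained components), got {k}"
        )
    x = d_aux.eigenvectors[:, :k]
    mu = np.einsum("ik,ij,jk->k", x, a_target, x)  # mu_k = x_k^T A x_k
    matrix = (x * mu) @ x.T
    return Reconstruction(mu, matrix)


def objective_Z(
    a_target: np.ndarray, d_aux: SpectralDecomposition, mu: Sequence[float]
) -> float:
    """Squared Frobenius reconstruction error ``||A - sum_k mu_k x_k x_k^T||_F^2``."""
    mu = np.asarray(mu, dtype=float)
    if len(mu) > d_aux.k_used:
        raise ContractViolation("more coefficients than retained eigenvectors")
    x = d_aux.eigenvectors[:, : len(mu)]
    resid = np.asarray(a_target, dtype=float) - (x * mu) @ x.T
    return float(np.sum(resid * resid))


def _perturbation_split(edges: list, p_h: float, rng: np.random.Generator):
    """Split training edges into remainder and perturbation sets."""
    m = len(edges)
    n_pert = int(np.floor(p_h * m + 0.5))
    if n_pert >= m:
        raise ContractViolation(
            f"perturbation fraction {p_h} leaves no remainder links (m={m})"
        )
    perm = rng.permutation(m)
    pert = [edges[t] for t in perm[:n_pert]]
    remainder = [edges[t] for t in perm[n_pert:]]
    return remainder, pert


def _spm_matrix(
    a_train: np.ndarray,
    k: int | None,
    cfg: PerturbationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturbation-averaged self-reconstruction ``<A~>`` of a training
    adjacency: per iteration, remove a random fraction ``p_h`` of links
    (perturbation set ``Delta A``), decompose the remainder, and assemble
    ``sum_k (lambda_k + x_k^T Delta A x_k) x_k x_k^T`` over the k leading
    eigenpairs."""
    n = a_train.shape[0]
    iu, ju = np.triu_indices(n, 1)
    on = a_train[iu, ju] > 0
    edges = list(zip(iu[on].tolist(), ju[on].tolist()))
    if len(edges) < 2:
        raise ContractViolation("SPM needs a training layer with at least 2 edges")
    acc = np.zeros((n, n))
    for _ in range(cfg.iterations):
        remainder, pert = _perturbation_split(edges, cfg.p_h, rng)
        a_r = np.zeros((n, n))
        for i, j in remainder:
            a_r[i, j] = a_r[j, i] = 1.0
        delta = a_train - a_r
        d = spectral_decompose(a_r, k=None)
        kk = d.k_used if k is None else k
        x = d.eigenvectors[:, :kk]
        dlam = np.einsum("ik,ij,jk->k", x, delta, x)
        acc += (x * (d.eigenvalues[:kk] + dlam)) @ x.T
    return acc / cfg.iterations


def spm_scores(
    a_train: np.ndarray,
    k: int | None = None,
    cfg: PerturbationConfig | None = None,
    seed: int | None = None,
) -> PredictionScores:
    """Structural-perturbation-method scores on the non-observed pairs.

    ``a_train`` is the training adjacency; the result scores exactly the
    pairs outside the training edge set.
    """
    cfg = cfg or PerturbationConfig()
    a_train = np.asarray(a_train, dtype=float)
    n = a_train.shape[0]
    rng = rng_for(seed, "spm")
    s = _spm_matrix(a_train, k, cfg, rng)
    training = _edgeset_of(a_train)
    return PredictionScores.from_matrix(s, training, n)


def _edgeset_of(a: np.ndarray) -> EdgeSet:
    iu, ju = np.triu_indices(a.shape[0], 1)
    on = a[iu, ju] > 0
    return EdgeSet.from_pairs(zip(iu[on].tolist(), ju[on].tolist()))


def gor(e_alpha: EdgeSet, e_beta: EdgeSet) -> float:
    """Global overlap rate: twice the shared-link count over the total link
    count of the two layers; 0 when both layers are empty."""
    total = e_alpha.m + e_beta.m
    if total == 0:
        return 0.0
    return 2.0 * len(e_alpha.edges & e_beta.edges) / total


def randomize_auxiliary(a_aux: np.ndarray, seed: int | None = None) -> np.ndarray:
    """ER adjacency with the node count and link density of ``a_aux``
    (the randomized-auxiliary baseline)."""
    a_aux = np.asarray(a_aux, dtype=float)
    n = a_aux.shape[0]
    if n < 2:
        return np.zeros_like(a_aux)
    p = a_aux.sum() / (n * (n - 1))
    rng = rng_for(seed, "randaux")
    iu = np.triu_indices(n, 1)
    out = np.zeros((n, n))
    mask = rng.random(len(iu[0])) < p
    out[iu[0][mask], iu[1][mask]] = 1.0
    return out + out.T


def _resolve_aux(net: MultiplexNetwork, target: str, cfg: MethodConfig) -> tuple:
    if cfg.auxiliary_layers is None:
        aux = tuple(name for name in net.layer_names if name != target)
    else:
        aux = tuple(cfg.auxiliary_layers)
        for name in aux:
            if name == target:
                raise ConfigurationError(
                    f"auxiliary layer {name!r} equals the target layer"
                )
            net.layer(name)  # raises KeyError on unknown layer
    return aux


def _aux_decompositions(net, target, cfg, seed):
    """Decompose each auxiliary layer (randomized first for lrm_rand).

    All-zero auxiliaries map to None: their eigenbasis is arbitrary, so
    their contribution is defined as zero rather than solver-dependent.
    """
    out = {}
    for idx, name in enumerate(_resolve_aux(net, target, cfg)):
        a_aux = adjacency(net, name)
        if cfg.method == "lrm_rand":
            a_aux = randomize_auxiliary(
                a_aux, seed=None if seed is None else child_seed(seed, "randaux", idx)
            )
        out[name] = None if not a_aux.any() else spectral_decompose(a_aux)
    return out


def _self_matrix(a_train, cfg: MethodConfig, seed):
    if cfg.self_term == "none":
        return 0.0
    if cfg.self_term == "plain":
        return reconstruct(a_train, spectral_decompose(a_train), k=cfg.k).matrix
    return _spm_matrix(a_train, cfg.k, cfg.perturbation, rng_for(seed, "spm"))


def _weights(net, target, e_train, cfg: MethodConfig, aux_names):
    if cfg.layer_weights is not None:
        return {name: float(cfg.layer_weights.get(name, 1.0)) for name in aux_names}
    if cfg.method == "lrm_pg":
        return {name: gor(e_train, net.layer(name)) for name in aux_names}
    return {name: 1.0 for name in aux_names}


def lrm_scores(
    net: MultiplexNetwork,
    target: str,
    e_train: EdgeSet,
    cfg: MethodConfig | None = None,
    seed: int | None = None,
) -> PredictionScores:
    """Layer-reconstruction-method scores: SPM self term plus one full
    reconstruction of the training adjacency per auxiliary layer."""
    cfg = cfg or MethodConfig()
    n = net.N
    a_train = e_train.to_adjacency(n)
    s = np.zeros((n, n)) + _self_matrix(a_train, cfg, seed)
    decomps = _aux_decompositions(net, target, cfg, seed)
    weights = _weights(net, target, e_train, cfg, decomps)
    for name, d in decomps.items():
        if d is None or weights[name] == 0.0:
            continue
        s += weights[name] * reconstruct(a_train, d, k=cfg.k).matrix
    return PredictionScores.from_matrix(s, e_train, n)


def _perturbed_scores(net, target, e_train, cfg: MethodConfig, seed):
    """Shared body of the perturbed LRM variants: in each iteration a random
    subsample of the training links is reconstructed by every auxiliary
    eigenbasis; per-pair auxiliary scores are averaged over iterations."""
    n = net.N
    a_train = e_train.to_adjacency(n)
    s = np.zeros((n, n)) + _self_matrix(a_train, cfg, seed)
    decomps = _aux_decompositions(net, target, cfg, seed)
    weights = _weights(net, target, e_train, cfg, decomps)
    live = {name: d for name, d in decomps.items() if d is not None and weights[name] != 0.0}
    if live:
        edges = sorted(e_train.edges)
        m = len(edges)
        n_keep = int(np.floor(cfg.subsample_fraction * m + 0.5))
        if n_keep < 1:
            raise ContractViolation("subsample fraction leaves no training links")
        rng = rng_for(seed, "subsample")
        iters = cfg.perturbation.iterations
        acc = {name: np.zeros((n, n)) for name in live}
        for _ in range(iters):
            if n_keep == m:
                a_sub = a_train
            else:
                take = rng.choice(m, size=n_keep, replace=False)
                a_sub = np.zeros((n, n))
                for t in take:
                    i, j = edges[t]
                    a_sub[i, j] = a_sub[j, i] = 1.0
            for name, d in live.items():
                acc[name] += reconstruct(a_sub, d, k=cfg.k).matrix
        for name in live:
            s += weights[name] * acc[name] / iters
    return PredictionScores.from_matrix(s, e_train, n)


def perturbed_lrm_scores(
    net: MultiplexNetwork,
    target: str,
    e_train: EdgeSet,
    cfg: MethodConfig | None = None,
    seed: int | None = None,
) -> PredictionScores:
    """Perturbed LRM: auxiliary terms reconstruct random subsamples
    (``subsample_fraction``, default 90%) of the training links, averaged
    over the configured number of iterations."""
    cfg = cfg or MethodConfig(method="lrm_p")
    return _perturbed_scores(net, target, e_train, cfg, seed)


def perturbed_lrm_gor_scores(
    net: MultiplexNetwork,
    target: str,
    e_train: EdgeSet,
    cfg: MethodConfig | None = None,
    seed: int | None = None,
) -> PredictionScores:
    """Perturbed LRM with each auxiliary term weighted by the global overlap
    rate between the training edges and that auxiliary layer; the self term
    stays unweighted."""
    cfg = cfg or MethodConfig(method="lrm_pg")
    if cfg.method != "lrm_pg":
        cfg = replace(cfg, method="lrm_pg")
    return _perturbed_scores(net, target, e_train, cfg, seed)


def predict_scores(
    net: MultiplexNetwork,
    target: str,
    e_train: EdgeSet,
    cfg: MethodConfig,
    seed: int | None = None,
) -> PredictionScores:
    """Dispatch a scoring method by ``cfg.method``."""
    if cfg.method == "spm":
        return spm_scores(
            e_train.to_adjacency(net.N), k=cfg.k, cfg=cfg.perturbation, seed=seed
        )
    if cfg.method in ("lrm", "lrm_rand"):
        return lrm_scores(net, target, e_train, cfg, seed)
    if cfg.method == "lrm_p":
        return perturbed_lrm_scores(net, target, e_train, cfg, seed)
    if cfg.method == "lrm_pg":
        return perturbed_lrm_gor_scores(net, target, e_train, cfg, seed)
    raise ConfigurationError(f"unknown method {cfg.method!r}")


class MultiplexLinkPredictor:
    """Model object: score the non-observed links of one multiplex layer.

    Parameters
    ----------
    network : MultiplexNetwork
    target : str
        Layer whose missing links are to be predicted.
    method : {"spm", "lrm", "lrm_p", "lrm_pg", "lrm_rand"}
    k : int or None
        Leading eigenvectors used (None = all).
    auxiliary : sequence of str, optional
        Auxiliary layers; all non-target layers by default.
    p_h, iterations, subsample_fraction :
        Perturbation settings (see :class:`PerturbationConfig` /
        :class:`MethodConfig`).

    Examples
    --------
    >>> model = MultiplexLinkPredictor(net, "air", method="lrm")
    >>> res = model.fit(seed=0)
    >>> res.to_frame().head()
    """

    def __init__(
        self,
        network: MultiplexNetwork,
        target: str,
        method: str = "lrm",
        k: int | None = None,
        auxiliary: Sequence[str] | None = None,
        p_h: float = 0.1,
        iterations: int = 10,
        subsample_fraction: float = 0.9,
        layer_weights: Mapping | None = None,
        self_term: str = "spm",
    ):
        network.layer(target)  # fail fast on unknown layer
        self.network = network
        self.target = target
        self.config = MethodConfig(
            method=method,
            k=k,
            auxiliary_layers=None if auxiliary is None else tuple(auxiliary),
            layer_weights=layer_weights,
            perturbation=PerturbationConfig(p_h=p_h, iterations=iterations),
            subsample_fraction=subsample_fraction,
            self_term=self_term,
        )
        if method != "spm":
            _resolve_aux(network, target, self.config)  # validate now

    def fit(
        self, training_edges: EdgeSet | None = None, seed: int | None = None
    ) -> "LinkPredictionResults":
        """Score all non-observed pairs given the training edges (the full
        observed layer by default)."""
        e_train = training_edges if training_edges is not None else self.network.layer(self.target)
        scores = predict_scores(self.network, self.target, e_train, self.config, seed)
        return LinkPredictionResults(self, e_train, scores, seed)


class LinkPredictionResults:
    """Fitted scores plus evaluation and export helpers."""

    def __init__(self, model, training_edges, scores, seed):
        self.model = model
        self.training_edges = training_edges
        self.scores = scores
        self.seed = seed

    def to_frame(self):
        """Descending score table with external node labels."""
        import pandas as pd

        labels = self.model.network.node_labels
        order = np.argsort(-self.scores.values, kind="stable")
        return pd.DataFrame(
            {
                "nodeA": [labels[i] for i in self.scores.pairs[order, 0]],
                "nodeB": [labels[j] for j in self.scores.pairs[order, 1]],
                "score": self.scores.values[order],
            }
        )

    def top(self, n: int = 10):
        return self.to_frame().head(n)

    def evaluate(self, probe: EdgeSet) -> dict:
        """AUC, precision and average precision against a probe edge set."""
        from .evaluation import auc, average_precision, precision

        return {
            "auc": auc(self.scores, probe),
            "precision": precision(self.scores, probe),
            "average_precision": average_precision(self.scores, probe),
        }

    def summary(self) -> str:
        cfg = self.model.config
        aux = cfg.auxiliary_layers or tuple(
            n for n in self.model.network.layer_names if n != self.model.target
        )
        lines = [
            "Multiplex link prediction",
            "=" * 58,
            f"{'target layer':<28}{self.model.target}",
            f"{'method':<28}{cfg.method}",
            f"{'eigenvectors (k)':<28}{cfg.k if cfg.k is not None else 'all'}",
            f"{'auxiliary layers':<28}{', '.join(aux) if cfg.method != 'spm' else '-'}",
            f"{'training links':<28}{self.training_edges.m}",
            f"{'scored pairs':<28}{len(self.scores)}",
            "=" * 58,
        ]
        return "\n".join(lines)
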