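"""Train/probe splitting and rank-based evaluation of link predictors.

The protocol: remove a random fraction of a layer's links to form the probe
set ``E_p``, expose the remaining training set ``E_T`` to the predictor, and
judge how the probe links rank among all non-observed pairs ``U - E_T``
(``U`` = all N(N-1)/2 pairs).

Metrics
-------
AUC
    Probability that a random missing (probe) link outscores a random
    non-existent link; ties count 0.5. The exact value is the all-pairs
    average, computed through midranks; a sampled estimator
    ``(n' + 0.5 n'') / n`` with ``n`` random comparisons is also provided.
precision
    Fraction of the top ``L = |E_p|`` scored pairs that are probe links.
average precision
    Mean over probe links of the precision at that link's rank in the
    descending score list.

Ranking ties are broken by node-pair lexicographic order (stable), which is
documented because tie handling changes top-L membership. All three metrics
are invariant under strictly increasing transforms of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from ._seeds import child_seed, rng_for
from .core import EdgeSet, MultiplexNetwork
from .errors import ContractViolation
from .prediction import MethodConfig, PredictionScores, predict_scores

__all__ = [
    "EdgeSplit",
    "EvaluationRecord",
    "split_edges",
    "auc",
    "precision",
    "average_precision",
    "run_experiment",
]


@dataclass(frozen=True)
class EdgeSplit:
    """Disjoint training/probe partition of a layer's edge set."""

    train: EdgeSet
    probe: EdgeSet
    n_nodes: int | None = None

    @property
    def u_minus_train_size(self) -> int | None:
        if self.n_nodes is None:
            return None
        return self.n_nodes * (self.n_nodes - 1) // 2 - self.train.m


@dataclass(frozen=True)
class EvaluationRecord:
    """Mean and spread of the three metrics over repeated random splits."""

    method: str
    fraction_removed: float
    auc: float
    auc_sd: float
    precision: float
    precision_sd: float
    average_precision: float
    average_precision_sd: float
    repeats: int


def split_edges(
    edges: EdgeSet,
    fraction_probe: float,
    seed: int | None = None,
    n_nodes: int | None = None,
) -> EdgeSplit:
    """Uniformly sample ``round(fraction_probe * m)`` links as the probe set.

    Round-half-up keeps the probe size deterministic (18 of 180 at 10%).
    A split that would empty either side is a contract violation.
    """
    if not 0 < fraction_probe < 1:
        raise ContractViolation(f"fraction_probe must be in (0, 1), got {fraction_probe}")
    m = edges.m
    if m < 2:
        raise ContractViolation("need at least 2 edges to split")
    n_probe = int(np.floor(fraction_probe * m + 0.5))
    if n_probe == 0 or n_probe == m:
        raise ContractViolation(
            f"probe fraction {fraction_probe} of {m} edges rounds to a degenerate split"
        )
    rng = rng_for(seed, "split")
    ordered = sorted(edges.edges)
    take = rng.choice(m, size=n_probe, replace=False)
    probe = EdgeSet.from_pairs(ordered[t] for t in take)
    train = EdgeSet(edges.edges - probe.edges)
    return EdgeSplit(train, probe, n_nodes)


def _probe_and_negative(scores: PredictionScores, probe: EdgeSet):
    domain = scores.domain()
    missing = [tuple(p) for p in sorted(probe.edges)]
    if not missing:
        raise ContractViolation("probe set is empty")
    if not set(missing) <= domain:
        raise ContractViolation("probe links missing from the score domain")
    probe_set = set(missing)
    neg_mask = np.asarray(
        [(int(i), int(j)) not in probe_set for i, j in scores.pairs], dtype=bool
    )
    if not neg_mask.any():
        raise ContractViolation("no non-existent links to compare against")
    idx = scores.entries
    s_miss = np.asarray([idx[p] for p in missing])
    s_neg = scores.values[neg_mask]
    return s_miss, s_neg


def auc(
    scores: PredictionScores,
    probe: EdgeSet,
    method: str = "exact",
    n: int | None = None,
    seed: int | None = None,
) -> float:
    """Probability that a random probe link outscores a random non-existent
    link (ties 0.5).

    ``method="exact"`` averages over all (missing, non-existent) pairs via
    midranks; ``method="sampled"`` draws ``n`` independent comparisons.
    """
    s_miss, s_neg = _probe_and_negative(scores, probe)
    if method == "exact":
        ranks = rankdata(np.concatenate([s_miss, s_neg]))
        n1, n2 = len(s_miss), len(s_neg)
        return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))
    if method == "sampled":
        if not n or n < 1:
            raise ContractViolation("sampled AUC needs a positive sample count n")
        rng = rng_for(seed, "auc")
        a = s_miss[rng.integers(len(s_miss), size=n)]
        b = s_neg[rng.integers(len(s_neg), size=n)]
        return float((np.sum(a > b) + 0.5 * np.sum(a == b)) / n)
    raise ContractViolation(f"unknown AUC method {method!r}")


def _descending_order(scores: PredictionScores) -> np.ndarray:
    """Stable descending sort; pairs are already lexicographic, so tied
    scores fall back to node-pair order."""
    return np.argsort(-scores.values, kind="stable")


def precision(scores: PredictionScores, probe: EdgeSet) -> float:
    """Hits among the top ``L = |E_p|`` entries of the sorted list, over L."""
    _probe_and_negative(scores, probe)  # validates domain
    order = _descending_order(scores)
    L = probe.m
    top = scores.pairs[order[:L]]
    hits = sum(1 for i, j in top if (int(i), int(j)) in probe)
    return float(hits / L)


def average_precision(scores: PredictionScores, probe: EdgeSet) -> float:
    """Mean of precision@rank taken at each probe link's rank."""
    _probe_and_negative(scores, probe)
    order = _descending_order(scores)
    is_hit = np.asarray(
        [(int(i), int(j)) in probe for i, j in scores.pairs[order]], dtype=bool
    )
    ranks = np.flatnonzero(is_hit) + 1  # 1-based rank of each probe link
    hits_so_far = np.arange(1, len(ranks) + 1)
    return float(np.mean(hits_so_far / ranks))


def run_experiment(
    net: MultiplexNetwork,
    target: str,
    cfg: MethodConfig,
    fractions: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    repeats: int = 30,
    seed: int | None = None,
) -> list[EvaluationRecord]:
    """Repeated-split evaluation harness.

    For each removal fraction: ``repeats`` independent train/probe splits of
    the target layer, one fit per split, and all three metrics; the record
    carries their mean and standard deviation (the error bars of a
    fraction-sweep plot).
    """
    edges = net.layer(target)
    records = []
    for fi, frac in enumerate(fractions):
        if not 0 < frac < 1:
            raise ContractViolation(f"removal fraction must be in (0, 1), got {frac}")
        metrics = np.empty((repeats, 3))
        for r in range(repeats):
            sub = None if seed is None else child_seed(seed, "repeat", fi * 100003 + r)
            split = split_edges(edges, frac, seed=sub, n_nodes=net.N)
            scores = predict_scores(net, target, split.train, cfg, seed=sub)
            metrics[r] = (
                auc(scores, split.probe),
                precision(scores, split.probe),
                average_precision(scores, split.probe),
            )
        mean = metrics.mean(axis=0)
        sd = metrics.std(axis=0, ddof=1) if repeats > 1 else np.zeros(3)
        records.append(
            EvaluationRecord(
                method=cfg.method,
                fraction_removed=float(frac),
                auc=float(mean[0]),
                auc_sd=float(sd[0]),
                precision=float(mean[1]),
                precision_sd=float(sd[1]),
                average_precision=float(mean[2]),
                average_precision_sd=float(sd[2]),
                repeats=repeats,
            )
        )
    return records
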