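"""Discrimination and robustness evaluation of pairwise probability models.

Positives are the observed metabolite-reaction links, negatives all absent
pairs (no subsampling). The ROC curve sweeps the distinct predicted
probabilities as thresholds; the AUC is the probability that a randomly
chosen observed link outranks a randomly chosen absent pair (ties credited
1/2), computed by the Mann-Whitney rank formulation, which equals the
trapezoidal area under the ROC curve.

The robustness statistic removes a fraction of links uniformly at random,
refits the model on the remaining network, and measures the AUC of removed
links against never-present pairs; it ranges from 0.5 (chance) to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .hrbg import PairProbabilities
from .network import BipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "roc_curve",
    "auc",
    "removal_test",
    "calibration",
]

ModelFn = Callable[[BipartiteNetwork, np.random.Generator], PairProbabilities]


@dataclass
class ValidationReport:
    """Collected validation output for a set of models."""

    roc: dict[str, np.ndarray] = field(default_factory=dict)   # (n, 2) FPR, TPR
    auc: dict[str, float] = field(default_factory=dict)
    removal: dict[str, pd.DataFrame] = field(default_factory=dict)
    calibration: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["# model\tAUC"]
        for name, value in sorted(self.auc.items(), key=lambda kv: -kv[1]):
            lines.append(f"{name}\t{value:.4f}")
        return "\n".join(lines)


def _scores_labels(
    p: PairProbabilities, net: BipartiteNetwork
) -> tuple[np.ndarray, np.ndarray]:
    if tuple(p.metabolite_ids) != tuple(net.metabolite_ids) or tuple(
        p.reaction_ids
    ) != tuple(net.reaction_ids):
        raise ValueError("probabilities and network index different node sets")
    labels = net.biadjacency().ravel()
    scores = p.p.ravel()
    return scores, labels


def roc_curve(p: PairProbabilities, net: BipartiteNetwork) -> np.ndarray:
    """ROC points as an (n, 2) array of (FPR, TPR).

    One point per distinct predicted probability (thresholds swept from
    highest to lowest) plus the endpoints (0, 0) and (1, 1).
    """
    scores, labels = _scores_labels(p, net)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both observed links and absent pairs")
    if np.unique(scores).size == 1:
        warnings.warn("all predicted probabilities equal: degenerate ROC",
                      stacklevel=2)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], (0.0, 0.0)):
        pts = np.vstack([(0.0, 0.0), pts])
    if not np.allclose(pts[-1], (1.0, 1.0)):
        pts = np.vstack([pts, (1.0, 1.0)])
    return pts


def auc(p: PairProbabilities, net: BipartiteNetwork) -> float:
    """Rank-formulation AUC with ties counted 1/2.

    Equals the probability that a random observed link has a higher
    predicted probability than a random absent pair, and (exactly) the
    trapezoidal area under :func:`roc_curve`.
    """
    scores, labels = _scores_labels(p, net)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both links and absent pairs")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 credits
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def removal_test(
    net: BipartiteNetwork,
    fraction: float,
    model: ModelFn,
    reps: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Link-removal robustness statistic.

    For each repetition, ``floor(fraction * L)`` links are removed uniformly
    at random, the model is refit on the remaining network (isolated nodes
    are retained with degree 0), and the AUC of removed links versus
    never-present pairs is recorded. Returns one row per repetition plus
    the mean and standard deviation are available from the column.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_remove = int(fraction * net.L)
    if n_remove < 1:
        raise ValueError(
            f"fraction {fraction} removes no links from a network with L={net.L}"
        )
    rng = rng if rng is not None else np.random.default_rng()
    edges = sorted(net.edges)
    never = ~net.biadjacency()  # absent in the *original* network
    rows = []
    for rep in range(reps):
        idx = rng.choice(len(edges), size=n_remove, replace=False)
        removed = [edges[i] for i in idx]
        reduced = net.remove_edges(removed)
        p = model(reduced, rng)
        if tuple(p.metabolite_ids) != tuple(net.metabolite_ids) or tuple(
            p.reaction_ids
        ) != tuple(net.reaction_ids):
            raise ValueError("model returned probabilities over different nodes")
        mi, ri = net.metabolite_index(), net.reaction_index()
        removed_scores = np.array([p.p[mi[m], ri[r]] for m, r in removed])
        negative_scores = p.p[never]
        scores = np.concatenate([removed_scores, negative_scores])
        ranks = rankdata(scores)
        n_pos, n_neg = removed_scores.size, negative_scores.size
        u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
        rows.append({"rep": rep, "n_removed": n_pos,
                     "auc_removed": float(u / (n_pos * n_neg))})
    return pd.DataFrame(rows)


def calibration(
    p: PairProbabilities, net: BipartiteNetwork, bins: int = 10
) -> pd.DataFrame:
    """Reliability table: predicted-probability bins vs observed link fraction.

    Pairs are binned by predicted probability into ``bins`` equal-width bins
    on [0, 1]; each row reports the bin edges, the pair count, the mean
    prediction and the observed fraction of true links. Empty bins are
    skipped (logged). Well-calibrated probabilities put every row near the
    diagonal observed ~= predicted.
    """
    if bins < 1:
        raise ValueError("bins must be positive")
    scores, labels = _scores_labels(p, net)
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = np.clip(np.digitize(scores, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = which == b
        if not mask.any():
            logger.info("calibration: bin [%.3f, %.3f) empty, skipped",
                        edges[b], edges[b + 1])
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_pairs": int(mask.sum()),
                "mean_predicted": float(scores[mask].mean()),
                "observed_fraction": float(labels[mask].mean()),
            }
        )
    return pd.DataFrame(rows)
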