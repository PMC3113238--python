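"""Reaction scores from pairwise connection probabilities.

A reaction is identified with its metabolite combination nu. Given a
probability p_mr for every metabolite-reaction pair, the probability that
exactly the combination nu occurs at reaction r is (independence assumed)

    P(nu, r) = prod_{m in nu} p_mr * prod_{m' not in nu} (1 - p_m'r)

and the expected number of co-occurrences of nu over the whole network is

    n_nu = sum_r P(nu, r)

which is the absolute score of the reaction. Three probability models feed
this machinery:

* TDB (tree distance bipartite): the hierarchical-fit distances d_mr are
  degree-corrected into p_mr = 1 / (1 + d_mr / (mu * k_m)) with mu = 1/R,
  so a pair at maximal distance d = 1 connects with probability
  k_m / (k_m + R) ~= k_m / R and the expected link count matches L.
* CMB (configuration model for bipartite networks): the degree-preserving
  null, p_mr = k_m * k_r / L. Because reaction degrees are nearly
  homogeneous (k_r ~= <k_r>), n_nu has the closed form
  S_CMB = R * prod_{m in nu} p_m * prod_{m' not in nu} (1 - p_m'), with
  p_m = min(1, k_m <k_r> / L).
* CN (common neighbours): a local baseline scoring each pair by the summed
  reaction-overlap o_mm' between m and the members of r; used only for
  rank-based validation, so its normalization is immaterial.

The relative score Sigma = S_TDB / S_CMB reads off tree-distance
correlations: Sigma > 1 means the reaction's metabolites aggregate in the
fitted metric compared to the degree-preserving random case, Sigma < 1 that
they avoid each other. Scores span many orders of magnitude, so all
products are evaluated in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hrbg import PairProbabilities
from .network import BipartiteNetwork, ReactionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TdbParameters",
    "tdb_probabilities",
    "cmb_probabilities",
    "combination_probability",
    "log_combination_probability",
    "score_tdb",
    "score_cmb",
    "score_cn",
    "score_reactions",
    "relative_scores",
    "write_score_table",
]


@dataclass(frozen=True)
class TdbParameters:
    """Calibration constant mu = 1/R and the metabolite degrees k_m."""

    mu: float
    k_m: dict[str, int]

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    @classmethod
    def from_network(cls, net: BipartiteNetwork) -> "TdbParameters":
        return cls(mu=1.0 / net.R, k_m=net.metabolite_degrees())


# ---------------------------------------------------------------------------
# Pairwise probability models
# ---------------------------------------------------------------------------

def tdb_probabilities(
    pairs: PairProbabilities, net: BipartiteNetwork
) -> PairProbabilities:
    """Degree-correct hierarchical tree distances into TDB probabilities.

    p_mr = 1 / (1 + d_mr / (mu k_m)), mu = 1/R. Strictly decreasing in the
    tree distance at fixed degree, non-decreasing in the degree at fixed
    distance, and calibrated so that sum_mr p_mr tracks the observed link
    count L (a far pair, d ~= 1, contributes ~ k_m / R and the row sums of
    k_m / R reproduce L exactly).
    """
    if tuple(pairs.metabolite_ids) != tuple(net.metabolite_ids) or tuple(
        pairs.reaction_ids
    ) != tuple(net.reaction_ids):
        raise ValueError("pair probabilities and network index different node sets")
    d = pairs.d
    bad = ~np.isfinite(d)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "tree distance undefined for pair "
            f"({pairs.metabolite_ids[i]!r}, {pairs.reaction_ids[j]!r})"
        )
    params = TdbParameters.from_network(net)
    km = np.array([params.k_m[m] for m in net.metabolite_ids], dtype=float)
    muk = params.mu * km[:, None]  # (M, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(muk > 0, 1.0 / (1.0 + d / np.where(muk > 0, muk, 1.0)), 0.0)
    return PairProbabilities(net.metabolite_ids, net.reaction_ids, p)


def cmb_probabilities(net: BipartiteNetwork) -> PairProbabilities:
    """Configuration-model pair probabilities p_mr = k_m k_r / L (clamped)."""
    km = np.array([net.metabolite_degrees()[m] for m in net.metabolite_ids], float)
    kr = np.array([net.reaction_degrees()[r] for r in net.reaction_ids], float)
    p = np.outer(km, kr) / net.L
    if (p > 1.0).any():
        logger.warning(
            "CMB: %d degree products exceed L; probabilities clamped to 1",
            int((p > 1.0).sum()),
        )
        p = np.minimum(p, 1.0)
    return PairProbabilities(net.metabolite_ids, net.reaction_ids, p)


def score_cn(net: BipartiteNetwork) -> PairProbabilities:
    """Common-neighbours pair scores, rescaled to [0, 1].

    o_mm' counts the reactions in which metabolites m and m' are concurrent;
    the score of pair (m, r) is the sum over the members m' of r (excluding
    m itself) of o_mm', leaving out co-occurrence contributed by r itself.
    Without that leave-one-out every observed link would carry automatic
    self-support of about k_r - 1 while absent pairs carry none, and the
    measure would grade its own input rather than predict. Only the ranking
    matters for ROC validation, so the rescaling by the maximum is cosmetic.
    """
    B = net.biadjacency().astype(np.int64)
    O = B @ B.T
    np.fill_diagonal(O, 0)
    S = (O @ B).astype(float)
    kr = B.sum(axis=0)
    S -= B * np.maximum(kr - 1, 0)[None, :]  # drop r's own co-occurrence
    top = S.max()
    if top > 0:
        S /= top
    return PairProbabilities(net.metabolite_ids, net.reaction_ids, S)


# ---------------------------------------------------------------------------
# Combination probabilities and absolute scores (log space throughout)
# ---------------------------------------------------------------------------

def _log_terms(p: PairProbabilities, nu: Iterable[str]) -> np.ndarray:
    """log P(nu, r) for every reaction r, as a length-R vector."""
    nu = set(nu)
    unknown = nu - set(p.metabolite_ids)
    if unknown:
        raise ValueError(f"unknown metabolites in nu: {sorted(unknown)[:5]}")
    if not nu:
        raise ValueError("nu must be a nonempty metabolite set")
    mask = np.array([m in nu for m in p.metabolite_ids])
    with np.errstate(divide="ignore"):
        log_p = np.log(p.p)
        log_q = np.log1p(-p.p)
    terms = np.where(mask[:, None], log_p, log_q)  # (M, R)
    return terms.sum(axis=0)


def log_combination_probability(
    nu: Iterable[str], reaction: str, p: PairProbabilities
) -> float:
    """log of the probability that exactly the set nu occurs at ``reaction``."""
    j = list(p.reaction_ids).index(reaction)
    return float(_log_terms(p, nu)[j])


def combination_probability(
    nu: Iterable[str], reaction: str, p: PairProbabilities
) -> float:
    """P(nu, r): members of nu connect, all other metabolites do not."""
    return float(np.exp(log_combination_probability(nu, reaction, p)))


def score_tdb(nu: Iterable[str], p: PairProbabilities) -> float:
    """Absolute score n_nu: expected co-occurrences of nu over all reactions.

    The sum runs over every reaction, including the one whose metabolite
    set nu is (reactions enter only through their probability columns).
    """
    lt = _log_terms(p, nu)
    finite = lt[np.isfinite(lt)]
    if finite.size == 0:
        return 0.0
    top = finite.max()
    return float(np.exp(top) * np.exp(finite - top).sum())


def _cmb_metabolite_probs(net: BipartiteNetwork, warn: bool = True) -> np.ndarray:
    """Per-metabolite CMB probabilities p_m = min(1, k_m <k_r> / L)."""
    km = np.array([net.metabolite_degrees()[m] for m in net.metabolite_ids], float)
    pm = km * (net.L / net.R) / net.L
    n_clamped = int((pm >= 1.0).sum())
    if n_clamped and warn:
        logger.warning("CMB: %d metabolite probabilities >= 1 clamped", n_clamped)
    return np.minimum(pm, 1.0)


def _cmb_score_from_probs(
    nu: set, metabolite_ids: Sequence[str], pm: np.ndarray, R: int
) -> float:
    mask = np.array([m in nu for m in metabolite_ids])
    with np.errstate(divide="ignore"):
        log_term = np.where(mask, np.log(pm), np.log1p(-pm)).sum()
    return float(R * np.exp(log_term))


def score_cmb(nu: Iterable[str], net: BipartiteNetwork) -> float:
    """Analytic configuration-model score under k_r ~= <k_r>.

    S_CMB = R * prod_{m in nu} p_m * prod_{m' not in nu} (1 - p_m') with
    p_m = min(1, k_m <k_r> / L): all R reaction terms of the co-occurrence
    sum coincide once reaction degrees are replaced by their mean.
    """
    nu = set(nu)
    unknown = nu - set(net.metabolite_ids)
    if unknown:
        raise ValueError(f"unknown metabolites in nu: {sorted(unknown)[:5]}")
    pm = _cmb_metabolite_probs(net)
    return _cmb_score_from_probs(nu, net.metabolite_ids, pm, net.R)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def score_reactions(
    net: BipartiteNetwork,
    tdb: PairProbabilities,
    records: Sequence[ReactionRecord] | None = None,
    rank_by: str = "s_tdb",
) -> pd.DataFrame:
    """Score every reaction of the network; returns the full score table.

    Columns: reaction_id, size (|nu|), s_tdb, s_cmb, sigma (= s_tdb/s_cmb),
    rank, and confidence when ``records`` supplies database scores.
    ``rank_by`` is 's_tdb' or 'sigma'; ranks are descending, ties broken
    stably by reaction id.
    """
    members = net.reaction_members()
    pm = _cmb_metabolite_probs(net)
    rows = []
    log_terms_cache: dict[frozenset, np.ndarray] = {}
    for rid in net.reaction_ids:
        nu = members[rid]
        if not nu:
            logger.warning("reaction %s has no metabolites; skipped", rid)
            continue
        key = frozenset(nu)
        if key not in log_terms_cache:
            log_terms_cache[key] = _log_terms(tdb, nu)
        lt = log_terms_cache[key]
        finite = lt[np.isfinite(lt)]
        s_tdb = float(np.exp(finite.max()) * np.exp(finite - finite.max()).sum()) if finite.size else 0.0
        s_cmb = _cmb_score_from_probs(set(nu), net.metabolite_ids, pm, net.R)
        rows.append({"reaction_id": rid, "size": len(nu), "s_tdb": s_tdb, "s_cmb": s_cmb})
    table = pd.DataFrame(rows)
    table = relative_scores(table, rank_by=rank_by)
    if records is not None:
        conf = pd.DataFrame(
            {
                "reaction_id": [rec.reaction_id for rec in records],
                "confidence": [rec.confidence for rec in records],
            }
        )
        missing = set(table["reaction_id"]) - set(conf["reaction_id"])
        if missing:
            raise ValueError(
                f"reactions absent from the record table: {sorted(missing)[:5]}"
            )
        table = table.merge(conf, on="reaction_id", how="left")
    return table


def relative_scores(table: pd.DataFrame, rank_by: str = "s_tdb") -> pd.DataFrame:
    """Attach Sigma = S_TDB / S_CMB and a descending rank to a score table."""
    if rank_by not in ("s_tdb", "sigma"):
        raise ValueError("rank_by must be 's_tdb' or 'sigma'")
    out = table.copy()
    zero = out["s_cmb"] <= 0.0
    if zero.any():
        logger.warning("%d reactions have S_CMB = 0; Sigma undefined", int(zero.sum()))
    out["sigma"] = np.where(zero, np.nan, out["s_tdb"] / out["s_cmb"])
    key = out[rank_by].fillna(-np.inf)
    order = np.lexsort((out["reaction_id"].to_numpy(), -key.to_numpy()))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated export with a '#' header line."""
    cols = ["reaction_id", "size", "s_tdb", "s_cmb", "sigma", "rank"]
    if "confidence" in table.columns:
        cols.append("confidence")
    with Path(path).open("w") as fh:
        fh.write("# " + "\t".join(cols) + "\n")
        for _, row in table[cols].iterrows():
            vals = []
            for c in cols:
                v = row[c]
                if isinstance(v, float):
                    vals.append("nan" if np.isnan(v) else f"{v:.10g}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
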