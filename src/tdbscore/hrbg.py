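"""Hierarchical random graph fitting for bipartite networks.

The model adjusts a dendrogram (rooted binary tree whose leaves are the
M metabolites and R reactions) to an observed bipartite network. Each of the
M + R - 1 internal nodes t carries a connection probability rho_t; a
metabolite-reaction pair whose lowest common ancestor (LCA) is t connects
with probability rho_t, independently of every other pair. For a fixed
topology the likelihood

    log L = sum_t [ E_t log rho_t + (eps_t - E_t) log(1 - rho_t) ]

is maximized by rho_t = E_t / eps_t, where E_t counts observed edges whose
LCA is t and eps_t = Lm_t * Rr_t + Lr_t * Rm_t counts the possible such
edges (metabolite leaves on one side of t times reaction leaves on the
other, both ways). Internal nodes with eps_t = 0 separate only same-class
leaves, are never the LCA of any metabolite-reaction pair, and contribute
nothing to the likelihood.

Tree space is explored by a Metropolis-Hastings Markov chain over subtree
swaps: a non-root internal node exchanges one of its two child branches with
its sibling branch (the "alternative branch at its father level"). The move
is self-inverse and chosen symmetrically, so the chain satisfies detailed
balance and its stationary distribution is proportional to the likelihood.
After burn-in, dendrograms are sampled at regular intervals and rho at each
pair's LCA is averaged into a pairwise probability matrix rho_mr; the tree
distance is d_mr = 1 - rho_mr.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import BipartiteNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "PairProbabilities",
    "McmcConfig",
    "NonEquilibratedWarning",
    "log_likelihood",
    "mcmc_step",
    "fit",
]


class NonEquilibratedWarning(UserWarning):
    """The chain's log-likelihood was still trending when sampling began."""


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------
# Leaves 0..M-1 are metabolites, M..M+R-1 reactions. In child slots a leaf j
# is encoded as ~j (negative); internal nodes are indices >= 0 into the
# parallel arrays below.


def _term(E: int, eps: int) -> float:
    """One internal node's log-likelihood contribution, 0*log 0 := 0."""
    if eps == 0:
        return 0.0
    rho = E / eps
    t = 0.0
    if E > 0:
        t += E * math.log(rho)
    if E < eps:
        t += (eps - E) * math.log(1.0 - rho)
    return t


class Dendrogram:
    """Mutable dendrogram over a fixed bipartite network.

    Maintains per internal node: children, parent, metabolite/reaction leaf
    counts of its subtree (``nm``/``nr``) and the observed cross-edge count
    ``E`` of pairs whose LCA it is. The network enters only through the
    adjacency lists ``adj`` (leaf index -> list of neighbour leaf indices).
    """

    __slots__ = ("M", "R", "n_leaves", "adj", "left", "right", "parent",
                 "leaf_parent", "nm", "nr", "E", "root", "logL")

    def __init__(self, net: BipartiteNetwork, rng: np.random.Generator):
        if net.M < 2 or net.R < 2:
            raise ValueError("fitting requires at least 2 metabolites and 2 reactions")
        self._setup_arrays(net)
        n_int = self.n_leaves - 1
        leaves = list(range(self.n_leaves))
        rng.shuffle(leaves)
        counter = iter(range(n_int))

        def build(chunk: list[int]) -> int:
            if len(chunk) == 1:
                return ~chunk[0]
            node = next(counter)
            half = len(chunk) // 2
            lc, rc = build(chunk[:half]), build(chunk[half:])
            self.left[node], self.right[node] = lc, rc
            self._set_parent(lc, node)
            self._set_parent(rc, node)
            return node

        self.root = build(leaves)
        self._init_counts()
        self.logL = self._loglik_full()

    def _setup_arrays(self, net: BipartiteNetwork) -> None:
        self.M, self.R = net.M, net.R
        self.n_leaves = self.M + self.R
        mi, ri = net.metabolite_index(), net.reaction_index()
        self.adj = [[] for _ in range(self.n_leaves)]
        for m, r in net.edges:
            u, v = mi[m], self.M + ri[r]
            self.adj[u].append(v)
            self.adj[v].append(u)
        n_int = self.n_leaves - 1
        self.left = np.empty(n_int, dtype=np.int64)
        self.right = np.empty(n_int, dtype=np.int64)
        self.parent = np.full(n_int, -1, dtype=np.int64)
        self.leaf_parent = np.full(self.n_leaves, -1, dtype=np.int64)
        self.nm = np.zeros(n_int, dtype=np.int64)
        self.nr = np.zeros(n_int, dtype=np.int64)
        self.E = np.zeros(n_int, dtype=np.int64)

    @classmethod
    def from_topology(cls, net: BipartiteNetwork, topology) -> "Dendrogram":
        """Build a dendrogram with a prescribed shape.

        ``topology`` is a nested pair structure over node labels, e.g.
        ``(("m1", "r1"), ("m2", "r2"))``. Every network node must appear
        exactly once as a leaf.
        """
        if net.M < 2 or net.R < 2:
            raise ValueError("fitting requires at least 2 metabolites and 2 reactions")
        self = cls.__new__(cls)
        self._setup_arrays(net)
        mi, ri = net.metabolite_index(), net.reaction_index()

        def leaf_index(label: str) -> int:
            if label in mi:
                return mi[label]
            if label in ri:
                return self.M + ri[label]
            raise ValueError(f"unknown node label {label!r} in topology")

        counter = iter(range(self.n_leaves - 1))
        seen: set[int] = set()

        def build(node) -> int:
            if isinstance(node, str):
                leaf = leaf_index(node)
                if leaf in seen:
                    raise ValueError(f"leaf {node!r} appears twice")
                seen.add(leaf)
                return ~leaf
            if len(node) != 2:
                raise ValueError("topology nodes must be pairs or labels")
            idx = next(counter)
            lc, rc = build(node[0]), build(node[1])
            self.left[idx], self.right[idx] = lc, rc
            self._set_parent(lc, idx)
            self._set_parent(rc, idx)
            return idx

        self.root = build(topology)
        if len(seen) != self.n_leaves:
            raise ValueError("topology does not cover every network node")
        self._init_counts()
        self.logL = self._loglik_full()
        return self

    def _set_parent(self, child: int, par: int) -> None:
        if child < 0:
            self.leaf_parent[~child] = par
        else:
            self.parent[child] = par

    def _child_counts(self, child: int) -> tuple[int, int]:
        if child < 0:
            leaf = ~child
            return (1, 0) if leaf < self.M else (0, 1)
        return int(self.nm[child]), int(self.nr[child])

    def _init_counts(self) -> None:
        # subtree leaf counts by postorder
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            for c in (self.left[node], self.right[node]):
                if c >= 0:
                    stack.append(c)
        for node in reversed(order):
            lm, lr = self._child_counts(int(self.left[node]))
            rm, rr = self._child_counts(int(self.right[node]))
            self.nm[node] = lm + rm
            self.nr[node] = lr + rr
        # E via LCA of every edge
        depth = self._depths()
        self.E[:] = 0
        for u in range(self.M):  # each edge once, from the metabolite side
            for v in self.adj[u]:
                self.E[self._lca(u, v, depth)] += 1

    def _depths(self) -> np.ndarray:
        depth = np.zeros(len(self.left), dtype=np.int64)
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in (self.left[node], self.right[node]):
                if c >= 0:
                    depth[c] = depth[node] + 1
                    stack.append(c)
        return depth

    def _lca(self, u: int, v: int, depth: np.ndarray) -> int:
        a, b = int(self.leaf_parent[u]), int(self.leaf_parent[v])
        while a != b:
            if depth[a] >= depth[b]:
                a = int(self.parent[a])
            else:
                b = int(self.parent[b])
        return a

    # -- likelihood --------------------------------------------------------

    def eps(self, node: int) -> int:
        lm, lr = self._child_counts(int(self.left[node]))
        rm, rr = self._child_counts(int(self.right[node]))
        return lm * rr + lr * rm

    def rho(self, node: int) -> float:
        """ML connection probability of an internal node; NaN when eps=0."""
        e = self.eps(node)
        return float(self.E[node]) / e if e > 0 else math.nan

    def _loglik_full(self) -> float:
        total = 0.0
        for t in range(len(self.left)):
            total += _term(int(self.E[t]), self.eps(t))
        return total

    def validate(self) -> None:
        """Internal-consistency checks: counts vs tree and edge conservation."""
        L = sum(len(a) for a in self.adj) // 2
        if int(self.E.sum()) != L:
            raise AssertionError(
                f"sum of E_t ({int(self.E.sum())}) != L ({L}): "
                "some edge has no unique lowest common ancestor"
            )
        for t in range(len(self.left)):
            lm, lr = self._child_counts(int(self.left[t]))
            rm, rr = self._child_counts(int(self.right[t]))
            if self.nm[t] != lm + rm or self.nr[t] != lr + rr:
                raise AssertionError(f"leaf counts inconsistent at node {t}")
            if not (0 <= self.E[t] <= self.eps(t)):
                raise AssertionError(f"E_t out of range at node {t}")

    # -- subtree utilities -------------------------------------------------

    def _subtree_leaves(self, child: int) -> list[int]:
        if child < 0:
            return [~child]
        out: list[int] = []
        stack = [child]
        while stack:
            node = stack.pop()
            for c in (int(self.left[node]), int(self.right[node])):
                if c < 0:
                    out.append(~c)
                else:
                    stack.append(c)
        return out

    def _in_subtree(self, leaf: int, sub_root: int, stop: int) -> bool:
        """Is ``leaf`` inside the subtree rooted at ``sub_root``?

        ``stop`` is an ancestor of sub_root's parent; the climb from any
        leaf under ``stop`` terminates there at the latest.
        """
        if sub_root < 0:
            return leaf == ~sub_root
        node = int(self.leaf_parent[leaf])
        while node != -1:
            if node == sub_root:
                return True
            if node == stop:
                return False
            node = int(self.parent[node])
        return False

    def _cross_edges(self, a: int, b: int, stop: int) -> int:
        """Edges between subtrees a and b (disjoint, both under ``stop``)."""
        ca, cb = self._child_counts(a), self._child_counts(b)
        if sum(ca) <= sum(cb):
            small, other = a, b
        else:
            small, other = b, a
        count = 0
        for u in self._subtree_leaves(small):
            for v in self.adj[u]:
                if self._in_subtree(v, other, stop):
                    count += 1
        return count

    # -- MCMC move ---------------------------------------------------------

    def step(self, rng: np.random.Generator) -> tuple[bool, float]:
        """One Metropolis-Hastings branch-swap proposal.

        Picks a non-root internal node t uniformly, one of its two child
        branches uniformly, and proposes exchanging it with t's sibling
        branch under t's parent p. Only the likelihood terms of t and p
        change. Returns (accepted, delta_logL_applied).
        """
        n_int = len(self.left)
        # draw until we hit a non-root internal node (root index varies)
        while True:
            t = int(rng.integers(n_int))
            if t != self.root:
                break
        p = int(self.parent[t])
        c = int(self.right[p]) if int(self.left[p]) == t else int(self.left[p])
        swap_left = bool(rng.integers(2))
        a = int(self.left[t]) if swap_left else int(self.right[t])
        b = int(self.right[t]) if swap_left else int(self.left[t])

        E_t, E_p = int(self.E[t]), int(self.E[p])
        E_ac = self._cross_edges(a, c, stop=p)
        new_E_t = E_p - E_ac           # edges(b, c)
        new_E_p = E_t + E_ac           # edges(a, b) + edges(a, c)

        ca, cb, cc = (self._child_counts(x) for x in (a, b, c))
        eps_t = ca[0] * cb[1] + ca[1] * cb[0]
        eps_p = (ca[0] + cb[0]) * cc[1] + (ca[1] + cb[1]) * cc[0]
        new_eps_t = cc[0] * cb[1] + cc[1] * cb[0]
        new_eps_p = (cc[0] + cb[0]) * ca[1] + (cc[1] + cb[1]) * ca[0]

        delta = (_term(new_E_t, new_eps_t) + _term(new_E_p, new_eps_p)
                 - _term(E_t, eps_t) - _term(E_p, eps_p))

        if delta < 0 and rng.random() >= math.exp(delta):
            return False, 0.0

        # apply: a moves under p, c moves under t
        if swap_left:
            self.left[t] = c
        else:
            self.right[t] = c
        if int(self.left[p]) == t:
            self.right[p] = a
        else:
            # t could be either child; keep t where it was
            if int(self.right[p]) == t:
                self.left[p] = a
        self._set_parent(c, t)
        self._set_parent(a, p)
        self.nm[t] = cc[0] + cb[0]
        self.nr[t] = cc[1] + cb[1]
        self.E[t] = new_E_t
        self.E[p] = new_E_p
        self.logL += delta
        return True, delta

    # -- pair probabilities ------------------------------------------------

    def accumulate_pair_rho(self, acc: np.ndarray) -> None:
        """Add rho at each pair's LCA into the M x R accumulator ``acc``.

        One postorder pass: at each internal node the metabolite leaves of
        one child are crossed with the reaction leaves of the other. Every
        metabolite-reaction pair has exactly one LCA, so a full pass adds a
        complete rho matrix (whose entries sum to L, since
        sum_t eps_t * rho_t = sum_t E_t = L).
        """
        M = self.M
        # iterative postorder carrying (met_list, rxn_list) per subtree
        lists: dict[int, tuple[list[int], list[int]]] = {}
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            l, r = int(self.left[node]), int(self.right[node])
            if not expanded:
                stack.append((node, True))
                for c in (l, r):
                    if c >= 0:
                        stack.append((c, False))
                continue
            def leaf_lists(child: int) -> tuple[list[int], list[int]]:
                if child < 0:
                    leaf = ~child
                    return ([leaf], []) if leaf < M else ([], [leaf - M])
                return lists.pop(child)
            lm, lr_ = leaf_lists(l)
            rm, rr_ = leaf_lists(r)
            e = self.eps(node)
            if e > 0 and self.E[node] > 0:
                rho = float(self.E[node]) / e
                if lm and rr_:
                    acc[np.ix_(lm, rr_)] += rho
                if rm and lr_:
                    acc[np.ix_(rm, lr_)] += rho
            lists[node] = (lm + rm, lr_ + rr_)
        lists.clear()


# ---------------------------------------------------------------------------
# Pair probabilities container
# ---------------------------------------------------------------------------

@dataclass
class PairProbabilities:
    """A probability for every metabolite-reaction pair, present or absent.

    ``p`` is an M x R array indexed by the sorted id lists. For the raw
    hierarchical fit, ``p`` holds the sample-averaged rho_mr and ``d``
    (= 1 - p) is the tree distance; degree-corrected or null-model
    probabilities use the same container.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.metabolite_ids), len(self.reaction_ids)):
            raise ValueError("probability matrix shape does not match id lists")
        finite = self.p[np.isfinite(self.p)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("pair probabilities must lie in [0, 1]")
        np.clip(self.p, 0.0, 1.0, out=self.p)

    @property
    def d(self) -> np.ndarray:
        """Tree distances d_mr = 1 - rho_mr."""
        return 1.0 - self.p

    def lookup(self, metabolite: str, reaction: str) -> float:
        i = self.metabolite_ids.index(metabolite)
        j = self.reaction_ids.index(reaction)
        return float(self.p[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("# metabolite\treaction\tprobability\n")
            for i, m in enumerate(self.metabolite_ids):
                for j, r in enumerate(self.reaction_ids):
                    fh.write(f"{m}\t{r}\t{self.p[i, j]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairProbabilities":
        mets: dict[str, int] = {}
        rxns: dict[str, int] = {}
        triples: list[tuple[str, str, float]] = []
        with Path(path).open() as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                m, r, v = line.split("\t")
                mets.setdefault(m, len(mets))
                rxns.setdefault(r, len(rxns))
                triples.append((m, r, float(v)))
        if not triples:
            raise ValueError(f"{path}: no probability entries")
        mids = tuple(sorted(mets))
        rids = tuple(sorted(rxns))
        mi = {m: i for i, m in enumerate(mids)}
        ri = {r: j for j, r in enumerate(rids)}
        p = np.full((len(mids), len(rids)), np.nan)
        for m, r, v in triples:
            p[mi[m], ri[r]] = v
        if np.isnan(p).any():
            raise ValueError(f"{path}: probability matrix has missing pairs")
        return cls(mids, rids, p)


# ---------------------------------------------------------------------------
# MCMC driver
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    """Schedule of the dendrogram sampler.

    ``burn_in`` defaults to 50 * (M+R)^2 proposals; ``sample_interval``
    (default M+R) is counted in *proposals*, not accepted moves: sampling at
    acceptance events would draw from the jump chain, which over-represents
    states with high exit acceptance and is measurably biased on enumerable
    tree spaces. ``num_samples`` dendrograms are averaged. The last ``eq_window`` burn-in trace points feed a linear
    slope test; a drift larger than ``eq_tol`` standard deviations of the
    window's residuals raises :class:`NonEquilibratedWarning`.
    """

    burn_in: int | None = None
    num_samples: int = 1000
    sample_interval: int | None = None
    seed: int = 0
    eq_window: int = 50
    eq_tol: float = 3.0

    def __post_init__(self) -> None:
        for name in ("num_samples", "eq_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.sample_interval is not None and self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")


def log_likelihood(dend: Dendrogram) -> float:
    """Dendrogram log-likelihood, recomputed from scratch (always <= 0)."""
    dend.validate()
    return dend._loglik_full()


def mcmc_step(dend: Dendrogram, rng: np.random.Generator) -> tuple[Dendrogram, bool]:
    """Apply one branch-swap proposal in place; returns (dend, accepted)."""
    accepted, _ = dend.step(rng)
    return dend, accepted


def fit(
    net: BipartiteNetwork,
    cfg: McmcConfig | None = None,
) -> tuple[PairProbabilities, np.ndarray]:
    """Fit the hierarchical model and average rho_mr over sampled dendrograms.

    Returns the pair-probability container (sample mean of rho at each
    pair's LCA) and a trace array of shape (n, 2) with columns
    (proposal index, log-likelihood) for convergence diagnostics. Fully
    reproducible given ``cfg.seed``.
    """
    cfg = cfg or McmcConfig()
    if net.L == 0:
        raise ValueError("cannot fit a network with no edges")
    rng = np.random.default_rng(cfg.seed)
    N = net.M + net.R
    burn_in = cfg.burn_in if cfg.burn_in is not None else 50 * N * N
    interval = cfg.sample_interval if cfg.sample_interval is not None else N

    dend = Dendrogram(net, rng)
    trace: list[tuple[int, float]] = [(0, dend.logL)]
    record_every = max(1, burn_in // max(cfg.eq_window * 4, 200))
    step = 0
    for _ in range(burn_in):
        dend.step(rng)
        step += 1
        if step % record_every == 0:
            trace.append((step, dend.logL))

    _check_equilibrium(trace, cfg)

    acc = np.zeros((net.M, net.R))
    dend.logL = dend._loglik_full()  # drop accumulated float drift
    for s in range(cfg.num_samples):
        for _ in range(interval):
            dend.step(rng)
            step += 1
        dend.accumulate_pair_rho(acc)
        trace.append((step, dend.logL))
        if (s + 1) % 200 == 0:
            dend.logL = dend._loglik_full()

    rho = acc / cfg.num_samples
    pairs = PairProbabilities(net.metabolite_ids, net.reaction_ids, rho)
    return pairs, np.asarray(trace, dtype=float)


def _check_equilibrium(trace: list[tuple[int, float]], cfg: McmcConfig) -> None:
    """Two-sided stationarity heuristic on the burn-in log-likelihood trace.

    (a) a linear drift over the last ``eq_window`` points large compared to
    the residual fluctuation flags a steep trend; (b) a late-quarter mean
    well above the preceding quarter flags slow climbing that a short
    window cannot see. Both use ``eq_tol`` standard deviations with a small
    absolute floor so that a chain sitting at a perfect-fit plateau
    (fluctuations at float precision) never warns.
    """
    values = np.asarray([v for _, v in trace], dtype=float)
    if len(values) < 12:
        return
    floor = 1e-6

    window = values[-cfg.eq_window:]
    x = np.arange(len(window), dtype=float)
    slope, intercept = np.polyfit(x, window, 1)
    scale = (window - (slope * x + intercept)).std()
    drift = abs(slope) * len(window)
    steep = drift > cfg.eq_tol * scale and drift > floor

    q = len(values) // 4
    prev, last = values[2 * q: 3 * q], values[3 * q:]
    diff = last.mean() - prev.mean()
    climbing = diff > cfg.eq_tol * max(last.std(), floor) and diff > floor

    if steep or climbing:
        warnings.warn(
            f"log-likelihood still trending at end of burn-in "
            f"(window drift {drift:.3g} vs {scale:.3g}; quarter rise "
            f"{diff:.3g} vs {last.std():.3g}); increase burn_in",
            NonEquilibratedWarning,
            stacklevel=3,
        )
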