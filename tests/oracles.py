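"""Brute-force oracles for tiny bipartite networks.

Everything here is computed from first principles — exhaustive enumeration
of all rooted binary leaf-labelled trees and direct evaluation of the
Bernoulli likelihood — deliberately sharing no code with the package, so it
can serve as an independent reference for the fitting machinery.
"""

import math
from itertools import count


def all_dendrograms(leaves):
    """Yield every rooted binary tree (unordered children) over ``leaves``.

    Trees are nested 2-tuples with string leaves; there are (2n-3)!! of
    them for n leaves. Generated by leaf insertion: every tree over n+1
    leaves arises uniquely by attaching the new leaf on one of the 2n-1
    positions (each subtree slot, or above the root) of a tree over n.
    """
    leaves = list(leaves)
    if not leaves:
        return
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in all_dendrograms(rest):
        for spot in _insert_points(sub):
            yield _attach(sub, spot, first)


def _insert_points(tree):
    yield ()
    if isinstance(tree, tuple):
        for i, child in enumerate(tree):
            for p in _insert_points(child):
                yield (i,) + p


def _attach(tree, path, leaf):
    if not path:
        return (leaf, tree)
    i = path[0]
    children = list(tree)
    children[i] = _attach(children[i], path[1:], leaf)
    return tuple(children)


def tree_loglik_and_pair_rho(tree, edges, is_metabolite):
    """Log-likelihood of a dendrogram plus rho at every pair's ancestor.

    ``edges`` is a set of (metabolite, reaction) label pairs,
    ``is_metabolite`` maps labels to booleans. Returns (loglik, dict
    {(m, r): rho at the pair's lowest common ancestor}).
    """
    pair_rho = {}

    def rec(node):
        if not isinstance(node, tuple):
            mets = [node] if is_metabolite[node] else []
            rxns = [] if is_metabolite[node] else [node]
            return mets, rxns, 0.0
        lm, lr, ll_left = rec(node[0])
        rm, rr, ll_right = rec(node[1])
        eps = len(lm) * len(rr) + len(rm) * len(lr)
        E = sum((m, r) in edges for m in lm for r in rr)
        E += sum((m, r) in edges for m in rm for r in lr)
        ll = ll_left + ll_right
        if eps > 0:
            rho = E / eps
            if E > 0:
                ll += E * math.log(rho)
            if E < eps:
                ll += (eps - E) * math.log(1.0 - rho)
        else:
            rho = 0.0
        for m in lm:
            for r in rr:
                pair_rho[(m, r)] = rho
        for m in rm:
            for r in lr:
                pair_rho[(m, r)] = rho
        return lm + rm, lr + rr, ll

    _, _, ll = rec(tree)
    return ll, pair_rho


def exact_pair_probabilities(labels, edges, is_metabolite):
    """Likelihood-weighted average of rho_mr over ALL dendrograms.

    The exact quantity that MCMC sampling under a likelihood-proportional
    stationary distribution estimates. Only feasible for a handful of
    leaves.
    """
    total = 0.0
    acc = {}
    for tree in all_dendrograms(labels):
        ll, pr = tree_loglik_and_pair_rho(tree, edges, is_metabolite)
        w = math.exp(ll)
        total += w
        for key, rho in pr.items():
            acc[key] = acc.get(key, 0.0) + w * rho
    return {key: v / total for key, v in acc.items()}


def canonical_form(dend, labels, node=None):
    """Order-independent canonical form of a package Dendrogram state.

    ``labels`` maps leaf index (metabolites first, then reactions) to the
    node label, so the form is directly comparable with
    :func:`canonical_nested` applied to oracle trees.
    """
    if node is None:
        node = dend.root
    if node < 0:
        return (0, labels[~node])
    a = canonical_form(dend, labels, int(dend.left[node]))
    b = canonical_form(dend, labels, int(dend.right[node]))
    return (1, a, b) if a <= b else (1, b, a)


def canonical_nested(tree):
    """Canonical form of an oracle nested-tuple tree (for cross-matching)."""
    if not isinstance(tree, tuple):
        return (0, tree)
    a, b = canonical_nested(tree[0]), canonical_nested(tree[1])
    return (1, a, b) if a <= b else (1, b, a)


class ScriptedRng:
    """Replays a fixed sequence of integer/uniform draws (for forcing a
    specific MCMC proposal)."""

    def __init__(self, integers=(), randoms=()):
        self._ints = iter(integers)
        self._rands = iter(randoms)

    def integers(self, *args, **kwargs):
        return next(self._ints)

    def random(self):
        return next(self._rands)
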