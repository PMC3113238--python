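"""Reaction scores: combination probabilities, TDB/CMB/CN models, Sigma."""

import numpy as np
import pandas as pd
import pytest

import tdbscore as t
from tdbscore.hrbg import PairProbabilities
from tdbscore.scoring import _log_terms


def _pp(mets, rxns, p):
    return PairProbabilities(tuple(mets), tuple(rxns), np.asarray(p, float))


# ---------------------------------------------------------------------------
# Degree-corrected TDB probabilities
# ---------------------------------------------------------------------------

class TestTdbProbabilities:
    def _net_and_pairs(self, d):
        """Network with metabolite degrees 2, 1, 1 and a given d matrix."""
        net = t.BipartiteNetwork.from_edges(
            [("a", "r1"), ("a", "r2"), ("b", "r1"), ("c", "r2")]
        )
        return net, _pp(net.metabolite_ids, net.reaction_ids, 1.0 - np.asarray(d))

    def test_zero_distance_gives_certainty(self):
        net, pairs = self._net_and_pairs(np.zeros((3, 2)))
        p = t.tdb_probabilities(pairs, net)
        assert np.allclose(p.p, 1.0)

    def test_monotone_decreasing_in_distance(self):
        net, pairs = self._net_and_pairs([[0.2, 0.8], [0.5, 0.5], [0.5, 0.5]])
        p = t.tdb_probabilities(pairs, net)
        assert p.p[0, 0] > p.p[0, 1]  # same metabolite, closer pair wins

    def test_monotone_in_degree(self):
        net, pairs = self._net_and_pairs(np.full((3, 2), 0.5))
        p = t.tdb_probabilities(pairs, net)
        # metabolite 'a' (degree 2) beats 'b' and 'c' (degree 1) at equal d
        assert p.p[0, 0] > p.p[1, 0]
        assert p.p[0, 1] > p.p[2, 1]

    def test_far_pair_sits_at_configuration_baseline(self):
        """At maximal distance p ~= k_m / (k_m + R), the expected-degree
        share that keeps the total link count calibrated."""
        net, pairs = self._net_and_pairs(np.ones((3, 2)))
        p = t.tdb_probabilities(pairs, net)
        km = np.array([2.0, 1.0, 1.0])
        assert np.allclose(p.p, (km / (km + net.R))[:, None])

    def test_undefined_distance_names_pair(self):
        net = t.BipartiteNetwork.from_edges([("a", "r1"), ("b", "r2")])
        bad = _pp(net.metabolite_ids, net.reaction_ids, [[0.5, np.nan], [0.5, 0.5]])
        with pytest.raises(ValueError, match="'a'.*'r2'"):
            t.tdb_probabilities(bad, net)


# ---------------------------------------------------------------------------
# Combination probability and absolute scores
# ---------------------------------------------------------------------------

class TestCombinationProbability:
    def test_certainty_case(self):
        p = _pp("abc", ["r1"], [[1.0], [1.0], [0.0]])
        assert t.combination_probability({"a", "b"}, "r1", p) == pytest.approx(1.0)

    def test_excluded_metabolite_with_p_one_vetoes(self):
        p = _pp("abc", ["r1"], [[1.0], [1.0], [1.0]])
        assert t.combination_probability({"a", "b"}, "r1", p) == 0.0

    def test_matches_hand_product(self):
        p = _pp("abc", ["r1", "r2"], [[0.9, 0.1], [0.5, 0.4], [0.2, 0.3]])
        want = 0.9 * 0.5 * (1 - 0.2)
        assert t.combination_probability({"a", "b"}, "r1", p) == pytest.approx(want)
        want2 = 0.1 * (1 - 0.4) * 0.3
        assert t.combination_probability({"a", "c"}, "r2", p) == pytest.approx(want2)

    def test_unknown_metabolite_rejected(self):
        p = _pp("ab", ["r1"], [[0.5], [0.5]])
        with pytest.raises(ValueError, match="unknown"):
            t.combination_probability({"zz"}, "r1", p)

    def test_log_space_matches_direct_product(self):
        rng = np.random.default_rng(0)
        p = _pp([f"m{i}" for i in range(6)], [f"r{j}" for j in range(4)],
                rng.uniform(0.05, 0.95, (6, 4)))
        nu = {"m0", "m3", "m4"}
        for j, r in enumerate(p.reaction_ids):
            direct = 1.0
            for i, m in enumerate(p.metabolite_ids):
                direct *= p.p[i, j] if m in nu else 1 - p.p[i, j]
            assert t.combination_probability(nu, r, p) == pytest.approx(
                direct, rel=1e-12
            )


class TestScoreTdb:
    def test_unique_realizing_reaction_scores_one(self):
        p = _pp("abc", ["r1", "r2", "r3"],
                [[1, 0, 1], [1, 0, 0], [0, 1, 0]])
        assert t.score_tdb({"a", "b"}, p) == pytest.approx(1.0)

    def test_matches_bruteforce_sum(self):
        rng = np.random.default_rng(1)
        p = _pp("abc", ["r1", "r2", "r3"], rng.uniform(0.1, 0.9, (3, 3)))
        nu = {"a", "c"}
        brute = sum(
            t.combination_probability(nu, r, p) for r in p.reaction_ids
        )
        assert t.score_tdb(nu, p) == pytest.approx(brute, rel=1e-12)

    def test_sum_includes_own_reaction(self):
        # one reaction only: the scored set's own column is the whole sum
        p = _pp("ab", ["r1"], [[0.7], [0.6]])
        assert t.score_tdb({"a", "b"}, p) == pytest.approx(0.42)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        mat = rng.uniform(0.1, 0.9, (4, 3))
        p1 = _pp("abcd", ["r1", "r2", "r3"], mat)
        # permute metabolite labels: score of the equivalent set is equal
        perm = [2, 0, 3, 1]
        p2 = _pp([p1.metabolite_ids[i] for i in perm], ["r1", "r2", "r3"],
                 mat[perm])
        assert t.score_tdb({"a", "c"}, p1) == pytest.approx(
            t.score_tdb({"a", "c"}, p2), rel=1e-12
        )

    def test_monotone_in_member_probability(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.1, 0.8, (3, 3))
        nu = {"a", "b"}
        p_lo = _pp("abc", ["r1", "r2", "r3"], base)
        bumped = base.copy()
        bumped[0, 1] += 0.1  # 'a' is in nu: raising its p cannot hurt
        p_hi = _pp("abc", ["r1", "r2", "r3"], bumped)
        assert t.score_tdb(nu, p_hi) >= t.score_tdb(nu, p_lo)
        bumped2 = base.copy()
        bumped2[2, 1] += 0.1  # 'c' is outside nu: raising its p cannot help
        p_out = _pp("abc", ["r1", "r2", "r3"], bumped2)
        assert t.score_tdb(nu, p_out) <= t.score_tdb(nu, p_lo)


# ---------------------------------------------------------------------------
# Configuration-model scores
# ---------------------------------------------------------------------------

class TestScoreCmb:
    def test_regular_network_symmetric(self):
        # 4x4 cycle: every metabolite and reaction has degree 2
        edges = [(f"m{i}", f"r{i}") for i in range(4)]
        edges += [(f"m{i}", f"r{(i + 1) % 4}") for i in range(4)]
        net = t.BipartiteNetwork.from_edges(edges)
        members = net.reaction_members()
        scores = {r: t.score_cmb(members[r], net) for r in net.reaction_ids}
        vals = list(scores.values())
        assert np.allclose(vals, vals[0])

    def test_analytic_matches_numeric_on_reaction_regular_net(self):
        """When all k_r are equal the mean-degree approximation is exact, so
        the closed form must equal the co-occurrence sum over CMB pair
        probabilities."""
        edges = [(f"m{i}", f"r{i}") for i in range(4)]
        edges += [(f"m{i}", f"r{(i + 1) % 4}") for i in range(4)]
        net = t.BipartiteNetwork.from_edges(edges)
        cmb = t.cmb_probabilities(net)
        for r, nu in net.reaction_members().items():
            numeric = sum(
                t.combination_probability(nu, rr, cmb) for rr in net.reaction_ids
            )
            assert t.score_cmb(nu, net) == pytest.approx(numeric, rel=1e-9)

    def test_clamps_large_degree_products(self, caplog):
        net = t.BipartiteNetwork.from_edges(
            [("hub", f"r{j}") for j in range(3)] + [("x", "r0")]
        )
        with caplog.at_level("WARNING"):
            s = t.score_cmb({"hub"}, net)
        assert 0 < s <= net.R
        assert "clamped" in caplog.text

    def test_unknown_metabolite_rejected(self, toy_net):
        with pytest.raises(ValueError, match="unknown"):
            t.score_cmb({"nope"}, toy_net)


class TestScoreCn:
    def test_no_shared_reaction_means_zero(self):
        net = t.BipartiteNetwork.from_edges(
            [("a", "r1"), ("b", "r2"), ("c", "r2"), ("c", "r3"), ("b", "r3")]
        )
        cn = t.score_cn(net)
        i = net.metabolite_index()["a"]
        assert np.all(cn.p[i] == 0.0)

    def test_matches_hand_count(self):
        # b and c share r2 and r3 (o_bc = 2); a shares nothing
        net = t.BipartiteNetwork.from_edges(
            [("a", "r1"), ("b", "r2"), ("c", "r2"), ("c", "r3"), ("b", "r3")]
        )
        cn = t.score_cn(net)
        mi, ri = net.metabolite_index(), net.reaction_index()
        # pair (b, r2): the only co-member is c; o_bc = 2 minus the
        # co-occurrence inside r2 itself leaves 1, the global maximum
        for m, r in [("b", "r2"), ("b", "r3"), ("c", "r2"), ("c", "r3")]:
            assert cn.p[mi[m], ri[r]] == pytest.approx(1.0)
        assert cn.p[mi["b"], ri["r1"]] == 0.0

    def test_ranking_invariant_under_rescaling(self):
        net = t.generate_cmb(t.GeneratorSpec(M=15, R=25, seed=3))
        cn = t.score_cn(net)
        scaled = PairProbabilities(
            cn.metabolite_ids, cn.reaction_ids, cn.p * 0.5
        )
        assert t.auc(cn, net) == pytest.approx(t.auc(scaled, net))


# ---------------------------------------------------------------------------
# Score tables and relative scores
# ---------------------------------------------------------------------------

class TestRelativeScores:
    def _table(self, s_tdb, s_cmb, ids=None):
        ids = ids or [f"r{i}" for i in range(len(s_tdb))]
        return pd.DataFrame(
            {"reaction_id": ids, "size": 2, "s_tdb": s_tdb, "s_cmb": s_cmb}
        )

    def test_equal_scores_give_sigma_one(self):
        out = t.relative_scores(self._table([0.5, 2.0], [0.5, 2.0]))
        assert np.allclose(out["sigma"], 1.0)

    def test_zero_cmb_flagged_undefined(self):
        out = t.relative_scores(self._table([0.5, 1.0], [0.5, 0.0]))
        row = out.set_index("reaction_id").loc["r1"]
        assert np.isnan(row["sigma"])

    def test_ranks_are_permutation_descending(self):
        out = t.relative_scores(self._table([3.0, 1.0, 2.0], [1, 1, 1]))
        assert sorted(out["rank"]) == [1, 2, 3]
        assert out.sort_values("rank")["s_tdb"].is_monotonic_decreasing

    def test_rank_by_sigma(self):
        out = t.relative_scores(
            self._table([2.0, 1.0], [4.0, 1.0]), rank_by="sigma"
        )
        best = out.loc[out["rank"] == 1, "reaction_id"].item()
        assert best == "r1"  # sigma 1.0 beats sigma 0.5

    def test_ties_break_stably_by_id(self):
        out = t.relative_scores(self._table([1.0, 1.0], [1.0, 1.0],
                                            ids=["zz", "aa"]))
        first = out.loc[out["rank"] == 1, "reaction_id"].item()
        assert first == "aa"


def test_score_reactions_joins_confidence(toy_net):
    pairs = _pp(toy_net.metabolite_ids, toy_net.reaction_ids,
                np.full((3, 2), 0.5))
    records = [
        t.ReactionRecord("r1", frozenset(["m1", "m2"]), confidence=4),
        t.ReactionRecord("r2", frozenset(["m2", "m3"]), confidence=1),
    ]
    table = t.score_reactions(toy_net, pairs, records=records)
    got = table.set_index("reaction_id")["confidence"].to_dict()
    assert got == {"r1": 4, "r2": 1}


def test_score_reactions_missing_record_rejected(toy_net):
    pairs = _pp(toy_net.metabolite_ids, toy_net.reaction_ids,
                np.full((3, 2), 0.5))
    records = [t.ReactionRecord("r1", frozenset(["m1"]), confidence=2)]
    with pytest.raises(ValueError, match="absent"):
        t.score_reactions(toy_net, pairs, records=records)


def test_write_score_table_round_trippable(toy_net, tmp_path):
    pairs = _pp(toy_net.metabolite_ids, toy_net.reaction_ids,
                np.full((3, 2), 0.4))
    table = t.score_reactions(toy_net, pairs)
    f = tmp_path / "scores.tsv"
    t.write_score_table(table, f)
    back = pd.read_csv(f, sep="\t", comment=None, skiprows=1,
                       names=["reaction_id", "size", "s_tdb", "s_cmb",
                              "sigma", "rank"])
    assert len(back) == toy_net.R
    assert np.allclose(back["s_tdb"], table["s_tdb"], rtol=1e-9)
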