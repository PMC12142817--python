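import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fminer.similarity import (
    RoleWeights,
    calc_jaccard,
    find_sim_rxs,
    grp_sim_score,
    jaccard,
    network_node_table,
    similarity_network,
    wt_similarity,
)
from fminer.standardize import FormulaDataset

from .oracles import brute_jaccard_matrix

ITEMS = [f"h{k}" for k in range(12)]
set_strategy = st.frozensets(st.sampled_from(ITEMS), min_size=1, max_size=8)


def dataset(*sets, prefix="F"):
    return FormulaDataset(
        formulas=[(f"{prefix}{i}", frozenset(s)) for i, s in enumerate(sets)]
    )


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard(a, b) == expected

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), set())

    @settings(max_examples=200, deadline=None)
    @given(a=set_strategy, b=set_strategy)
    def test_symmetric_bounded_identity(self, a, b):
        j = jaccard(a, b)
        assert 0 <= j <= 1
        assert j == jaccard(b, a)
        assert (j == 1) == (a == b)


class TestCalcJaccard:
    def test_identical_pair(self):
        jr = calc_jaccard(dataset({"x", "y"}, {"x", "y"}), threshold=0.5)
        assert jr.matrix.values.tolist() == [[1, 1], [1, 1]]
        assert len(jr.pair_table) == 1

    def test_disjoint_formulas_empty_pairs(self):
        jr = calc_jaccard(dataset({"a"}, {"b"}, {"c"}), threshold=0.1)
        assert jr.pair_table.empty

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(31)
        sets = [
            frozenset(rng.choice(ITEMS, size=int(rng.integers(1, 8)), replace=False))
            for _ in range(30)
        ]
        jr = calc_jaccard(dataset(*sets), threshold=0.0)
        assert np.allclose(jr.matrix.values, brute_jaccard_matrix(sets), atol=1e-12)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            calc_jaccard(dataset({"a"}))


class TestGrpSimScore:
    def test_identical_singleton_groups(self):
        s = [frozenset({"a", "b"})]
        assert grp_sim_score(s, s) == 1.0

    def test_worked_example(self):
        a = [frozenset({"a", "b"}), frozenset({"c", "d"})]
        b = [frozenset({"a", "b"})]
        assert grp_sim_score(a, b) == 0.5

    def test_symmetry_and_brute_force(self):
        rng = np.random.default_rng(32)
        ga = [
            frozenset(rng.choice(ITEMS, size=int(rng.integers(1, 8)), replace=False))
            for _ in range(5)
        ]
        gb = [
            frozenset(rng.choice(ITEMS, size=int(rng.integers(1, 8)), replace=False))
            for _ in range(7)
        ]
        expect = sum(jaccard(a, b) for a in ga for b in gb) / 35
        assert grp_sim_score(ga, gb) == pytest.approx(expect, abs=1e-12)
        assert grp_sim_score(gb, ga) == pytest.approx(expect, abs=1e-12)

    def test_one_iff_all_cross_pairs_identical(self):
        same = [frozenset({"x", "y"})] * 3
        assert grp_sim_score(same, same[:2]) == 1.0
        mixed = [frozenset({"x", "y"}), frozenset({"x"})]
        assert grp_sim_score(mixed, mixed) < 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            grp_sim_score([], [frozenset({"a"})])


class TestWtSimilarity:
    CORE = {"M": "Monarch", "m": "Minister", "a": "Assistant", "e": "Envoy"}

    def test_equal_to_core_scores_one(self):
        ds = dataset(set(self.CORE))
        t = wt_similarity(self.CORE, ds)
        assert t["weighted_score"].tolist() == [1.0]

    def test_disjoint_scores_zero(self):
        ds = dataset({"x", "y"})
        t = wt_similarity(self.CORE, ds)
        assert t["weighted_score"].tolist() == [0.0]

    def test_worked_example(self):
        core = {"M": "Monarch", "m": "Minister"}
        ds = dataset({"M", "x"})
        t = wt_similarity(core, ds)  # 4 / (4 + 3 + 1)
        assert t["weighted_score"].tolist() == [0.5]

    def test_unassigned_core_herb_rejected(self):
        with pytest.raises(ValueError):
            wt_similarity({"M": "Boss"}, dataset({"M"}))

    def test_equal_weights_reduce_to_jaccard(self):
        rng = np.random.default_rng(33)
        w = RoleWeights(monarch=2, minister=2, assistant=2, envoy=2, unassigned=2)
        roles = ["Monarch", "Minister", "Assistant", "Envoy"]
        for _ in range(100):
            core_herbs = rng.choice(ITEMS, size=int(rng.integers(1, 6)), replace=False)
            core = {h: roles[int(rng.integers(4))] for h in core_herbs}
            other = frozenset(
                rng.choice(ITEMS, size=int(rng.integers(1, 8)), replace=False)
            )
            t = wt_similarity(core, dataset(other), w)
            assert t["weighted_score"].iloc[0] == pytest.approx(
                jaccard(frozenset(core), other), abs=1e-12
            )


class TestFindSimRxs:
    def test_exact_match_ranks_first(self, classics):
        target = classics.get("Siwu Tang")
        t = find_sim_rxs(target, classics)
        assert t.iloc[0]["formula_id"] == "Siwu Tang"
        assert t.iloc[0]["jaccard"] == 1.0

    def test_impossible_threshold_empty(self, classics):
        t = find_sim_rxs(frozenset({"Huangqi", "Nonexistent"}), classics, threshold=1.0)
        assert t.empty

    def test_matches_brute_scan(self):
        rng = np.random.default_rng(34)
        sets = [
            frozenset(rng.choice(ITEMS, size=int(rng.integers(1, 8)), replace=False))
            for _ in range(15)
        ]
        ref = dataset(*sets)
        target = frozenset({"h0", "h1", "h2"})
        t = find_sim_rxs(target, ref, threshold=0.0)
        expect = sorted(
            ((f"F{i}", jaccard(target, s)) for i, s in enumerate(sets)),
            key=lambda r: (-r[1], r[0]),
        )
        assert list(map(tuple, t.values)) == [(f, pytest.approx(j)) for f, j in expect]

    def test_empty_target_rejected(self, classics):
        with pytest.raises(ValueError):
            find_sim_rxs(frozenset(), classics)


class TestSimilarityNetwork:
    def toy(self):
        # J(F0,F1)=0.9, J(F0,F2)=0.9, J(F1,F2)=0.5 via constructed sets:
        # F0 = 18 shared with each of F1, F2; overlap structure below
        jr = calc_jaccard(dataset({"a", "b", "c"}, {"a", "b", "d"}, {"a", "c", "d"}), 0.0)
        # overwrite with the exact toy values to pin the contract
        jr.matrix.iloc[0, 1] = jr.matrix.iloc[1, 0] = 0.9
        jr.matrix.iloc[0, 2] = jr.matrix.iloc[2, 0] = 0.9
        jr.matrix.iloc[1, 2] = jr.matrix.iloc[2, 1] = 0.5
        return jr

    def test_degree_centralities_exact(self):
        g = similarity_network(self.toy(), threshold=0.8)
        cents = {n: g.nodes[n]["degree_centrality"] for n in g.nodes}
        assert cents == {"F0": 1.0, "F1": 0.5, "F2": 0.5}

    def test_strict_threshold_no_edges_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            similarity_network(self.toy(), threshold=0.95)

    def test_raising_threshold_never_raises_degree(self):
        jr = self.toy()
        g_low = similarity_network(jr, threshold=0.4)
        g_high = similarity_network(jr, threshold=0.8)
        for n in g_high.nodes:
            assert g_high.degree[n] <= g_low.degree[n]

    def test_planted_hub_attains_max_centrality(self):
        rng = np.random.default_rng(35)
        hub = frozenset({"a", "b", "c", "d", "e"})
        near = []
        for i in range(6):
            variant = set(hub)
            variant.discard(sorted(hub)[i % 5])
            near.append(frozenset(variant | {"a"}))
        noise = [
            frozenset(rng.choice([f"z{k}" for k in range(20)], size=5, replace=False))
            for _ in range(10)
        ]
        ds = dataset(hub, *near, *noise)
        jr = calc_jaccard(ds, 0.0)
        g = similarity_network(jr, threshold=0.7)
        table = network_node_table(g)
        assert table.iloc[0]["formula_id"] == "F0"  # the hub
        assert (table["degree_centrality"] <= 1.0).all()

    def test_node_frequency_attribute(self):
        ds = dataset({"a", "b"}, {"a", "b"}, {"a", "c"})
        jr = calc_jaccard(ds, 0.0)
        g = similarity_network(jr, threshold=0.2)
        assert g.nodes["F0"]["frequency"] == 2  # duplicate composition
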