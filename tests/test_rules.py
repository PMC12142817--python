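from itertools import combinations

import numpy as np
import pytest

from fminer.rules import (
    TransactionSet,
    explore_rules,
    extract_rules,
    mine_frequent_itemsets,
    rules_network,
)

from .conftest import random_transactions
from .oracles import brute_frequent, brute_rules


def as_rule_set(rules):
    return {
        (
            tuple(sorted(r.antecedent)),
            tuple(sorted(r.consequent)),
            round(r.support, 12),
            round(r.confidence, 12),
            round(r.lift, 12),
        )
        for r in rules
    }


class TestFrequentItemsets:
    def test_toy_enumeration(self, toy_transactions):
        t = mine_frequent_itemsets(toy_transactions, 0.5)
        got = dict(zip(t["itemset"], t["support"]))
        assert got == {
            ("A",): 0.75,
            ("B",): 0.75,
            ("C",): 0.5,
            ("A", "B"): 0.5,
            ("A", "C"): 0.5,
        }

    def test_support_one_keeps_universal_item(self):
        t = TransactionSet.from_lists([{"X", "Y"}, {"X"}, {"X", "Z"}])
        res = mine_frequent_itemsets(t, 1.0)
        assert list(res["itemset"]) == [("X",)]

    def test_threshold_above_max_support_is_empty(self, toy_transactions):
        assert mine_frequent_itemsets(toy_transactions, 0.8).empty

    def test_downward_closure(self, toy_transactions):
        res = mine_frequent_itemsets(toy_transactions, 0.4)
        frequent = set(res["itemset"])
        for itemset in frequent:
            for r in range(1, len(itemset)):
                for sub in combinations(itemset, r):
                    assert sub in frequent

    def test_empty_transactions_rejected(self):
        with pytest.raises(ValueError):
            mine_frequent_itemsets(TransactionSet.from_lists([]), 0.5)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        trans = random_transactions(rng)
        t = TransactionSet.from_lists(trans)
        min_support = float(rng.choice([0.1, 0.2, 0.3, 0.5]))
        got = dict(
            zip(
                mine_frequent_itemsets(t, min_support)["itemset"],
                mine_frequent_itemsets(t, min_support)["count"],
            )
        )
        expect = {
            tuple(sorted(s)): c for s, c in brute_frequent(trans, min_support).items()
        }
        assert got == expect


class TestExtractRules:
    def test_lift_below_one_excluded(self, toy_transactions):
        # A -> B: support 0.5, confidence 2/3, lift 8/9 < 1
        kept = extract_rules(toy_transactions, 0.4, 0.5, retain_lift_gt1=True)
        assert (frozenset({"A"}), frozenset({"B"})) not in {
            (r.antecedent, r.consequent) for r in kept
        }
        loose = extract_rules(toy_transactions, 0.4, 0.5)
        ab = [r for r in loose if r.antecedent == {"A"} and r.consequent == {"B"}]
        assert ab and abs(ab[0].lift - 8 / 9) < 1e-12

    def test_lift_exactly_one_excluded(self):
        t = TransactionSet.from_lists([{"A", "B"}, {"A", "B"}])
        assert extract_rules(t, 0.5, 0.5, retain_lift_gt1=True) == []
        loose = extract_rules(t, 0.5, 0.5)
        assert {(r.confidence, r.lift) for r in loose} == {(1.0, 1.0)}

    def test_sorted_deterministically(self, toy_transactions):
        rules = extract_rules(toy_transactions, 0.25, 0.3)
        keys = [r.sort_key() for r in rules]
        assert keys == sorted(keys)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        trans = random_transactions(rng)
        t = TransactionSet.from_lists(trans)
        ms = float(rng.choice([0.1, 0.2, 0.3]))
        mc = float(rng.choice([0.4, 0.6, 0.8]))
        lift_flag = bool(rng.integers(2))
        got = as_rule_set(
            extract_rules(t, ms, mc, retain_lift_gt1=lift_flag, max_len=10)
        )
        assert got == brute_rules(trans, ms, mc, lift_gt1=lift_flag)

    def test_multi_item_consequents_flag(self):
        t = TransactionSet.from_lists([{"A", "B", "C"}] * 3 + [{"A"}])
        rules = extract_rules(t, 0.5, 0.5, singleton_consequents=False)
        assert any(len(r.consequent) == 2 for r in rules)


class TestExploreRules:
    def test_grid_is_cross_product(self, toy_transactions):
        grid = explore_rules(toy_transactions, [0.1, 0.3, 0.5], [0.4, 0.6])
        assert len(grid.full) == 6

    def test_single_cell_matches_extract(self, toy_transactions):
        grid = explore_rules(toy_transactions, [0.25], [0.5])
        direct = extract_rules(toy_transactions, 0.25, 0.5, retain_lift_gt1=True)
        assert grid.full.loc[0, "n_rules"] == len(direct)

    def test_empty_combinations_dropped_from_table(self):
        t = TransactionSet.from_lists([{"A", "B"}, {"A", "C"}, {"B", "C"}, {"A"}])
        grid = explore_rules(t, [0.25, 0.99], [0.5])
        assert (grid.table["min_support"] < 0.99).all()
        assert len(grid.full) == 2
        assert grid.table.notna().all().all()  # finite ranges only

    def test_n_rules_monotone_in_both_thresholds(self, toy_transactions):
        grid = explore_rules(
            toy_transactions, [0.1, 0.25, 0.5, 0.75], [0.3, 0.5, 0.7]
        ).full
        piv = grid.pivot(index="min_support", columns="min_confidence", values="n_rules")
        assert (piv.diff(axis=0).fillna(0) <= 0).all().all()
        assert (piv.diff(axis=1).fillna(0) <= 0).all().all()

    def test_grid_rows_match_per_cell_brute_force(self):
        rng = np.random.default_rng(77)
        trans = random_transactions(rng, n_items=8, n_trans=25)
        t = TransactionSet.from_lists(trans)
        grid = explore_rules(t, [0.1, 0.2, 0.4], [0.5, 0.7], max_len=10).full
        for row in grid.itertuples(index=False):
            expect = brute_rules(
                trans, row.min_support, row.min_confidence, lift_gt1=True
            )
            assert row.n_rules == len(expect)
            if expect:
                assert row.min_lift == pytest.approx(min(r[4] for r in expect))
                assert row.support_min == pytest.approx(min(r[2] for r in expect))
                assert row.confidence_max == pytest.approx(max(r[3] for r in expect))


class TestRulesNetwork:
    def test_single_rule_graph(self, toy_transactions):
        rules = extract_rules(toy_transactions, 0.5, 0.9)
        one = rules[:1]
        g = rules_network(one)
        assert g.number_of_nodes() == len(one[0].antecedent) + 2
        assert g.number_of_edges() == len(one[0].antecedent) + 1

    def test_shared_items_deduplicated(self):
        t = TransactionSet.from_lists([{"A", "B"}, {"A", "B"}, {"A", "C"}, {"A", "C"}])
        rules = extract_rules(t, 0.4, 0.5)
        g = rules_network(rules)
        item_nodes = [n for n, d in g.nodes(data=True) if d.get("kind") == "item"]
        assert sorted(item_nodes) == ["A", "B", "C"]

    def test_counts_match_construction(self):
        rng = np.random.default_rng(9)
        t = TransactionSet.from_lists(random_transactions(rng, n_items=6, n_trans=20))
        rules = extract_rules(t, 0.1, 0.3)[:20]
        g = rules_network(rules)
        items = set().union(*[r.antecedent | r.consequent for r in rules])
        assert g.number_of_nodes() == len(items) + len(rules)
        assert g.number_of_edges() == sum(
            len(r.antecedent) + len(r.consequent) for r in rules
        )

    def test_empty_rules_rejected(self):
        with pytest.raises(ValueError):
            rules_network([])
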