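"""Frequent-itemset and association-rule mining over formula transactions.

Each prescription is one transaction; items are standardized ingredient
labels. Mining is level-wise Apriori with candidate pruning by downward
closure. ``explore_rules`` evaluates a whole grid of (min_support,
min_confidence) combinations at once, which is how a practitioner picks
thresholds for dense herbal data instead of trusting a single arbitrary
pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .standardize import FormulaDataset

__all__ = [
    "TransactionSet",
    "AssociationRule",
    "RuleGrid",
    "trans_rules",
    "mine_frequent_itemsets",
    "extract_rules",
    "explore_rules",
    "rules_network",
    "rules_to_frame",
]


@dataclass(frozen=True)
class TransactionSet:
    """Itemset transactions plus their item universe."""

    transactions: tuple[frozenset[str], ...]
    items: frozenset[str]

    def __len__(self) -> int:
        return len(self.transactions)

    @classmethod
    def from_dataset(cls, ds: FormulaDataset) -> "TransactionSet":
        sets = tuple(ds.ingredient_sets)
        items = frozenset().union(*sets) if sets else frozenset()
        return cls(transactions=sets, items=items)

    @classmethod
    def from_lists(cls, lists) -> "TransactionSet":
        sets = tuple(frozenset(t) for t in lists)
        items = frozenset().union(*sets) if sets else frozenset()
        return cls(transactions=sets, items=items)


def trans_rules(ds: FormulaDataset) -> TransactionSet:
    """Convert a cleaned dataset into the transaction form used for mining."""
    return TransactionSet.from_dataset(ds)


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float
    count: int

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")
        if not self.consequent:
            raise ValueError("consequent must be non-empty")

    def sort_key(self) -> tuple:
        return (
            -self.lift,
            -self.support,
            tuple(sorted(self.antecedent)),
            tuple(sorted(self.consequent)),
        )


def _support_counts(
    t: TransactionSet, min_support: float, max_len: int | None = None
) -> dict[frozenset[str], int]:
    """Apriori: counts for all itemsets with support >= min_support."""
    n = len(t)
    if n == 0:
        raise ValueError("empty transaction set")
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    min_count = min_support * n

    counts: dict[frozenset[str], int] = {}
    singles: dict[frozenset[str], int] = {}
    for tr in t.transactions:
        for item in tr:
            key = frozenset((item,))
            singles[key] = singles.get(key, 0) + 1
    level = {s: c for s, c in singles.items() if c >= min_count}
    counts.update(level)
    k = 1
    while level and (max_len is None or k < max_len):
        k += 1
        prev = set(level)
        # candidate generation: join frequent (k-1)-sets sharing a (k-2)-prefix
        sorted_prev = sorted(tuple(sorted(s)) for s in prev)
        candidates: set[frozenset[str]] = set()
        for i, a in enumerate(sorted_prev):
            for b in sorted_prev[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break
                cand = frozenset(a) | frozenset(b)
                if all(frozenset(sub) in prev for sub in combinations(cand, k - 1)):
                    candidates.add(cand)
        if not candidates:
            break
        level = {}
        for tr in t.transactions:
            if len(tr) < k:
                continue
            for cand in candidates:
                if cand <= tr:
                    level[cand] = level.get(cand, 0) + 1
        level = {s: c for s, c in level.items() if c >= min_count}
        counts.update(level)
    return counts


def mine_frequent_itemsets(
    t: TransactionSet, min_support: float, max_len: int | None = None
) -> pd.DataFrame:
    """All itemsets (size >= 1) with support >= min_support.

    Sorted by support descending, then by size, then lexicographically.
    """
    counts = _support_counts(t, min_support, max_len)
    n = len(t)
    rows = sorted(
        ((tuple(sorted(s)), c / n, c) for s, c in counts.items()),
        key=lambda r: (-r[1], len(r[0]), r[0]),
    )
    return pd.DataFrame(rows, columns=["itemset", "support", "count"])


def extract_rules(
    t: TransactionSet,
    min_support: float,
    min_confidence: float,
    *,
    retain_lift_gt1: bool = False,
    max_len: int = 5,
    singleton_consequents: bool = True,
) -> list[AssociationRule]:
    """Association rules meeting the support/confidence thresholds.

    ``retain_lift_gt1`` keeps only rules with lift strictly above 1 (the
    positive-association filter). By default consequents are single items,
    the convention of classic rule miners; set ``singleton_consequents``
    False to enumerate every antecedent/consequent split.
    Output order is (lift desc, support desc, lexicographic) and is
    deterministic.
    """
    if not 0 < min_confidence <= 1:
        raise ValueError("min_confidence must be in (0, 1]")
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    counts = _support_counts(t, min_support, max_len)
    n = len(t)
    rules: list[AssociationRule] = []
    for itemset, count in counts.items():
        if len(itemset) < 2:
            continue
        support = count / n
        if singleton_consequents:
            splits = [(itemset - {c}, frozenset((c,))) for c in itemset]
        else:
            splits = []
            for r in range(1, len(itemset)):
                for cons in combinations(sorted(itemset), r):
                    cons_f = frozenset(cons)
                    splits.append((itemset - cons_f, cons_f))
        for ante, cons in splits:
            if not ante:
                continue
            confidence = count / counts[ante]
            if confidence < min_confidence:
                continue
            lift = confidence * n / counts[cons]
            if retain_lift_gt1 and not lift > 1:
                continue
            rules.append(
                AssociationRule(
                    antecedent=ante,
                    consequent=cons,
                    support=support,
                    confidence=confidence,
                    lift=lift,
                    count=count,
                )
            )
    rules.sort(key=AssociationRule.sort_key)
    return rules


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    """Tidy table of rules (antecedent/consequent ``|``-joined)."""
    return pd.DataFrame(
        {
            "antecedent": ["|".join(sorted(r.antecedent)) for r in rules],
            "consequent": ["|".join(sorted(r.consequent)) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
            "count": [r.count for r in rules],
        }
    )


@dataclass
class RuleGrid:
    """Result of a parameter-grid exploration.

    ``table`` holds only the combinations that produced at least one rule
    (range statistics over an empty rule set are undefined, the ``-Inf``
    cases, and are dropped). ``full`` keeps every evaluated combination,
    including zero-rule ones, for bubble-chart style exports.
    """

    table: pd.DataFrame
    full: pd.DataFrame


_GRID_COLUMNS = [
    "min_support",
    "min_confidence",
    "n_rules",
    "support_min",
    "support_max",
    "confidence_min",
    "confidence_max",
    "min_lift",
]


def explore_rules(
    t: TransactionSet,
    supports: list[float],
    confidences: list[float],
    *,
    max_len: int = 5,
    singleton_consequents: bool = True,
) -> RuleGrid:
    """Batch-evaluate every (min_support, min_confidence) combination.

    For each pair, rules are extracted with the lift > 1 retention filter
    and summarized: rule count, support range, confidence range, minimum
    lift. All |supports| x |confidences| combinations are evaluated; the
    filtered table drops zero-rule rows.
    """
    if not supports or not confidences:
        raise ValueError("supports and confidences must be non-empty")
    base = extract_rules(
        t,
        min(supports),
        min(confidences),
        retain_lift_gt1=True,
        max_len=max_len,
        singleton_consequents=singleton_consequents,
    )
    rows = []
    for s in supports:
        for c in confidences:
            sel = [r for r in base if r.support >= s and r.confidence >= c]
            if sel:
                rows.append(
                    (
                        s,
                        c,
                        len(sel),
                        min(r.support for r in sel),
                        max(r.support for r in sel),
                        min(r.confidence for r in sel),
                        max(r.confidence for r in sel),
                        min(r.lift for r in sel),
                    )
                )
            else:
                rows.append((s, c, 0, None, None, None, None, None))
    full = pd.DataFrame(rows, columns=_GRID_COLUMNS)
    table = full[full["n_rules"] > 0].reset_index(drop=True)
    return RuleGrid(table=table, full=full)


def rules_network(rules: list[AssociationRule]) -> nx.DiGraph:
    """Bipartite item-rule graph for network-style rule plots.

    Item nodes connect into a rule node (one per rule) which connects out to
    its consequent items; rule nodes carry support/confidence/lift.
    """
    if not rules:
        raise ValueError("empty rule list")
    g = nx.DiGraph()
    for i, r in enumerate(rules):
        rid = f"rule_{i}"
        g.add_node(
            rid,
            kind="rule",
            support=r.support,
            confidence=r.confidence,
            lift=r.lift,
            count=r.count,
        )
        for item in sorted(r.antecedent):
            if item not in g:
                g.add_node(item, kind="item")
            g.add_edge(item, rid)
        for item in sorted(r.consequent):
            if item not in g:
                g.add_node(item, kind="item")
            g.add_edge(rid, item)
    return g
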