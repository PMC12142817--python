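"""Intra- and inter-group formula similarity.

Formulas are sets of standardized ingredient labels, so the natural
similarity is the Jaccard coefficient J(A, B) = |A ∩ B| / |A ∪ B|. On top
of it this module provides:

* ``calc_jaccard`` — the full pairwise matrix within a dataset plus a
  threshold-filtered pair table;
* ``grp_sim_score`` — the mean Jaccard over all cross pairs of two formula
  groups, grpSimScore = (1/(n·m)) Σᵢ Σⱼ J(Aᵢ, Bⱼ);
* ``wt_similarity`` — a weighted Jaccard in which the ingredients of a
  core formula carry role weights (Monarch/Minister/Assistant/Envoy, the
  classical jun-chen-zuo-shi ranking) and everything else the unassigned
  weight;
* ``find_sim_rxs`` — ranked retrieval of reference formulas similar to a
  target;
* ``similarity_network`` — the thresholded similarity graph with degree
  centrality, used to spot hub prescriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .standardize import FormulaDataset

__all__ = [
    "RoleWeights",
    "JaccardResult",
    "jaccard",
    "calc_jaccard",
    "grp_sim_score",
    "wt_similarity",
    "find_sim_rxs",
    "similarity_network",
    "network_node_table",
]

ROLES = ("Monarch", "Minister", "Assistant", "Envoy", "unassigned")


@dataclass(frozen=True)
class RoleWeights:
    """Positive weights for the four classical ingredient roles.

    ``unassigned`` applies to any herb outside the core formula (and to
    core herbs left without an explicit role, which is an error for
    ``wt_similarity``). The default 4/3/2/1/1 ranking follows the
    Monarch > Minister > Assistant > Envoy hierarchy.
    """

    monarch: float = 4.0
    minister: float = 3.0
    assistant: float = 2.0
    envoy: float = 1.0
    unassigned: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.monarch, self.minister, self.assistant, self.envoy, self.unassigned)
        if any(v <= 0 for v in vals):
            raise ValueError("all role weights must be positive")

    def of(self, role: str) -> float:
        try:
            return {
                "Monarch": self.monarch,
                "Minister": self.minister,
                "Assistant": self.assistant,
                "Envoy": self.envoy,
                "unassigned": self.unassigned,
            }[role]
        except KeyError:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}") from None


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """|A ∩ B| / |A ∪ B|; errors when both sets are empty."""
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


@dataclass
class JaccardResult:
    """Symmetric Jaccard matrix over formula ids plus a filtered pair table.

    ``pair_table`` holds (id_a, id_b, jaccard) rows with J >= threshold,
    sorted by coefficient descending.
    """

    matrix: pd.DataFrame
    pair_table: pd.DataFrame
    threshold: float = 0.0
    frequencies: dict[str, int] = field(default_factory=dict)


def calc_jaccard(ds: FormulaDataset, threshold: float = 0.5) -> JaccardResult:
    """Pairwise Jaccard similarity of every formula pair in a dataset."""
    if len(ds) < 2:
        raise ValueError("need at least 2 formulas")
    ids = ds.ids
    sets = ds.ingredient_sets
    n = len(ids)
    mat = np.eye(n)
    rows = []
    for i, j in combinations(range(n), 2):
        v = jaccard(sets[i], sets[j])
        mat[i, j] = mat[j, i] = v
        if v >= threshold:
            rows.append((ids[i], ids[j], v))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    # occurrence frequency: how often each exact composition appears in ds
    comp_counts: dict[frozenset[str], int] = {}
    for _, s in ds.formulas:
        comp_counts[s] = comp_counts.get(s, 0) + 1
    freqs = {fid: comp_counts[s] for fid, s in ds.formulas}
    return JaccardResult(
        matrix=pd.DataFrame(mat, index=ids, columns=ids),
        pair_table=pd.DataFrame(rows, columns=["id_a", "id_b", "jaccard"]),
        threshold=threshold,
        frequencies=freqs,
    )


def grp_sim_score(
    group_a: list[frozenset[str]] | FormulaDataset,
    group_b: list[frozenset[str]] | FormulaDataset,
) -> float:
    """Mean Jaccard coefficient over all cross pairs of two formula groups."""
    sets_a = group_a.ingredient_sets if isinstance(group_a, FormulaDataset) else list(group_a)
    sets_b = group_b.ingredient_sets if isinstance(group_b, FormulaDataset) else list(group_b)
    if not sets_a or not sets_b:
        raise ValueError("both groups must be non-empty")
    total = sum(jaccard(a, b) for a in sets_a for b in sets_b)
    return total / (len(sets_a) * len(sets_b))


def wt_similarity(
    core: dict[str, str],
    others: FormulaDataset,
    weights: RoleWeights = RoleWeights(),
) -> pd.DataFrame:
    """Weighted similarity of each formula to a role-annotated core formula.

    ``core`` maps each core herb to its role. The score against formula F is
    a weighted Jaccard:

        score(F) = Σ_{h ∈ core ∩ F} w(role(h)) / Σ_{h ∈ core ∪ F} w(role(h))

    where herbs outside the core take the ``unassigned`` weight. With all
    weights equal this reduces exactly to the plain Jaccard coefficient.
    Returns (formula_id, weighted_score) sorted descending, ties by id.
    """
    if not core:
        raise ValueError("core formula is empty")
    bad_roles = {h: r for h, r in core.items() if r not in ROLES[:-1]}
    if bad_roles:
        raise ValueError(
            f"core herb(s) without a valid role assignment: {bad_roles}"
        )
    core_set = frozenset(core)

    def weight(h: str) -> float:
        return weights.of(core.get(h, "unassigned"))

    rows = []
    for fid, s in others.formulas:
        num = sum(weight(h) for h in core_set & s)
        den = sum(weight(h) for h in core_set | s)
        rows.append((fid, num / den))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["formula_id", "weighted_score"])


def find_sim_rxs(
    target: frozenset[str] | set[str],
    reference: FormulaDataset,
    threshold: float = 0.0,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Reference formulas similar to a target, ranked by Jaccard descending.

    Only formulas with J >= threshold are kept; ties are broken by
    formula_id, and the result is truncated to ``top_k`` when given.
    """
    target = frozenset(target)
    if not target:
        raise ValueError("target formula is empty")
    if len(reference) == 0:
        raise ValueError("reference dataset is empty")
    rows = [
        (fid, jaccard(target, s))
        for fid, s in reference.formulas
        if jaccard(target, s) >= threshold
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(rows, columns=["formula_id", "jaccard"])


def similarity_network(
    jr: JaccardResult,
    freq: dict[str, int] | None = None,
    threshold: float = 0.8,
) -> nx.Graph:
    """Thresholded formula similarity graph with degree centrality.

    Edges connect formula pairs with J strictly above ``threshold``;
    formulas with no surviving edge are excluded. Each node carries its
    occurrence frequency (node size in the usual rendering) and its degree
    centrality, degree / (n_nodes - 1), computed over the retained nodes.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    freq = freq if freq is not None else jr.frequencies
    ids = list(jr.matrix.index)
    g = nx.Graph()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            v = float(jr.matrix.loc[a, b])
            if v > threshold:
                g.add_edge(a, b, jaccard=v)
    if g.number_of_edges() == 0:
        raise ValueError(
            f"no formula pair exceeds similarity threshold {threshold}"
        )
    n_nodes = g.number_of_nodes()
    for node in g.nodes:
        g.nodes[node]["frequency"] = int(freq.get(node, 0))
        g.nodes[node]["degree_centrality"] = g.degree[node] / (n_nodes - 1)
    return g


def network_node_table(g: nx.Graph) -> pd.DataFrame:
    """Node attribute table (formula_id, frequency, degree_centrality),
    sorted by centrality descending."""
    rows = [
        (n, g.nodes[n].get("frequency", 0), g.nodes[n]["degree_centrality"])
        for n in g.nodes
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(rows, columns=["formula_id", "frequency", "degree_centrality"])
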