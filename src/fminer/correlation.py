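"""Phi correlation and co-occurrence statistics over binary occurrence columns.

The phi coefficient is the Pearson correlation of two binary variables. For
the 2x2 contingency table (a = both present, b = x only, c = y only,
d = neither):

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))

and the chi-square statistic with 1 df equals n * phi^2, which is how the
p-values are obtained here (no continuity correction by default — the
identity only holds without it; a Yates-corrected variant is available by
flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .standardize import FIELD_TYPES, FormulaDataset

__all__ = ["PhiResult", "calc_phi", "cooc", "cooc_network", "phi_long_format"]


@dataclass
class PhiResult:
    """Phi coefficients with chi-square p-values and significance stars.

    ``phi`` is symmetric with unit diagonal where rows and columns coincide;
    ``p`` holds the chi-square p-values (NaN on the diagonal); ``stars`` has
    "*" exactly where p < 0.05. Columns with zero variance (an item present
    in every formula or in none) have undefined phi; they are reported as
    phi 0, p 1 and listed in ``degenerate``.
    """

    phi: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    degenerate: list[str] = field(default_factory=list)


def _check_binary(m: pd.DataFrame, cols: list[str]) -> np.ndarray:
    x = m[cols].to_numpy(dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        bad = [cols[j] for j in sorted(set(np.argwhere(~np.isin(x, (0.0, 1.0)))[:, 1]))]
        raise ValueError(f"non-binary column(s): {bad}")
    return x


def calc_phi(
    m: pd.DataFrame,
    cols_a: list[str] | None = None,
    cols_b: list[str] | None = None,
    *,
    yates: bool = False,
    star_threshold: float = 0.05,
) -> PhiResult:
    """Phi correlation matrix between two binary column sets of a wide matrix.

    With the defaults both sides span all columns, giving the symmetric
    herb-herb matrix; pass e.g. herb columns as ``cols_a`` and symptom
    columns as ``cols_b`` for a rectangular herb-symptom matrix.
    """
    cols_a = list(cols_a) if cols_a is not None else list(m.columns)
    cols_b = list(cols_b) if cols_b is not None else list(m.columns)
    n = len(m)
    if n < 2:
        raise ValueError("need at least 2 rows to correlate")
    x = _check_binary(m, cols_a)
    y = _check_binary(m, cols_b)

    a = x.T @ y                               # both present
    ra, rb = x.sum(axis=0), y.sum(axis=0)     # marginals
    b = ra[:, None] - a                       # x only
    c = rb[None, :] - a                       # y only
    d = n - a - b - c
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
        phi = np.where(denom > 0, (a * d - b * c) / np.where(denom > 0, denom, 1), 0.0)

    degenerate_a = [cols_a[i] for i in np.nonzero((ra == 0) | (ra == n))[0]]
    degenerate_b = [cols_b[i] for i in np.nonzero((rb == 0) | (rb == n))[0]]
    degenerate = sorted(set(degenerate_a) | set(degenerate_b))

    if yates:
        with np.errstate(invalid="ignore", divide="ignore"):
            num = (np.abs(a * d - b * c) - n / 2).clip(min=0) ** 2 * n
            den = (a + b) * (c + d) * (a + c) * (b + d)
            chi2 = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)
    else:
        chi2 = n * phi**2
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(np.asarray(phi) == 0.0, np.where(chi2 == 0, 1.0, p), p)
    bad = np.zeros_like(p, dtype=bool)
    for j, col in enumerate(cols_a):
        if col in degenerate:
            bad[j, :] = True
    for j, col in enumerate(cols_b):
        if col in degenerate:
            bad[:, j] = True
    phi = np.where(bad, 0.0, phi)
    p = np.where(bad, 1.0, p)

    phi_df = pd.DataFrame(phi, index=cols_a, columns=cols_b)
    p_df = pd.DataFrame(p, index=cols_a, columns=cols_b)
    for col in set(cols_a) & set(cols_b):
        phi_df.loc[col, col] = 1.0
        p_df.loc[col, col] = np.nan
    stars = p_df.map(lambda v: "*" if (not np.isnan(v)) and v < star_threshold else "")
    return PhiResult(phi=phi_df, p=p_df, stars=stars, degenerate=degenerate)


def phi_long_format(res: PhiResult) -> pd.DataFrame:
    """Heatmap-ready long table: one row per (row, col) cell."""
    rows = []
    for r in res.phi.index:
        for c in res.phi.columns:
            rows.append(
                (r, c, res.phi.loc[r, c], res.p.loc[r, c], res.stars.loc[r, c])
            )
    return pd.DataFrame(rows, columns=["row", "col", "phi", "p", "star"])


def cooc(ds: FormulaDataset, field: str = "ingredient", min_count: int = 1) -> pd.DataFrame:
    """Pairwise co-occurrence counts within formulas.

    Returns (item_a, item_b, count) with ``item_a < item_b`` lexicographically,
    restricted to pairs with count >= min_count, sorted by count descending
    then alphabetically.
    """
    if field not in FIELD_TYPES:
        raise ValueError(f"unknown field {field!r}; expected one of {FIELD_TYPES}")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if field == "ingredient":
        groups = ds.ingredient_sets
    else:
        groups = [
            frozenset(ds.annotations.get(fid, {}).get(field, [])) for fid in ds.ids
        ]
    counts: dict[tuple[str, str], int] = {}
    for s in groups:
        for a, b in combinations(sorted(s), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    if min_count == 0:
        # include never-co-occurring pairs of observed items
        universe = sorted(set().union(*groups)) if groups else []
        for pair in combinations(universe, 2):
            counts.setdefault(pair, 0)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [(a, b, c) for (a, b), c in rows if c >= min_count],
        columns=["item_a", "item_b", "count"],
    )


def cooc_network(
    ct: pd.DataFrame, freq: pd.DataFrame, min_count: int = 1
) -> nx.Graph:
    """Weighted co-occurrence graph from a co-occurrence table.

    Nodes are items appearing in at least one retained edge, annotated with
    their overall frequency (from a :func:`fminer.standardize.freq_table`
    result); edge weights are co-occurrence counts.
    """
    kept = ct[ct["count"] >= min_count]
    if kept.empty:
        raise ValueError(f"no co-occurrence pair reaches min_count={min_count}")
    freq_map = dict(zip(freq["term"], freq["count"]))
    g = nx.Graph()
    for row in kept.itertuples(index=False):
        for item in (row.item_a, row.item_b):
            if item not in g:
                g.add_node(item, frequency=int(freq_map.get(item, 0)))
        g.add_edge(row.item_a, row.item_b, weight=int(row.count))
    return g
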