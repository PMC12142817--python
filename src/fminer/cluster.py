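"""Agglomerative clustering of items over binary occurrence data.

Items (herbs) are clustered by the dissimilarity of their occurrence
patterns across formulas, either binary Jaccard distance or 1 - phi. The
agglomeration engine implements the Lance-Williams recurrence with the
seven classical linkage coefficient sets (ward.D, ward.D2, single,
complete, average, centroid, median), following the R ``hclust``
conventions: ward.D applies Ward's update to the dissimilarities as given,
ward.D2 to their squares (heights reported on the original scale);
centroid and median apply the recurrence to the input as given.

``k_selection`` recommends a number of clusters by letting a panel of
internal validity indices vote: each index is evaluated on partitions
obtained by cutting one dendrogram (ward.D2 by default) at every k in the
requested range, and votes for the k it considers best. The winner is the
modal recommendation, ties broken toward the smallest k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from .correlation import calc_phi

__all__ = [
    "LINKAGES",
    "DEFAULT_INDICES",
    "DistanceMatrix",
    "Dendrogram",
    "KVote",
    "compute_distance",
    "agglomerate",
    "explore_cluster",
    "cut_tree",
    "k_selection",
]

logger = logging.getLogger(__name__)

LINKAGES = ("ward.D", "ward.D2", "single", "complete", "average", "centroid", "median")


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix over item labels with a metric tag."""

    values: np.ndarray
    labels: list[str]
    metric: str = "jaccard_binary"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix entries must be finite")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def compute_distance(m: pd.DataFrame, metric: str = "jaccard_binary") -> DistanceMatrix:
    """Item-item dissimilarities from a binary wide matrix (items = columns).

    ``jaccard_binary``: d = 1 - |intersection| / |union| of the formula sets
    containing each item. ``one_minus_phi``: d = 1 - phi, clipped to [0, 2].
    Items occurring in no formula have no defined occurrence pattern and are
    rejected.
    """
    cols = list(m.columns)
    x = m.to_numpy(dtype=float)
    never = [c for c, s in zip(cols, x.sum(axis=0)) if s == 0]
    if never:
        raise ValueError(f"item(s) never occurring in any formula: {never}")
    if metric == "jaccard_binary":
        inter = x.T @ x
        sizes = np.diag(inter)
        union = sizes[:, None] + sizes[None, :] - inter
        d = 1.0 - inter / union
        np.fill_diagonal(d, 0.0)
    elif metric == "one_minus_phi":
        phi = calc_phi(m).phi.loc[cols, cols].to_numpy()
        d = np.clip(1.0 - phi, 0.0, 2.0)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d = (d + d.T) / 2
    return DistanceMatrix(values=d, labels=cols, metric=metric)


@dataclass
class Dendrogram:
    """Merge history in scipy linkage-matrix form.

    ``z`` is the (n-1, 4) matrix: clusters 0..n-1 are leaves, cluster n+i is
    the result of merge i; columns are (left, right, height, size).
    """

    z: np.ndarray
    linkage: str
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.z[:, 2].copy()

    def leaf_order(self) -> list[str]:
        from scipy.cluster.hierarchy import leaves_list

        z = self.z.copy()
        # leaves_list requires monotone heights only for plotting; safe here
        return [self.labels[i] for i in leaves_list(z)]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, columns=["left", "right", "height", "size"])


# Lance-Williams coefficients (alpha_i, alpha_j, beta, gamma) given cluster
# sizes ni, nj of the merging pair and nk of the outside cluster.
def _lw_coefficients(linkage: str, ni: int, nj: int, nk: int):
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if linkage in ("ward.D", "ward.D2"):
        s = ni + nj + nk
        return (ni + nk) / s, (nj + nk) / s, -nk / s, 0.0
    if linkage == "centroid":
        s = ni + nj
        return ni / s, nj / s, -ni * nj / s**2, 0.0
    if linkage == "median":
        return 0.5, 0.5, -0.25, 0.0
    raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")


def agglomerate(d: DistanceMatrix, linkage: str = "ward.D2") -> Dendrogram:
    """Agglomerative clustering via the Lance-Williams recurrence.

    At each step the pair of clusters at minimum current dissimilarity is
    merged; ties are broken by the lexicographically smallest index pair so
    the result is deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    dist = d.values.astype(float).copy()
    if linkage == "ward.D2":
        dist = dist**2
    sizes = {i: 1 for i in range(n)}
    cluster_id = {i: i for i in range(n)}  # active slot -> dendrogram id
    active = list(range(n))
    z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                v = dist[i, j]
                if best is None or v < best[0] or (v == best[0] and (i, j) < (best[1], best[2])):
                    best = (v, i, j)
        h, i, j = best
        height = np.sqrt(h) if linkage == "ward.D2" else h
        z[step] = (cluster_id[i], cluster_id[j], height, sizes[i] + sizes[j])
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            ai_, aj_, beta, gamma = _lw_coefficients(linkage, ni, nj, sizes[k])
            new = (
                ai_ * dist[i, k]
                + aj_ * dist[j, k]
                + beta * dist[i, j]
                + gamma * abs(dist[i, k] - dist[j, k])
            )
            dist[i, k] = dist[k, i] = new
        sizes[i] = ni + nj
        cluster_id[i] = next_id
        next_id += 1
        active.remove(j)
    return Dendrogram(z=z, linkage=linkage, labels=list(d.labels))


def explore_cluster(d: DistanceMatrix) -> dict[str, Dendrogram]:
    """Run all seven linkages; returns one dendrogram per linkage tag."""
    return {tag: agglomerate(d, tag) for tag in LINKAGES}


def cut_tree(dend: Dendrogram, k: int) -> np.ndarray:
    """Partition labels into k clusters; returns integer labels 1..k."""
    return fcluster(dend.z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# internal validity indices, all computed from the distance matrix alone
# (centroid-based indices use medoids). "max" indices vote for their argmax
# over k, "min" for their argmin, "elbow" for the largest second difference.

def _cluster_lists(labels: np.ndarray) -> list[np.ndarray]:
    return [np.nonzero(labels == c)[0] for c in np.unique(labels)]


def _within_between_masks(labels: np.ndarray):
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    return same[iu], iu


def _ssw(d: np.ndarray, labels: np.ndarray) -> float:
    # sum over clusters of (sum of squared within distances) / cluster size
    total = 0.0
    for idx in _cluster_lists(labels):
        if len(idx) > 1:
            sub = d[np.ix_(idx, idx)]
            total += (sub**2).sum() / (2 * len(idx))
    return total


def _medoids(d: np.ndarray, labels: np.ndarray) -> list[int]:
    meds = []
    for idx in _cluster_lists(labels):
        sub = d[np.ix_(idx, idx)]
        meds.append(idx[int(np.argmin(sub.sum(axis=1)))])
    return meds


def _silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    clusters = _cluster_lists(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    s = np.zeros(n)
    for idx in clusters:
        for i in idx:
            if len(idx) == 1:
                s[i] = 0.0
                continue
            a = d[i, idx].sum() / (len(idx) - 1)
            b = min(
                d[i, other].mean() for other in clusters if other is not idx
            )
            s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def _calinski_harabasz(d: np.ndarray, labels: np.ndarray) -> float:
    # distance-based pseudo-F: between/within sums of squares from pairwise d
    n, k = len(labels), len(np.unique(labels))
    sst = (d**2).sum() / (2 * n)
    ssw = _ssw(d, labels)
    if ssw <= 0 or k == n:
        raise ValueError("degenerate partition for pseudo-F")
    return ((sst - ssw) / (k - 1)) / (ssw / (n - k))


def _davies_bouldin(d: np.ndarray, labels: np.ndarray) -> float:
    clusters = _cluster_lists(labels)
    meds = _medoids(d, labels)
    scatter = [d[m, idx].mean() for m, idx in zip(meds, clusters)]
    k = len(clusters)
    worst = []
    for i in range(k):
        ratios = [
            (scatter[i] + scatter[j]) / d[meds[i], meds[j]]
            for j in range(k)
            if j != i and d[meds[i], meds[j]] > 0
        ]
        if not ratios:
            raise ValueError("coincident medoids")
        worst.append(max(ratios))
    return float(np.mean(worst))


def _dunn(d: np.ndarray, labels: np.ndarray) -> float:
    clusters = _cluster_lists(labels)
    diam = max(
        (d[np.ix_(idx, idx)].max() for idx in clusters if len(idx) > 1), default=0.0
    )
    sep = min(
        d[np.ix_(a, b)].min()
        for i, a in enumerate(clusters)
        for b in clusters[i + 1 :]
    )
    if diam == 0:
        raise ValueError("zero diameter partition")
    return sep / diam


def _c_index(d: np.ndarray, labels: np.ndarray) -> float:
    within, iu = _within_between_masks(labels)
    pair_d = d[iu]
    nw = int(within.sum())
    if nw == 0:
        raise ValueError("no within-cluster pairs")
    sw = pair_d[within].sum()
    ordered = np.sort(pair_d)
    smin, smax = ordered[:nw].sum(), ordered[-nw:].sum()
    if smax == smin:
        raise ValueError("all pairwise distances equal")
    return (sw - smin) / (smax - smin)


def _mcclain_rao(d: np.ndarray, labels: np.ndarray) -> float:
    within, iu = _within_between_masks(labels)
    pair_d = d[iu]
    if within.sum() == 0 or (~within).sum() == 0:
        raise ValueError("degenerate partition")
    mb = pair_d[~within].mean()
    if mb == 0:
        raise ValueError("zero between-cluster distances")
    return pair_d[within].mean() / mb


def _point_biserial(d: np.ndarray, labels: np.ndarray) -> float:
    within, iu = _within_between_masks(labels)
    pair_d = d[iu]
    nw, nb = int(within.sum()), int((~within).sum())
    nt = nw + nb
    if nw == 0 or nb == 0:
        raise ValueError("degenerate partition")
    sd = pair_d.std()
    if sd == 0:
        raise ValueError("all pairwise distances equal")
    return (pair_d[~within].mean() - pair_d[within].mean()) * np.sqrt(
        nw * nb / nt**2
    ) / sd


def _gamma_splus(d: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    within, iu = _within_between_masks(labels)
    pair_d = d[iu]
    wd = np.sort(pair_d[within])
    bd = np.sort(pair_d[~within])
    if len(wd) == 0 or len(bd) == 0:
        raise ValueError("degenerate partition")
    # concordant: within < between; discordant: within > between
    s_plus = 0
    s_minus = 0
    j_lt = 0
    j_le = 0
    for w in wd:
        while j_lt < len(bd) and bd[j_lt] < w:
            j_lt += 1
        while j_le < len(bd) and bd[j_le] <= w:
            j_le += 1
        s_minus += j_lt                 # between pairs strictly smaller than w
        s_plus += len(bd) - j_le        # between pairs strictly larger than w
    if s_plus + s_minus == 0:
        raise ValueError("no comparable pairs")
    gamma = (s_plus - s_minus) / (s_plus + s_minus)
    nt = len(pair_d)
    splus_index = 2 * s_minus / (nt * (nt - 1))
    return gamma, splus_index


def _xie_beni(d: np.ndarray, labels: np.ndarray) -> float:
    meds = _medoids(d, labels)
    if len(meds) < 2:
        raise ValueError("need >= 2 clusters")
    sep = min(
        d[meds[i], meds[j]] ** 2
        for i in range(len(meds))
        for j in range(i + 1, len(meds))
    )
    if sep == 0:
        raise ValueError("coincident medoids")
    compact = sum(
        (d[m, idx] ** 2).sum() for m, idx in zip(_medoids(d, labels), _cluster_lists(labels))
    )
    return compact / (len(labels) * sep)


DEFAULT_INDICES = (
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn",
    "c_index",
    "mcclain_rao",
    "point_biserial",
    "gamma",
    "g_plus",
    "elbow",
    "xie_beni",
)

_DIRECTION = {
    "silhouette": "max",
    "calinski_harabasz": "max",
    "davies_bouldin": "min",
    "dunn": "max",
    "c_index": "min",
    "mcclain_rao": "min",
    "point_biserial": "max",
    "gamma": "max",
    "g_plus": "min",
    "xie_beni": "min",
}


@dataclass
class KVote:
    """Vote-based recommendation for the number of clusters."""

    per_method: dict[str, int]
    tally: dict[int, int] = field(init=False)
    winner: int = field(init=False)

    def __post_init__(self) -> None:
        tally: dict[int, int] = {}
        for k in self.per_method.values():
            tally[k] = tally.get(k, 0) + 1
        self.tally = dict(sorted(tally.items()))
        self.winner = min(
            self.tally, key=lambda k: (-self.tally[k], k)
        )  # modal k, ties toward parsimony


def _index_value(name: str, d: np.ndarray, labels: np.ndarray) -> float:
    if name == "silhouette":
        return _silhouette(d, labels)
    if name == "calinski_harabasz":
        return _calinski_harabasz(d, labels)
    if name == "davies_bouldin":
        return _davies_bouldin(d, labels)
    if name == "dunn":
        return _dunn(d, labels)
    if name == "c_index":
        return _c_index(d, labels)
    if name == "mcclain_rao":
        return _mcclain_rao(d, labels)
    if name == "point_biserial":
        return _point_biserial(d, labels)
    if name == "gamma":
        return _gamma_splus(d, labels)[0]
    if name == "g_plus":
        return _gamma_splus(d, labels)[1]
    if name == "xie_beni":
        return _xie_beni(d, labels)
    raise ValueError(f"unknown index {name!r}")


def k_selection(
    d: DistanceMatrix,
    k_range: tuple[int, int] = (2, 10),
    methods: tuple[str, ...] = DEFAULT_INDICES,
    *,
    linkage: str = "ward.D2",
) -> KVote:
    """Recommend the number of clusters by internal-index voting.

    Partitions are obtained by cutting one ``linkage`` dendrogram at every
    k in ``k_range`` (inclusive). Each index votes for the k it scores
    best; the elbow index votes for the largest second difference of the
    within-cluster sum of squares. Indices that fail on every candidate
    partition (degenerate geometry) are excluded from the tally with a
    warning.
    """
    k_min, k_max = k_range
    n = len(d)
    if not (2 <= k_min <= k_max < n):
        raise ValueError(f"require 2 <= k_min <= k_max < n_items (got {k_range}, n={n})")
    dend = agglomerate(d, linkage)
    ks = list(range(k_min, k_max + 1))
    partitions = {k: cut_tree(dend, k) for k in ks}
    dm = d.values

    per_method: dict[str, int] = {}
    if len(ks) == 1:
        return KVote(per_method={m: ks[0] for m in methods})
    for name in methods:
        if name == "elbow":
            # extend by one k on each side where possible for second differences
            ext = list(range(max(1, k_min - 1), min(n, k_max + 1) + 1))
            ssw = {}
            for k in ext:
                labels = partitions[k] if k in partitions else cut_tree(dend, k)
                ssw[k] = _ssw(dm, labels)
            best_k, best_val = None, -np.inf
            for k in ks:
                if k - 1 in ssw and k + 1 in ssw:
                    curv = (ssw[k - 1] - ssw[k]) - (ssw[k] - ssw[k + 1])
                    if curv > best_val:
                        best_k, best_val = k, curv
            if best_k is None:
                warnings.warn("elbow index not evaluable in the requested range")
                continue
            per_method[name] = best_k
            continue
        scores: dict[int, float] = {}
        for k in ks:
            try:
                scores[k] = _index_value(name, dm, partitions[k])
            except (ValueError, ZeroDivisionError):
                continue
        if not scores:
            warnings.warn(f"index {name!r} failed on every partition; excluded")
            continue
        if _DIRECTION[name] == "max":
            per_method[name] = min(scores, key=lambda k: (-scores[k], k))
        else:
            per_method[name] = min(scores, key=lambda k: (scores[k], k))
    if not per_method:
        raise ValueError("no index produced a recommendation")
    return KVote(per_method=per_method)
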