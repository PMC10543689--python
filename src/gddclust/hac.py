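"""Agglomerative phenotype clustering of individuals.

Individuals are binary phenotype profiles; dissimilarity is the Jaccard
distance D(I_i, I_j) = 1 - |P_i ∩ P_j| / |P_i ∪ P_j|. A Ward-linkage
dendrogram is built directly on the (non-Euclidean) distance matrix via the
Lance-Williams recurrence applied to squared dissimilarities, with merge
heights reported as square roots; flat partitions are validated with the
silhouette index SIL_i = (b_i - a_i)/max(a_i, b_i).

Conventions: singleton clusters get silhouette 0; all tie-breaks (equal
merge distances, equally frequent phenotypes) resolve to the first
candidate in creation/lexicographic order so results are deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .cohort import Individual

__all__ = [
    "PhenotypeDistanceMatrix",
    "Dendrogram",
    "ClusterResult",
    "jaccard_matrix",
    "ward_linkage",
    "silhouette",
    "cut_dendrogram",
    "cluster_diagnostics",
    "cluster_gene_union",
    "to_newick",
]


@dataclass(frozen=True)
class PhenotypeDistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray  # dense symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if np.isnan(m).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix has nonzero diagonal")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("distances outside [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Dendrogram:
    """Ward merge sequence in scipy linkage-matrix form: each row is
    (node a, node b, height, merged size); leaves are 0..N-1, the merge at
    row r creates node N+r."""

    merges: np.ndarray  # (N-1, 4)
    n_leaves: int

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("merge table must have N-1 rows of 4")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights are not non-decreasing")


@dataclass(frozen=True)
class ClusterResult:
    ids: tuple[str, ...]
    labels: np.ndarray  # cluster IDs in 1..k, aligned with ids
    sil_samples: np.ndarray
    sil_by_cluster: Mapping[int, float]
    sil_overall: float
    k: int

    def label_of(self) -> dict[str, int]:
        return {i: int(c) for i, c in zip(self.ids, self.labels)}

    def members(self, cluster_id: int) -> list[str]:
        if cluster_id not in set(self.labels.tolist()):
            raise KeyError(f"unknown cluster {cluster_id}")
        return [i for i, c in zip(self.ids, self.labels) if c == cluster_id]


def jaccard_matrix(
    cohort: Sequence[Individual], exclude: frozenset[str] | set[str] = frozenset()
) -> PhenotypeDistanceMatrix:
    """Pairwise Jaccard distances over individuals' phenotype sets.

    ``exclude`` drops terms (typically the GDD anchor, carried cohort-wide
    and hence uninformative for stratification) from every profile before
    the distance is computed. The distance is undefined when both sets are
    empty, so individuals with no remaining phenotype are rejected up front
    with their IDs listed.
    """
    profiles = [ind.phenotypes - set(exclude) for ind in cohort]
    empty = [ind.id for ind, p in zip(cohort, profiles) if not p]
    if empty:
        raise ValueError(
            f"individuals with empty phenotype sets cannot be clustered: {empty[:10]}"
        )
    terms = sorted({t for p in profiles for t in p})
    col = {t: j for j, t in enumerate(terms)}
    x = np.zeros((len(cohort), len(terms)), dtype=bool)
    for i, p in enumerate(profiles):
        for t in p:
            x[i, col[t]] = True
    dist = squareform(pdist(x, metric="jaccard"))
    return PhenotypeDistanceMatrix(ids=tuple(ind.id for ind in cohort), matrix=dist)


def ward_linkage(dist: PhenotypeDistanceMatrix) -> Dendrogram:
    """Ward agglomeration on an arbitrary dissimilarity matrix.

    The Lance-Williams Ward update runs on squared dissimilarities:
        d²(k, i∪j) = [(n_i+n_k)d²_ki + (n_j+n_k)d²_kj − n_k d²_ij]
                     / (n_i+n_j+n_k)
    and merge heights are the square roots of the minimal d². Among equal
    minimal pairs the first in node-creation order merges (deterministic).
    """
    n = len(dist)
    if n < 2:
        raise ValueError("need at least two individuals")
    d2 = dist.matrix.astype(float) ** 2
    np.fill_diagonal(d2, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=float)
    node_id = np.arange(n)  # scipy node id held by each slot
    merges = np.zeros((n - 1, 4))
    work = d2.copy()
    for step in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], work, np.inf)
        flat = int(np.argmin(masked))  # C-order argmin = first minimal pair
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = float(np.sqrt(masked[i, j]))
        ni, nj = sizes[i], sizes[j]
        a, b = sorted((int(node_id[i]), int(node_id[j])))
        merges[step] = (a, b, h, ni + nj)
        # Lance-Williams update into slot i; slot j retires.
        k = active.copy()
        k[[i, j]] = False
        nk = sizes[k]
        work[i, k] = (
            (ni + nk) * work[i, k] + (nj + nk) * work[j, k] - nk * work[i, j]
        ) / (ni + nj + nk)
        work[k, i] = work[i, k]
        sizes[i] = ni + nj
        active[j] = False
        node_id[i] = n + step
    return Dendrogram(merges=merges, n_leaves=n)


def silhouette(
    dist: PhenotypeDistanceMatrix, labels: Sequence[int]
) -> tuple[np.ndarray, dict[int, float], float]:
    """Per-individual, per-cluster-mean and overall-mean silhouettes.

    a_i = mean distance to own-cluster co-members, b_i = smallest mean
    distance to another cluster, SIL_i = (b_i - a_i)/max(a_i, b_i).
    Singletons take SIL_i = 0; if a_i = b_i = 0 the value is defined as 0.
    """
    labels = np.asarray(labels)
    n = len(dist)
    if labels.shape != (n,):
        raise ValueError("labels length does not match matrix")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    d = dist.matrix
    # column c of `sums` = summed distance from each point to cluster c
    sums = np.stack([d[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    counts = np.array([(labels == c).sum() for c in uniq], dtype=float)
    own = np.searchsorted(uniq, labels)
    a = np.zeros(n)
    nontriv = counts[own] > 1
    a[nontriv] = sums[np.arange(n), own][nontriv] / (counts[own][nontriv] - 1)
    other_means = sums / counts[None, :]
    other_means[np.arange(n), own] = np.inf
    b = other_means.min(axis=1)
    denom = np.maximum(a, b)
    sil = np.zeros(n)
    ok = denom > 0
    sil[ok] = (b[ok] - a[ok]) / denom[ok]
    sil[counts[own] == 1] = 0.0  # singleton convention
    by_cluster = {int(c): float(sil[labels == c].mean()) for c in uniq}
    return sil, by_cluster, float(sil.mean())


def cut_dendrogram(
    dend: Dendrogram,
    dist: PhenotypeDistanceMatrix,
    k: int | str = "auto",
    k_range: tuple[int, int] = (2, 30),
) -> ClusterResult:
    """Extract a flat partition.

    ``k='auto'`` cuts at the largest merge-height gap within ``k_range``:
    the chosen k maximizes h(N-k+1) - h(N-k), the height jump incurred by
    going from k to k-1 clusters (ties toward smaller k). Silhouettes are
    then computed on the supplied distance matrix as the validation
    metric. Raw silhouette maximization over k is deliberately not used
    for selection: on discrete set profiles it degenerates toward the
    partition into identical-profile groups, which scores near 1 at large
    k regardless of any coarser structure.
    """
    n = dend.n_leaves
    if k == "auto":
        lo, hi = max(2, k_range[0]), min(k_range[1], n)
        if lo > hi:
            raise ValueError("no valid cut found in k_range")
        # padded so that cutting into k=n clusters sits above height 0
        heights = np.concatenate([[0.0], dend.merges[:, 2]])
        gaps = {
            kk: (heights[n - kk + 1] - heights[n - kk]) for kk in range(lo, hi + 1)
        }
        kk = min(gaps, key=lambda q: (-gaps[q], q))
        labels = sch.fcluster(dend.merges, t=kk, criterion="maxclust")
    else:
        kk = int(k)
        if not 2 <= kk <= n:
            raise ValueError(f"k={kk} outside [2, {n}]")
        labels = sch.fcluster(dend.merges, t=kk, criterion="maxclust")
    if len(np.unique(labels)) >= 2:
        sil, by_cluster, overall = silhouette(dist, labels)
    else:  # degenerate tie-heavy cut
        sil = np.zeros(n)
        by_cluster, overall = {int(labels[0]): 0.0}, 0.0
    return ClusterResult(
        ids=dist.ids,
        labels=np.asarray(labels),
        sil_samples=sil,
        sil_by_cluster=by_cluster,
        sil_overall=overall,
        k=int(len(np.unique(labels))),
    )


def cluster_diagnostics(
    cohort: Sequence[Individual],
    result: ClusterResult,
    exclude_anchor: str | None = None,
) -> dict[int, dict]:
    """Per-cluster diagnostic panels: top-5 phenotype frequencies, the
    dominant phenotype and its carrier count (optionally excluding a GDD
    anchor term, since every cluster is 'GDD + one dominant phenotype'),
    the phenotype-set-size histogram and the pairwise shared-phenotype
    histogram."""
    by_id = {ind.id: ind for ind in cohort}
    out: dict[int, dict] = {}
    for c in sorted(set(result.labels.tolist())):
        members = [by_id[i] for i in result.members(c)]
        freq: Counter[str] = Counter()
        for ind in members:
            freq.update(ind.phenotypes)
        top5 = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        dom_pool = {
            t: cnt for t, cnt in freq.items() if t != exclude_anchor
        }
        dominant, dom_count = (None, 0)
        if dom_pool:
            dominant = min(dom_pool, key=lambda t: (-dom_pool[t], t))
            dom_count = dom_pool[dominant]
        size_hist = Counter(len(ind.phenotypes) for ind in members)
        shared_hist: Counter[int] = Counter()
        sets = [ind.phenotypes for ind in members]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                shared_hist[len(sets[i] & sets[j])] += 1
        out[c] = {
            "size": len(members),
            "top5": top5,
            "dominant": dominant,
            "dominant_count": dom_count,
            "pheno_count_hist": dict(size_hist),
            "shared_count_hist": dict(shared_hist),
        }
    return out


def cluster_gene_union(
    cohort: Sequence[Individual], result: ClusterResult, cluster_id: int
) -> tuple[frozenset[str], dict[str, int]]:
    """Union of member gene sets with per-gene carrier counts."""
    by_id = {ind.id: ind for ind in cohort}
    counts: Counter[str] = Counter()
    for iid in result.members(cluster_id):
        counts.update(by_id[iid].genes)
    return frozenset(counts), dict(counts)


def to_newick(dend: Dendrogram, ids: Sequence[str]) -> str:
    """Newick rendering of the dendrogram with branch lengths from merge
    heights."""
    tree = sch.to_tree(dend.merges)

    def walk(node, parent_h: float) -> str:
        length = max(parent_h - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        return (
            f"({walk(node.left, node.dist)},{walk(node.right, node.dist)}):{length:.6g}"
        )

    return walk(tree, tree.dist) + ";"
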