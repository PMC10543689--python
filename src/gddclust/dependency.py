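"""Probabilistic gene-phenotype dependency model and divisive gene clustering.

The model accumulates prior-weighted gene/phenotype co-occurrence over
individuals: with indicator conditionals P(g|I_j) = 1{g in genes_j} and
P(h|I_j) = 1{h in phenotypes_j},

    P(G | H) ∝ Σ_j P(G | I_j) · P(H | I_j) · P(I_j)

with uniform priors P(I_j) = 1/N unless supplied. Columns are phenotype
conditions — a "present" column per phenotype of interest and, optionally,
the matching "absent" column — and each supported column is normalized to
sum to one, giving a conditional probability distribution over genes.
Causality between genes and phenotypes is deliberately not asserted.

Gene rows of the matrix are then clustered divisively with k-means; the
cluster count is chosen by the elbow and silhouette methods, and phenotype
conditions are contrasted within each gene cluster by Welch t-tests under
Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .cohort import Individual

__all__ = [
    "DependencyMatrix",
    "GeneClusterResult",
    "ClusterContrast",
    "build_dependency_matrix",
    "kmeans_genes",
    "select_k",
    "contrast_clusters",
]

PRESENT = "+"
ABSENT = "-"


@dataclass(frozen=True)
class DependencyMatrix:
    genes: tuple[str, ...]
    columns: tuple[str, ...]  # e.g. "HP:0001250+" / "HP:0001250-"
    matrix: np.ndarray  # genes x columns, column-normalized where supported
    priors: np.ndarray  # one weight per individual, sums to 1
    zero_genes: tuple[str, ...] = ()  # all-zero rows, excluded from clustering

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.columns)):
            raise ValueError("matrix shape mismatch")
        if self.matrix.min() < 0:
            raise ValueError("negative probabilities")

    def nonzero(self) -> "DependencyMatrix":
        """Restrict to genes with at least one nonzero entry."""
        keep = [i for i, g in enumerate(self.genes) if g not in set(self.zero_genes)]
        return DependencyMatrix(
            genes=tuple(self.genes[i] for i in keep),
            columns=self.columns,
            matrix=self.matrix[keep],
            priors=self.priors,
        )

    def subset_genes(self, genes: Sequence[str]) -> "DependencyMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in genes]
        return DependencyMatrix(
            genes=tuple(genes), columns=self.columns,
            matrix=self.matrix[rows], priors=self.priors,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.genes), columns=list(self.columns))


@dataclass(frozen=True)
class GeneClusterResult:
    genes: tuple[str, ...]
    labels: np.ndarray  # cluster IDs 1..k
    centroids: np.ndarray
    inertia: float
    k: int

    def label_of(self) -> dict[str, int]:
        return {g: int(c) for g, c in zip(self.genes, self.labels)}

    def members(self, cluster_id: int) -> list[str]:
        return [g for g, c in zip(self.genes, self.labels) if c == cluster_id]


@dataclass(frozen=True)
class ClusterContrast:
    """Welch t-test contrasts of phenotype-condition columns within gene
    clusters; ``table`` has one row per (cluster, column pair)."""

    table: pd.DataFrame  # cluster, col_a, col_b, t, p, p_adj, significant
    n_tests: int
    alpha: float
    skipped_clusters: tuple[int, ...] = ()


def build_dependency_matrix(
    cohort: Sequence[Individual],
    phenotypes_of_interest: Sequence[str],
    include_absent: bool = True,
    priors: Sequence[float] | None = None,
    per_individual_normalized: bool = False,
) -> DependencyMatrix:
    """Accumulate the P(G|H) matrix over the cohort.

    ``per_individual_normalized`` switches P(g|I_j) from the indicator to
    1/|genes_j|, spreading each individual's evidence equally over their
    carried genes.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    if priors is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(priors, dtype=float)
        if w.shape != (n,) or not np.isclose(w.sum(), 1.0):
            raise ValueError("priors must be one weight per individual summing to 1")
    carried = {t for ind in cohort for t in ind.phenotypes}
    for term in phenotypes_of_interest:
        if term not in carried:
            raise ValueError(f"phenotype {term!r} is carried by no individual")

    genes = tuple(sorted({g for ind in cohort for g in ind.genes}))
    gidx = {g: i for i, g in enumerate(genes)}
    columns: list[str] = []
    for term in phenotypes_of_interest:
        columns.append(term + PRESENT)
        if include_absent:
            columns.append(term + ABSENT)
    m = np.zeros((len(genes), len(columns)))
    for j, ind in enumerate(cohort):
        if not ind.genes:
            continue
        gw = w[j] / len(ind.genes) if per_individual_normalized else w[j]
        rows = [gidx[g] for g in ind.genes]
        for c, col in enumerate(columns):
            term, cond = col[:-1], col[-1]
            hit = term in ind.phenotypes
            if (cond == PRESENT and hit) or (cond == ABSENT and not hit):
                m[rows, c] += gw
    support = m.sum(axis=0)
    norm = np.where(support > 0, support, 1.0)
    m = m / norm[None, :]
    zero = tuple(g for i, g in enumerate(genes) if not m[i].any())
    return DependencyMatrix(
        genes=genes, columns=tuple(columns), matrix=m, priors=w, zero_genes=zero
    )


def kmeans_genes(
    dep: DependencyMatrix, k: int, seed: int = 0, n_init: int = 10
) -> GeneClusterResult:
    """k-means over nonzero gene rows (Lloyd, k-means++ greedy seeding,
    best of ``n_init`` restarts by inertia; deterministic given seed)."""
    nz = dep.nonzero()
    x = nz.matrix
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds {x.shape[0]} nonzero gene rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return GeneClusterResult(
        genes=nz.genes,
        labels=km.labels_ + 1,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        k=k,
    )


def _elbow_k(ks: np.ndarray, inertias: np.ndarray) -> int:
    """Knee of the inertia curve: the k maximizing perpendicular distance
    to the chord joining the curve's endpoints (axes min-max normalized)."""
    if len(ks) == 1:
        return int(ks[0])
    x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    span = inertias[0] - inertias[-1]
    y = (inertias - inertias[-1]) / (span if span > 0 else 1.0)
    # chord runs from (0, 1) to (1, 0); distance ∝ |x + y - 1|
    d = np.abs(x + y - 1.0)
    return int(ks[int(np.argmax(d))])


def select_k(
    dep: DependencyMatrix,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    n_init: int = 10,
) -> dict:
    """Choose the gene-cluster count by silhouette (elbow reported too).

    Returns {'k', 'elbow_k', 'diagnostics' (per-k inertia and mean
    silhouette), 'degenerate'}; all-identical rows yield k=1 with the
    degenerate flag set.
    """
    nz = dep.nonzero()
    x = nz.matrix
    if np.allclose(x, x[0]):
        return {"k": 1, "elbow_k": 1, "diagnostics": pd.DataFrame(), "degenerate": True}
    lo, hi = k_range
    hi = min(hi, x.shape[0])
    if lo > hi:
        raise ValueError("k_range outside the number of gene rows")
    rows = []
    for k in range(lo, hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        if len(np.unique(km.labels_)) < 2:
            continue
        sil = float(silhouette_score(x, km.labels_))
        rows.append((k, float(km.inertia_), sil))
    diag = pd.DataFrame(rows, columns=["k", "inertia", "mean_silhouette"])
    best = diag.loc[diag["mean_silhouette"].idxmax()]
    # ties toward smaller k
    top = diag[np.isclose(diag["mean_silhouette"], best["mean_silhouette"])]
    k_sel = int(top["k"].min())
    elbow = _elbow_k(diag["k"].to_numpy(), diag["inertia"].to_numpy())
    return {"k": k_sel, "elbow_k": elbow, "diagnostics": diag, "degenerate": False}


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # both constant
        if a[0] == b[0]:
            return 0.0, 1.0
        return (np.inf if a[0] > b[0] else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def contrast_clusters(
    dep: DependencyMatrix, clusters: GeneClusterResult, alpha: float = 0.05
) -> ClusterContrast:
    """Welch t-tests between every unordered pair of phenotype-condition
    columns within each gene cluster of size >= 2, Bonferroni-corrected over
    all tests actually performed."""
    nz = dep.subset_genes(clusters.genes)
    cols = nz.columns
    pairs = [(i, j) for i in range(len(cols)) for j in range(i + 1, len(cols))]
    rows, skipped = [], []
    for c in sorted(set(clusters.labels.tolist())):
        mask = clusters.labels == c
        if mask.sum() < 2:
            skipped.append(int(c))
            warnings.warn(f"gene cluster {c} has <2 genes; contrasts skipped")
            continue
        sub = nz.matrix[mask]
        for i, j in pairs:
            t, p = _welch(sub[:, i], sub[:, j])
            rows.append((int(c), cols[i], cols[j], t, p))
    m = len(rows)
    table = pd.DataFrame(rows, columns=["cluster", "col_a", "col_b", "t", "p"])
    table["p_adj"] = np.minimum(1.0, table["p"] * m)
    table["significant"] = table["p_adj"] <= alpha
    return ClusterContrast(
        table=table, n_tests=m, alpha=alpha, skipped_clusters=tuple(skipped)
    )
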