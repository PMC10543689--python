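"""Gene interaction sub-networks via Markov clustering, with enrichment.

A phenotype cluster's gene set is projected onto a supplied interaction
edge list (STRING-export style), decomposed into sub-networks by the
Markov clustering algorithm (MCL, inflation 1.5 by default), summarized
(sub-networks with more than ``min_size`` genes highlighted), and tested
for over-representation against flat GMT gene sets with a one-sided
hypergeometric tail and Benjamini-Hochberg correction within each
sub-network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneNetwork",
    "SubNetworkPartition",
    "OverlapReport",
    "induce_network",
    "mcl_cluster",
    "summarize_subnetworks",
    "read_gmt",
    "enrich",
    "overlap_report",
]


@dataclass(frozen=True)
class GeneNetwork:
    graph: nx.Graph  # weighted, undirected, no self-loops
    provenance: str = ""
    min_score: float = 0.0

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed on input")
        for u, v, w in self.graph.edges(data="weight"):
            if not 0 < w <= 1:
                raise ValueError(f"edge ({u},{v}) score {w} outside (0, 1]")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass(frozen=True)
class SubNetworkPartition:
    assignment: Mapping[str, int]  # gene -> sub-network ID (1..)
    converged: bool = True

    def members(self, sub_id: int) -> list[str]:
        return sorted(g for g, s in self.assignment.items() if s == sub_id)

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.assignment.values():
            out[s] = out.get(s, 0) + 1
        return out

    @property
    def n_subnetworks(self) -> int:
        return len(self.sizes)

    def n_larger_than(self, min_size: int = 10) -> int:
        return sum(1 for n in self.sizes.values() if n > min_size)


@dataclass(frozen=True)
class OverlapReport:
    size_a: int
    size_b: int
    intersection: int
    union: int
    jaccard_pct: float  # 100·|A∩B|/|A∪B|
    pct_of_a: float  # 100·|A∩B|/|A|
    pct_of_b: float
    both_empty: bool = False


def induce_network(
    gene_set: Iterable[str],
    edge_list_path: str | Path,
    min_score: float = 0.4,
) -> GeneNetwork:
    """Subgraph of the edge list induced on ``gene_set``.

    STRING-style integer combined scores (>1) are rescaled by 1/1000.
    Isolated genes stay in the graph as singleton nodes.
    """
    genes = set(gene_set)
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    df = pd.read_csv(edge_list_path, sep="\t", dtype=str, keep_default_na=False)
    need = {"node1", "node2", "score"}
    if not need <= set(df.columns):
        raise ValueError(f"{edge_list_path}: expected columns {sorted(need)}")
    for i, row in df.iterrows():
        try:
            score = float(row["score"])
        except ValueError as exc:
            raise ValueError(
                f"{edge_list_path} line {i + 2}: malformed score {row['score']!r}"
            ) from exc
        if score > 1:
            score /= 1000.0
        if not 0 < score <= 1:
            raise ValueError(f"{edge_list_path} line {i + 2}: score {score} outside (0, 1]")
        u, v = row["node1"], row["node2"]
        if u == v:
            raise ValueError(f"{edge_list_path} line {i + 2}: self-loop on {u}")
        if score >= min_score and u in genes and v in genes:
            g.add_edge(u, v, weight=score)
    return GeneNetwork(graph=g, provenance=str(edge_list_path), min_score=min_score)


def mcl_cluster(
    net: GeneNetwork,
    inflation: float = 1.5,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-6,
    _trace: list | None = None,
) -> SubNetworkPartition:
    """Markov clustering of the weighted graph.

    The adjacency matrix gains unit self-loops and is column-normalized,
    then expansion (matrix power), inflation (entrywise power followed by
    column renormalization) and pruning alternate until the flow matrix
    changes by less than ``tol`` or ``max_iter`` is reached (in which case
    the partition is returned with ``converged=False``). Clusters are read
    from attractor rows; a node claimed by several attractors goes to the
    one holding more flow mass, ties to the lexicographically first.
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("empty network")
    n = len(nodes)
    m = nx.to_numpy_array(net.graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune_threshold] = 0.0
        m /= m.sum(axis=0, keepdims=True)
        if _trace is not None:
            _trace.append(m.copy())
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break
    attractors = np.flatnonzero(np.diag(m) > 0)
    assignment: dict[str, int] = {}
    owner_mass: dict[str, float] = {}
    cluster_of_attractor: dict[int, int] = {}
    next_id = 1
    for a in attractors:
        # attractors whose rows overlap share one attractor system
        members = np.flatnonzero(m[a] > 0)
        existing = [cluster_of_attractor[b] for b in attractors
                    if b in cluster_of_attractor and m[a, b] > 0]
        cid = min(existing) if existing else next_id
        if not existing:
            next_id += 1
        cluster_of_attractor[a] = cid
        for j in members:
            node = nodes[j]
            mass = float(m[a, j])
            if node not in assignment or mass > owner_mass[node] + 1e-15:
                assignment[node] = cid
                owner_mass[node] = mass
    # numerically orphaned nodes become singletons
    for node in nodes:
        if node not in assignment:
            assignment[node] = next_id
            next_id += 1
    # relabel to contiguous 1..k by size desc then lexicographic leader
    groups: dict[int, list[str]] = {}
    for g, c in assignment.items():
        groups.setdefault(c, []).append(g)
    order = sorted(groups.values(), key=lambda gs: (-len(gs), min(gs)))
    relabeled = {g: i + 1 for i, gs in enumerate(order) for g in gs}
    return SubNetworkPartition(assignment=relabeled, converged=converged)


def summarize_subnetworks(part: SubNetworkPartition, min_size: int = 10) -> dict:
    """Totals, size histogram and the sub-networks strictly larger than
    ``min_size`` genes."""
    sizes = part.sizes
    hist: dict[int, int] = {}
    for s in sizes.values():
        hist[s] = hist.get(s, 0) + 1
    large = sorted(
        (sid for sid, s in sizes.items() if s > min_size),
        key=lambda sid: (-sizes[sid], sid),
    )
    return {
        "n_genes": sum(sizes.values()),
        "n_subnetworks": len(sizes),
        "size_histogram": hist,
        "large_subnetworks": large,
        "n_large": len(large),
    }


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Flat GMT gene sets (name, description, genes...)."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def enrich(
    part: SubNetworkPartition,
    gene_sets: Mapping[str, Sequence[str]],
    background: Iterable[str],
    q_threshold: float = 0.05,
    global_family: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in each
    sub-network against the background.

    p = P(X >= overlap) for X hypergeometric(background, set∩background,
    sub-network size); BH correction runs within each sub-network by
    default (``global_family=True`` pools all tests)."""
    bg = set(background)
    missing = set(part.assignment) - bg
    if missing:
        raise ValueError(
            f"background does not cover partition genes, e.g. {sorted(missing)[:5]}"
        )
    rows = []
    for sid in sorted(part.sizes):
        members = set(part.members(sid))
        for name, genes in gene_sets.items():
            term = set(genes) & bg
            if not term:
                warnings.warn(f"gene set {name!r} disjoint from background; skipped")
                continue
            overlap = len(members & term)
            p = float(stats.hypergeom.sf(overlap - 1, len(bg), len(term), len(members)))
            rows.append((sid, name, overlap, len(members), len(term), len(bg), p))
    df = pd.DataFrame(
        rows,
        columns=[
            "subnetwork", "gene_set", "overlap", "subnetwork_size",
            "gene_set_size", "background_size", "p",
        ],
    )
    if df.empty:
        df["q"] = []
        df["significant"] = []
        return df
    q = np.empty(len(df))
    if global_family:
        q[:] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        for sid in df["subnetwork"].unique():
            mask = df["subnetwork"] == sid
            q[mask.to_numpy()] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    df["q"] = q
    df["significant"] = df["q"] <= q_threshold
    return df


def overlap_report(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapReport:
    """Gene-set overlap: Jaccard percentage plus both one-sided
    percentages so any denominator convention can be inspected."""
    a, b = set(set_a), set(set_b)
    inter, union = len(a & b), len(a | b)
    return OverlapReport(
        size_a=len(a),
        size_b=len(b),
        intersection=inter,
        union=union,
        jaccard_pct=100.0 * inter / union if union else 0.0,
        pct_of_a=100.0 * inter / len(a) if a else 0.0,
        pct_of_b=100.0 * inter / len(b) if b else 0.0,
        both_empty=not a and not b,
    )
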