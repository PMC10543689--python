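"""End-to-end orchestration: simulate → load → phenotype HAC → dependency
model → gene networks → method comparison.

``RunConfig`` is a flat, module-prefixed key-value configuration (unknown
keys are rejected); ``run_pipeline`` executes the stages in dependency
order, writes every artifact as TSV/JSON under ``out_dir`` and returns a
machine-readable run report whose file digests are byte-stable for a fixed
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import cohort as cio
from . import dependency as dep
from . import hac
from . import networks as nets
from . import simulate as sim

__all__ = ["RunConfig", "StageError", "run_pipeline", "compare_methods"]

log = logging.getLogger("gddclust")


class RunConfig(BaseModel):
    """Flat pipeline configuration; every tunable has its module default."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "gddclust_run"
    seed: int = 0
    log_level: str = "INFO"

    # simulate stage (skipped when explicit input paths are given)
    simulate: bool = True
    sim_n_individuals: int = 1000
    sim_n_phenotypes: int = 6
    sim_n_genes: int = 150
    sim_n_pheno_clusters: int = 4
    sim_dominant_penetrance: float = 0.9
    sim_background_rate: float = 0.02

    # external inputs (used when simulate is false)
    phenotype_path: str | None = None
    gene_path: str | None = None
    classification_path: str | None = None
    edge_list_path: str | None = None
    gmt_path: str | None = None

    # phenotype HAC
    hac_k: int | str = "auto"
    hac_k_range: tuple[int, int] = (2, 30)
    anchor_term: str | None = sim.GDD_ANCHOR_TERM
    n_clusters_for_networks: int = 2

    # dependency model
    dep_phenotypes: list[str] | None = None
    dep_include_absent: bool = True
    dep_k: int | str = "auto"
    dep_k_range: tuple[int, int] = (2, 10)
    dep_alpha: float = 0.05

    # gene networks
    net_min_score: float = 0.4
    mcl_inflation: float = 1.5
    mcl_expansion: int = 2
    mcl_prune_threshold: float = 1e-5
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-6
    enrich_q: float = 0.05
    subnetwork_min_size: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compare_methods(
    hac_genes: Mapping[str, set], kmeans_genes: Mapping[str, set]
) -> pd.DataFrame:
    """Per-phenotype overlap between the gene sets the two clustering
    routes identify, plus the within-method overlaps between phenotypes."""
    if set(hac_genes) != set(kmeans_genes):
        raise ValueError(
            f"phenotype keys differ: {sorted(hac_genes)} vs {sorted(kmeans_genes)}"
        )
    rows = []
    for term in sorted(hac_genes):
        r = nets.overlap_report(hac_genes[term], kmeans_genes[term])
        rows.append(("hac_vs_kmeans", term, r))
    terms = sorted(hac_genes)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            rows.append(("within_hac", f"{a}|{b}", nets.overlap_report(hac_genes[a], hac_genes[b])))
            rows.append(
                ("within_kmeans", f"{a}|{b}", nets.overlap_report(kmeans_genes[a], kmeans_genes[b]))
            )
    return pd.DataFrame(
        [
            (kind, key, r.size_a, r.size_b, r.intersection, r.union,
             round(r.jaccard_pct, 2), round(r.pct_of_a, 2), round(r.pct_of_b, 2))
            for kind, key, r in rows
        ],
        columns=["comparison", "key", "size_a", "size_b", "intersection",
                 "union", "jaccard_pct", "pct_of_a", "pct_of_b"],
    )


def _kmeans_gene_sets(
    depmat: dep.DependencyMatrix,
    clusters: dep.GeneClusterResult,
    terms: Sequence[str],
) -> dict[str, set]:
    """Gene set a phenotype 'identifies' under the divisive route: the
    members of the gene cluster whose centroid loads highest on the
    phenotype's present column."""
    out: dict[str, set] = {}
    nz = depmat.subset_genes(clusters.genes)
    for term in terms:
        col = nz.columns.index(term + dep.PRESENT)
        best = int(np.argmax(clusters.centroids[:, col])) + 1
        out[term] = set(clusters.members(best))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the run report (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "warnings": [], "selected": {}, "counts": {}}
    caught: list[str] = []

    def stage(name: str):
        log.info("stage %s", name)
        report["stages"].append(name)

    # ---- simulate ----------------------------------------------------
    spec = sim.CohortSpec(
        n_individuals=config.sim_n_individuals,
        n_phenotypes=config.sim_n_phenotypes,
        n_genes=config.sim_n_genes,
        n_pheno_clusters=config.sim_n_pheno_clusters,
        dominant_penetrance=config.sim_dominant_penetrance,
        background_rate=config.sim_background_rate,
        seed=config.seed,
    )
    if config.simulate:
        stage("simulate")
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        cohort_s = sim.generate_cohort(spec)
        ph, gp, cp, tp = (
            inputs / "phenotypes.tsv", inputs / "genes.tsv",
            inputs / "classification.tsv", inputs / "truth.tsv",
        )
        sim.write_cohort(cohort_s, ph, gp, cp, tp)
        edges = sim.synthetic_edge_list(spec)
        ep = inputs / "edges.tsv"
        edges.to_csv(ep, sep="\t", index=False)
        gmt_sets = sim.synthetic_gene_sets(spec)
        gmt_p = inputs / "gene_sets.gmt"
        with open(gmt_p, "w") as fh:
            for name, genes in gmt_sets.items():
                fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
        phenotype_path, gene_path, classification_path = ph, gp, cp
        edge_list_path, gmt_path = ep, gmt_p
    else:
        for key in ("phenotype_path", "gene_path", "classification_path", "edge_list_path"):
            if getattr(config, key) is None:
                raise StageError("inputs", f"{key} required when simulate is false")
            if not Path(getattr(config, key)).exists():
                raise StageError("inputs", f"missing input file {getattr(config, key)}")
        phenotype_path = Path(config.phenotype_path)
        gene_path = Path(config.gene_path)
        classification_path = Path(config.classification_path)
        edge_list_path = Path(config.edge_list_path)
        gmt_path = Path(config.gmt_path) if config.gmt_path else None

    # ---- load --------------------------------------------------------
    stage("load")
    try:
        cohort = cio.load_cohort(phenotype_path, gene_path, classification_path)
    except (cio.SchemaError, ValueError) as exc:
        raise StageError("load", str(exc)) from exc
    report["counts"]["individuals"] = len(cohort)
    anchor = {config.anchor_term} if config.anchor_term else set()
    clusterable = [ind for ind in cohort if ind.phenotypes - anchor]
    dropped = len(cohort) - len(clusterable)
    if dropped:
        report["warnings"].append(
            f"{dropped} individual(s) with no functional phenotype beyond the "
            "anchor excluded from clustering"
        )

    # ---- phenotype HAC -----------------------------------------------
    stage("hac")
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        dist = hac.jaccard_matrix(clusterable, exclude=anchor)
        dend = hac.ward_linkage(dist)
        result = hac.cut_dendrogram(dend, dist, k=config.hac_k, k_range=config.hac_k_range)
        diagnostics = hac.cluster_diagnostics(clusterable, result, exclude_anchor=config.anchor_term)
        caught += [str(w.message) for w in wlist]
    report["selected"]["hac_k"] = result.k
    report["selected"]["hac_mean_silhouette"] = round(result.sil_overall, 6)

    labels_df = pd.DataFrame(
        {"individual_id": result.ids, "cluster": result.labels,
         "silhouette": np.round(result.sil_samples, 6)}
    )
    labels_df.to_csv(out / "hac_labels.tsv", sep="\t", index=False)
    pd.DataFrame(dend.merges, columns=["node_a", "node_b", "height", "size"]).to_csv(
        out / "hac_merges.tsv", sep="\t", index=False
    )
    (out / "hac_dendrogram.nwk").write_text(hac.to_newick(dend, list(result.ids)))
    diag_rows = [
        (c, d["size"], d["dominant"], d["dominant_count"],
         ";".join(f"{t}:{n}" for t, n in d["top5"]), round(result.sil_by_cluster[c], 6))
        for c, d in diagnostics.items()
    ]
    pd.DataFrame(
        diag_rows,
        columns=["cluster", "size", "dominant", "dominant_count", "top5", "mean_silhouette"],
    ).to_csv(out / "hac_diagnostics.tsv", sep="\t", index=False)

    # clusters analyzed downstream: largest dominant-phenotype clusters
    ranked = sorted(
        (c for c, d in diagnostics.items() if d["dominant"]),
        key=lambda c: (-diagnostics[c]["size"], c),
    )
    focus = ranked[: config.n_clusters_for_networks]
    hac_gene_sets: dict[str, set] = {}
    for c in focus:
        genes_c, _counts = hac.cluster_gene_union(clusterable, result, c)
        hac_gene_sets[diagnostics[c]["dominant"]] = set(genes_c)

    # ---- dependency model --------------------------------------------
    stage("depmodel")
    terms = config.dep_phenotypes or sorted(hac_gene_sets)
    try:
        depmat = dep.build_dependency_matrix(
            cohort, terms, include_absent=config.dep_include_absent
        )
    except ValueError as exc:
        raise StageError("depmodel", str(exc)) from exc
    if config.dep_k == "auto":
        sel = dep.select_k(depmat, k_range=config.dep_k_range, seed=config.seed)
        dep_k = max(sel["k"], 2)
        report["selected"]["dep_k"] = sel["k"]
        report["selected"]["dep_elbow_k"] = sel["elbow_k"]
        if not sel["degenerate"]:
            sel["diagnostics"].to_csv(out / "dep_k_selection.tsv", sep="\t", index=False)
    else:
        dep_k = int(config.dep_k)
        report["selected"]["dep_k"] = dep_k
    gclust = dep.kmeans_genes(depmat, k=dep_k, seed=config.seed)
    contrast = dep.contrast_clusters(depmat, gclust, alpha=config.dep_alpha)
    caught += [f"skipped gene cluster {c}" for c in contrast.skipped_clusters]
    depmat.to_frame().round(8).to_csv(out / "dependency_matrix.tsv", sep="\t")
    pd.DataFrame(
        {"gene": gclust.genes, "cluster": gclust.labels}
    ).to_csv(out / "gene_clusters.tsv", sep="\t", index=False)
    contrast.table.round(10).to_csv(out / "cluster_contrasts.tsv", sep="\t", index=False)
    kmeans_gene_sets = _kmeans_gene_sets(depmat, gclust, terms)
    report["counts"]["dep_genes"] = len(gclust.genes)

    # ---- gene networks -----------------------------------------------
    stage("networks")
    background = sorted({g for ind in cohort for g in ind.genes})
    gene_sets = nets.read_gmt(gmt_path) if gmt_path else {}
    net_summary = {}
    for term, genes_t in sorted(hac_gene_sets.items()):
        net = nets.induce_network(genes_t, edge_list_path, min_score=config.net_min_score)
        part = nets.mcl_cluster(
            net,
            inflation=config.mcl_inflation,
            expansion=config.mcl_expansion,
            prune_threshold=config.mcl_prune_threshold,
            max_iter=config.mcl_max_iter,
            tol=config.mcl_tol,
        )
        if not part.converged:
            caught.append(f"MCL did not converge for {term}")
        summ = nets.summarize_subnetworks(part, min_size=config.subnetwork_min_size)
        net_summary[term] = {
            "n_genes": summ["n_genes"],
            "n_subnetworks": summ["n_subnetworks"],
            "n_large": summ["n_large"],
        }
        tag = term.replace(":", "_")
        pd.DataFrame(
            sorted(part.assignment.items()), columns=["gene", "subnetwork"]
        ).to_csv(out / f"subnetworks_{tag}.tsv", sep="\t", index=False)
        if gene_sets:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                enr = nets.enrich(part, gene_sets, background, q_threshold=config.enrich_q)
                caught += [str(w.message) for w in wlist]
            enr.round(10).to_csv(out / f"enrichment_{tag}.tsv", sep="\t", index=False)
    report["counts"]["networks"] = net_summary

    # ---- compare ------------------------------------------------------
    stage("compare")
    comparison = compare_methods(hac_gene_sets, kmeans_gene_sets)
    comparison.to_csv(out / "method_overlap.tsv", sep="\t", index=False)

    report["warnings"] += caught
    report["config"] = json.loads(config.model_dump_json())
    report["digests"] = {
        p.name: _digest(p) for p in sorted(out.glob("*.tsv")) if p.is_file()
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
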