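"""Synthetic GDD-like cohort generator.

Produces cohorts with the statistical structure the downstream analyses
assume: planted phenotype clusters each carrying one dominant phenotype,
planted gene modules probabilistically associated with specific phenotypes,
a GDD anchor term carried by roughly half the cohort, long-tailed phenotype
sets (sizes clipped to a configurable range, mode around 2), and a
zero-inflated per-individual candidate-gene count with a configurable
median and zero fraction.

Phenotype term IDs are opaque ``HP:SYNxxxx`` strings; no ontology semantics
are simulated — the pipeline treats terms as atomic binary features.
All randomness flows through one ``numpy.random.Generator`` seeded from
``CohortSpec.seed``; regeneration from an identical spec is byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Individual

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "synthetic_edge_list",
    "synthetic_gene_sets",
]

GDD_ANCHOR_TERM = "HP:SYNGDD"


def _pheno_id(i: int) -> str:
    return f"HP:SYN{i:04d}"


def _morph_id(i: int) -> str:
    return f"HP:MORPH{i:04d}"


def _gene_id(i: int) -> str:
    return f"GENE{i:04d}"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults are a desk-scale rendition of the cohort the analyses target:
    1000 individuals, four planted phenotype clusters whose dominant
    phenotypes are each associated (probability 0.8) with one 12-gene
    module. The phenotype universe holds the K cluster-marker terms plus
    ``n_phenotypes - K`` noise terms; background carriage draws only from
    the noise terms (a marker of another cluster would make the planted
    label of its carrier genuinely ambiguous), and the default universe is
    kept lean so the per-individual background load stays low enough for
    the planted partition to be recoverable at the default penetrance.
    """

    n_individuals: int = 1000
    n_phenotypes: int = 6
    n_genes: int = 150
    n_pheno_clusters: int = 4
    dominant_penetrance: float = 0.9
    background_rate: float = 0.02
    pheno_set_size_range: tuple[int, int] = (1, 15)
    gene_module_sizes: tuple[int, ...] = (12, 12, 12, 12)
    # module index -> (phenotype term, association probability); None means
    # "module i is associated with the dominant phenotype of cluster i".
    module_phenotype_assoc: dict[int, tuple[str, float]] | None = None
    baseline_gene_rate: float = 0.03
    genes_per_individual_median: int = 3
    zero_gene_fraction: float = 0.035
    gdd_anchor_rate: float = 0.5
    n_morph_terms: int = 3
    morph_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "dominant_penetrance",
            "background_rate",
            "baseline_gene_rate",
            "zero_gene_fraction",
            "gdd_anchor_rate",
            "morph_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in (
            "n_individuals",
            "n_phenotypes",
            "n_genes",
            "n_pheno_clusters",
            "genes_per_individual_median",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_pheno_clusters > self.n_individuals:
            raise ValueError("n_pheno_clusters exceeds n_individuals")
        if self.n_pheno_clusters > self.n_phenotypes:
            raise ValueError("n_pheno_clusters exceeds n_phenotypes")
        if sum(self.gene_module_sizes) > self.n_genes:
            raise ValueError("sum of gene_module_sizes exceeds n_genes")
        lo, hi = self.pheno_set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("pheno_set_size_range must satisfy 1 <= lo <= hi")
        if self.dominant_penetrance < self.background_rate:
            raise ValueError(
                "dominant_penetrance is below background_rate; planted "
                "clusters would be undetectable"
            )
        if self.module_phenotype_assoc is not None:
            for mod, (term, p) in self.module_phenotype_assoc.items():
                if not 0 <= mod < len(self.gene_module_sizes):
                    raise ValueError(f"module_phenotype_assoc references unknown module {mod}")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"association probability for module {mod} not in [0, 1]")

    @property
    def phenotype_universe(self) -> list[str]:
        return [_pheno_id(i) for i in range(1, self.n_phenotypes + 1)]

    @property
    def gene_universe(self) -> list[str]:
        return [_gene_id(i) for i in range(1, self.n_genes + 1)]

    @property
    def dominant_phenotypes(self) -> list[str]:
        """Dominant phenotype of each planted cluster (first K terms)."""
        return self.phenotype_universe[: self.n_pheno_clusters]

    def resolved_assoc(self) -> dict[int, tuple[str, float]]:
        if self.module_phenotype_assoc is not None:
            return dict(self.module_phenotype_assoc)
        doms = self.dominant_phenotypes
        return {
            m: (doms[m % len(doms)], 0.8)
            for m in range(len(self.gene_module_sizes))
        }


@dataclass
class SyntheticCohort:
    """Individuals carry functional phenotype sets only; morphological
    terms live in ``morph_terms`` and are merged into the written
    phenotype table so the functional/morphological loader filter has
    something to strip."""

    individuals: list[Individual]
    true_pheno_labels: dict[str, int]
    true_gene_modules: dict[str, int]
    spec: CohortSpec
    morph_terms: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.individuals) != self.spec.n_individuals:
            raise ValueError("individual count does not match spec")

    def clusterable(self) -> list[Individual]:
        """Individuals with at least one functional phenotype beyond the
        GDD anchor — the subset phenotype clustering operates on."""
        return [
            ind
            for ind in self.individuals
            if ind.phenotypes - {GDD_ANCHOR_TERM}
        ]


def _gene_count(rng: np.random.Generator, spec: CohortSpec) -> int:
    """Zero-inflated, shifted Poisson: 0 w.p. zero_gene_fraction, else
    1 + Poisson(median - 1), whose median is the configured median."""
    if rng.random() < spec.zero_gene_fraction:
        return 0
    return 1 + int(rng.poisson(spec.genes_per_individual_median - 1))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort with planted phenotype clusters and gene modules."""
    rng = np.random.default_rng(spec.seed)
    phenos = spec.phenotype_universe
    genes = spec.gene_universe
    doms = spec.dominant_phenotypes
    noise_terms = phenos[spec.n_pheno_clusters :]
    lo, hi = spec.pheno_set_size_range

    # Gene modules occupy the head of the gene universe, in order.
    modules: list[list[str]] = []
    start = 0
    for size in spec.gene_module_sizes:
        modules.append(genes[start : start + size])
        start += size
    true_gene_modules = {g: m for m, mod in enumerate(modules) for g in mod}
    assoc = spec.resolved_assoc()
    # phenotype term -> list of (module genes, association probability)
    pheno_modules: dict[str, list[tuple[list[str], float]]] = {}
    for m, (term, p) in assoc.items():
        pheno_modules.setdefault(term, []).append((modules[m], p))

    individuals: list[Individual] = []
    true_labels: dict[str, int] = {}
    morph_by_id: dict[str, frozenset[str]] = {}
    cluster_of = rng.integers(0, spec.n_pheno_clusters, size=spec.n_individuals)
    for idx in range(spec.n_individuals):
        iid = f"IND{idx + 1:05d}"
        cluster = int(cluster_of[idx])
        dom = doms[cluster]

        pset: set[str] = set()
        if rng.random() < spec.dominant_penetrance:
            pset.add(dom)
        background = rng.random(len(noise_terms)) < spec.background_rate
        for j in np.flatnonzero(background):
            pset.add(noise_terms[j])
        if rng.random() < spec.gdd_anchor_rate:
            pset.add(GDD_ANCHOR_TERM)
        # Clip to the configured size range. Undershoot is padded with the
        # anchor first (so observed penetrance stays unbiased and the
        # individual remains identifiable as signal-free), then random
        # non-dominant terms; overshoot drops random background terms.
        if len(pset) < lo:
            pset.add(GDD_ANCHOR_TERM)
        while len(pset) < lo and noise_terms:
            pset.add(noise_terms[int(rng.integers(0, len(noise_terms)))])
        if len(pset) > hi:
            removable = sorted(pset - {dom, GDD_ANCHOR_TERM})
            rng.shuffle(removable)
            for term in removable[: len(pset) - hi]:
                pset.discard(term)

        morph = {
            _morph_id(j + 1)
            for j in range(spec.n_morph_terms)
            if rng.random() < spec.morph_rate
        }

        n_g = _gene_count(rng, spec)
        gset: set[str] = set()
        if n_g > 0:
            # One module draw per carried, module-associated phenotype;
            # non-carriers leak module genes at the baseline rate.
            for term, mods in pheno_modules.items():
                for mod_genes, p in mods:
                    rate = p if term in pset else spec.baseline_gene_rate
                    if len(gset) < n_g and rng.random() < rate:
                        gset.add(mod_genes[int(rng.integers(0, len(mod_genes)))])
            while len(gset) < n_g:
                gset.add(genes[int(rng.integers(0, len(genes)))])

        individuals.append(
            Individual(id=iid, phenotypes=frozenset(pset), genes=frozenset(gset))
        )
        morph_by_id[iid] = frozenset(morph)
        true_labels[iid] = cluster

    return SyntheticCohort(
        individuals=individuals,
        true_pheno_labels=true_labels,
        true_gene_modules=true_gene_modules,
        spec=spec,
        morph_terms=morph_by_id,
    )


def classification_table(spec: CohortSpec) -> pd.DataFrame:
    """Term classification covering the generated universes: synthetic
    functional terms plus the anchor are 'functional', HP:MORPH* terms
    'morphological'."""
    rows = [(t, "functional") for t in spec.phenotype_universe]
    rows.append((GDD_ANCHOR_TERM, "functional"))
    rows += [(_morph_id(i + 1), "morphological") for i in range(spec.n_morph_terms)]
    return pd.DataFrame(rows, columns=["term_id", "class"])


def write_cohort(
    cohort: SyntheticCohort,
    phenotype_path: str | Path,
    gene_path: str | Path,
    classification_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write the cohort in the TSV formats the loaders consume.

    Phenotype and gene columns are semicolon-separated, sorted for
    reproducibility; a truth TSV with the planted labels is written when a
    path is given.
    """
    ph_rows = [
        (
            ind.id,
            ";".join(sorted(ind.phenotypes | cohort.morph_terms.get(ind.id, frozenset()))),
        )
        for ind in cohort.individuals
    ]
    pd.DataFrame(ph_rows, columns=["individual_id", "phenotypes"]).to_csv(
        phenotype_path, sep="\t", index=False
    )
    g_rows = [(ind.id, ";".join(sorted(ind.genes))) for ind in cohort.individuals]
    pd.DataFrame(g_rows, columns=["individual_id", "genes"]).to_csv(
        gene_path, sep="\t", index=False
    )
    classification_table(cohort.spec).to_csv(classification_path, sep="\t", index=False)
    if truth_path is not None:
        t_rows = [
            (ind.id, cohort.true_pheno_labels[ind.id]) for ind in cohort.individuals
        ]
        pd.DataFrame(t_rows, columns=["individual_id", "true_cluster"]).to_csv(
            truth_path, sep="\t", index=False
        )


def synthetic_edge_list(
    spec: CohortSpec,
    within_module_p: float = 0.6,
    background_p: float = 0.01,
    seed_offset: int = 1,
) -> pd.DataFrame:
    """Interaction edge list whose dense blocks are the planted gene
    modules, for end-to-end runs without an external interaction database.

    Scores are STRING-like combined scores in (0, 1]; within-module edges
    score higher (0.7-0.99) than background edges (0.4-0.6).
    """
    rng = np.random.default_rng(spec.seed + seed_offset)
    genes = spec.gene_universe
    module_of = {}
    start = 0
    for m, size in enumerate(spec.gene_module_sizes):
        for g in genes[start : start + size]:
            module_of[g] = m
        start += size
    rows = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            same = module_of.get(g1) is not None and module_of.get(g1) == module_of.get(g2)
            if same and rng.random() < within_module_p:
                rows.append((g1, g2, round(float(rng.uniform(0.7, 0.99)), 3)))
            elif not same and rng.random() < background_p:
                rows.append((g1, g2, round(float(rng.uniform(0.4, 0.6)), 3)))
    return pd.DataFrame(rows, columns=["node1", "node2", "score"])


def synthetic_gene_sets(spec: CohortSpec) -> dict[str, list[str]]:
    """GMT-style gene sets: one per planted module plus a catch-all, for
    exercising over-representation analysis."""
    sets: dict[str, list[str]] = {}
    start = 0
    for m, size in enumerate(spec.gene_module_sizes):
        sets[f"MODULE_{m}_PATHWAY"] = spec.gene_universe[start : start + size]
        start += size
    sets["ALL_CANDIDATES"] = list(spec.gene_universe)
    return sets


def spec_with(spec: CohortSpec, **overrides) -> CohortSpec:
    """Return a copy of ``spec`` with fields replaced."""
    return dataclasses.replace(spec, **overrides)
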