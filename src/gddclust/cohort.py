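"""Cohort I/O, curation and filtering.

Reads the cohort phenotype/gene tables, restricts phenotype sets to
functional terms using a term classification table, applies the candidate
gene-list curation rule (a gene must appear in at least ``min_support``
source lists), filters annotated variants on allele frequency and clinical
significance, and computes phenotype prevalence summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Individual",
    "CuratedGeneList",
    "VariantRecord",
    "SchemaError",
    "load_classification",
    "load_cohort",
    "curate_gene_list",
    "read_variant_table",
    "read_variants_vcf",
    "filter_variants",
    "prevalence_percentage",
    "prevalence_table",
]


class SchemaError(ValueError):
    """Input file violates the declared schema."""


@dataclass(frozen=True)
class Individual:
    """One cohort member: opaque ID, functional phenotype set, and the set
    of genes carrying retained (pathogenic/likely pathogenic) variants."""

    id: str
    phenotypes: frozenset[str] = frozenset()
    genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("individual id must be non-empty")


@dataclass(frozen=True)
class CuratedGeneList:
    genes: frozenset[str]
    support: Mapping[str, int]
    min_support: int

    def __post_init__(self) -> None:
        bad = [g for g in self.genes if self.support.get(g, 0) < self.min_support]
        if bad:
            raise ValueError(f"genes below min_support retained: {bad[:5]}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class VariantRecord:
    individual_id: str
    gene: str
    allele_frequency: float | None = None
    clinical_significance: str = ""
    impact: str | None = None

    def __post_init__(self) -> None:
        af = self.allele_frequency
        if af is not None and not 0.0 <= af <= 1.0:
            raise ValueError(
                f"allele frequency {af!r} outside [0, 1] for {self.individual_id}/{self.gene}"
            )


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def load_classification(path: str | Path) -> dict[str, str]:
    """term_id -> {'functional', 'morphological'} lookup."""
    df = _read_tsv(path, ["term_id", "class"])
    bad = sorted(set(df["class"]) - {"functional", "morphological"})
    if bad:
        raise SchemaError(f"{path}: unknown phenotype class label(s) {bad}")
    return dict(zip(df["term_id"], df["class"]))


def _split_field(cell: str) -> set[str]:
    return {tok for tok in cell.split(";") if tok}


def load_cohort(
    phenotype_path: str | Path,
    gene_path: str | Path | None,
    classification_path: str | Path,
) -> list[Individual]:
    """Load individuals, keeping only phenotypes classified as functional.

    A term appearing in the cohort but absent from the classification table
    is a schema error, never silently dropped. Duplicate individual IDs are
    an error; duplicate terms/genes within a cell are de-duplicated.
    """
    classification = load_classification(classification_path)
    ph = _read_tsv(phenotype_path, ["individual_id", "phenotypes"])
    dup = ph["individual_id"][ph["individual_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate individual_id(s): {sorted(set(dup))[:5]}")

    genes_by_id: dict[str, set[str]] = {}
    if gene_path is not None:
        gdf = _read_tsv(gene_path, ["individual_id", "genes"])
        for iid, cell in zip(gdf["individual_id"], gdf["genes"]):
            genes_by_id.setdefault(iid, set()).update(_split_field(cell))

    individuals = []
    for iid, cell in zip(ph["individual_id"], ph["phenotypes"]):
        terms = _split_field(cell)
        unknown = sorted(t for t in terms if t not in classification)
        if unknown:
            raise SchemaError(
                f"phenotype term(s) missing from classification table: {unknown[:5]}"
            )
        functional = frozenset(t for t in terms if classification[t] == "functional")
        individuals.append(
            Individual(
                id=iid,
                phenotypes=functional,
                genes=frozenset(genes_by_id.get(iid, set())),
            )
        )
    return individuals


def curate_gene_list(
    source_lists: Iterable[Iterable[str]], min_support: int = 3
) -> CuratedGeneList:
    """Retain genes appearing in at least ``min_support`` source lists.

    Each source list counts once per gene regardless of internal duplicates.
    """
    source_lists = [set(lst) for lst in source_lists]
    if len(source_lists) < min_support:
        raise ValueError(
            f"only {len(source_lists)} source list(s) supplied; no gene can "
            f"reach min_support={min_support}"
        )
    support: Counter[str] = Counter()
    for lst in source_lists:
        support.update(lst)
    retained = frozenset(g for g, c in support.items() if c >= min_support)
    return CuratedGeneList(genes=retained, support=dict(support), min_support=min_support)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Parse a simplified annotated-variant TSV
    (individual_id, gene, af, clnsig[, impact]); empty af/impact are missing."""
    df = _read_tsv(path, ["individual_id", "gene", "af", "clnsig"])
    records = []
    for i, row in df.iterrows():
        af_cell = row["af"].strip()
        if af_cell in ("", ".", "NA"):
            af = None
        else:
            af = float(af_cell)
            if af < 0:
                raise SchemaError(f"{path} line {i + 2}: negative allele frequency {af}")
        impact = row["impact"].strip() if "impact" in df.columns else None
        records.append(
            VariantRecord(
                individual_id=row["individual_id"],
                gene=row["gene"],
                allele_frequency=af,
                clinical_significance=row["clnsig"],
                impact=impact or None,
            )
        )
    return records


def read_variants_vcf(path: str | Path, sample_key: str = "SAMPLE") -> list[VariantRecord]:
    """Minimal sites-only VCF dialect: INFO keys GENE, AF, CLNSIG and
    optionally IMPACT and SAMPLE (the individual the site is reported for)."""
    import pysam

    def _get(info, key):
        # pysam raises on INFO keys absent from the header
        try:
            return info.get(key)
        except (KeyError, ValueError):
            return None

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            info = site.info
            gene = _get(info, "GENE")
            if gene is None:
                continue
            if isinstance(gene, tuple):
                gene = gene[0]
            af = _get(info, "AF")
            if isinstance(af, tuple):
                af = af[0]
            clnsig = _get(info, "CLNSIG") or ""
            if isinstance(clnsig, tuple):
                clnsig = clnsig[0]
            impact = _get(info, "IMPACT")
            if isinstance(impact, tuple):
                impact = impact[0]
            iid = _get(info, sample_key)
            if isinstance(iid, tuple):
                iid = iid[0]
            records.append(
                VariantRecord(
                    individual_id=str(iid) if iid is not None else "",
                    gene=str(gene),
                    allele_frequency=float(af) if af is not None else None,
                    clinical_significance=str(clnsig),
                    impact=str(impact) if impact is not None else None,
                )
            )
    return records


def _norm_label(label: str) -> str:
    return label.strip().lower().replace(" ", "_")


def filter_variants(
    records: Iterable[VariantRecord],
    curated: CuratedGeneList,
    max_maf: float = 0.01,
    keep_significance: Iterable[str] = ("Pathogenic", "Likely_pathogenic"),
    keep_impact: Iterable[str] = ("HIGH", "MODERATE"),
) -> dict[str, frozenset[str]]:
    """Aggregate variants surviving the rare-pathogenic filter into
    per-individual gene sets.

    A record survives iff its gene is in the curated list, its allele
    frequency is missing (treated as rare) or <= max_maf, its clinical
    significance is in ``keep_significance`` (case- and separator-
    insensitive), and — when an impact annotation is present — its impact
    is in ``keep_impact``.
    """
    if not curated.genes:
        raise ValueError("curated gene list is empty")
    keep_sig = {_norm_label(s) for s in keep_significance}
    keep_imp = {s.strip().upper() for s in keep_impact}
    out: dict[str, set[str]] = {}
    for rec in records:
        if rec.gene not in curated:
            continue
        if rec.allele_frequency is not None and rec.allele_frequency > max_maf:
            continue
        if _norm_label(rec.clinical_significance) not in keep_sig:
            continue
        if rec.impact is not None and rec.impact.strip().upper() not in keep_imp:
            continue
        out.setdefault(rec.individual_id, set()).add(rec.gene)
    return {iid: frozenset(gs) for iid, gs in out.items()}


def prevalence_percentage(count: int, n: int) -> float:
    """100*count/n rounded half-up to 2 decimals (presentation convention)."""
    return float(
        (Decimal(100) * Decimal(count) / Decimal(n)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def prevalence_table(cohort: list[Individual], min_pct: float = 1.0) -> pd.DataFrame:
    """Per-phenotype carrier counts and cohort percentages, most prevalent
    first; rows below ``min_pct`` percent are omitted."""
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    counts: Counter[str] = Counter()
    for ind in cohort:
        counts.update(ind.phenotypes)
    rows = [
        (term, c, prevalence_percentage(c, n))
        for term, c in counts.items()
        if prevalence_percentage(c, n) >= min_pct
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["phenotype", "count", "percentage"])
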