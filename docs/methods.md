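# Methods

## The analysis

`gddclust` stratifies a phenotyped, exome-annotated cohort two ways and
compares the results at the gene level.

**Inputs.** A cohort table (individual → set of HPO-style phenotype term
IDs), a term classification (functional vs morphological — only
functional terms are analyzed, since the goal is grouping for
intervention rather than dysmorphology), per-individual candidate-gene
sets (genes carrying retained rare pathogenic variants), candidate-gene
source lists, a weighted gene–gene interaction edge list, and flat GMT
gene sets for enrichment. Terms are treated as atomic binary features; no
ontology traversal or term-similarity semantics are used.

**Curation and filtering.** The candidate-gene list retains genes present
in at least `min_support` (default 3) independent source lists. Variant
records are kept when the gene is curated, the allele frequency is ≤ 1%
or missing (absence from population databases is treated as rarity, the
standard rare-variant convention), the clinical significance is
pathogenic or likely pathogenic (matching is case- and
separator-insensitive across ClinVar dialects), and — when an impact
annotation is present at all — the impact is in the configured keep set
(default HIGH, MODERATE). Prevalence percentages are 100·count/N rounded
half-up to two decimals, matching clinical-table presentation.

**Agglomerative route.** Individuals are compared by Jaccard distance on
their functional phenotype sets. The distance is undefined for two empty
sets, so individuals with no functional phenotype — and, when an anchor
term is configured, no phenotype beyond that anchor — are excluded before
clustering, and the anchor itself is dropped from the distance features.
The anchor (the GDD diagnosis term itself) is carried cohort-wide at
roughly 50% independently of any subgroup: it cannot separate subgroups,
and at intermediate carriage rates it actively splits every real cluster
into anchor/no-anchor halves, so removing it is the conservative choice.
Ward linkage runs directly on the dissimilarity matrix via the
Lance–Williams recurrence applied to squared dissimilarities, with merge
heights reported as square roots (the conventional Ward definition;
embedding the sets into Euclidean space first would change the results).
Flat cuts at a requested k use the standard maxclust criterion; the
automatic cut is placed at the largest merge-height gap within the
scanned range (ties toward smaller k). Silhouettes — per individual, per
cluster and overall, singleton convention SIL = 0 — are computed on the
same Jaccard matrix as the validation metric for whatever cut is chosen.

*Why the automatic cut is not silhouette-maximizing.* On discrete set
profiles many individuals share identical phenotype sets. The partition
that isolates identical-profile groups has silhouette near 1 (each group
has zero intra-cluster distance), so the mean silhouette rises almost
monotonically with k and its maximum over a scanned range lands at the
top of the range rather than at any coarser structure; we verified this
across universe sizes from 5 to 80 terms. The merge-height gap is the
classic dendrogram-scale heuristic, is deterministic, and recovers
planted structure reliably; silhouette remains the validity measure it is
normally used as.

**Divisive route.** The dependency matrix accumulates, for every gene g
and phenotype condition h, Σ_j 1{g ∈ genes_j}·1{condition h holds for
I_j}·P(I_j) with uniform priors by default, then normalizes each
supported column to sum to 1, yielding a conditional distribution over
genes per condition. Conditions are a "present" column per phenotype of
interest and, by default, the matching "absent" column — the absent
condition is what separates genes never seen with a phenotype from genes
associated with it. The indicator form of P(g|I_j) keeps each carried
gene's evidence equal across individuals; a per-individual-normalized
variant (1/|genes_j|) is available via a switch. No causal direction
between genes and phenotypes is asserted anywhere. Genes with all-zero
rows are flagged and excluded from clustering. k-means (Lloyd,
k-means++-style greedy seeding, best of 10 restarts, seeded) runs on the
column-normalized rows with Euclidean distance; the cluster count is
chosen as the silhouette-maximizing k over the scanned range (here the
rows are continuous, so silhouette selection is well behaved), with the
elbow of the inertia curve — the point of maximum perpendicular distance
to the chord, axes min-max normalized — reported alongside. Within each
gene cluster of size ≥ 2, every unordered pair of condition columns is
contrasted with a Welch (unequal-variance) t-test; cluster sizes and
variances differ grossly, so the pooled test would be wrong. The
Bonferroni family is all tests actually performed (clusters × column
pairs); zero-variance degenerate pairs are defined as t = 0, p = 1 when
equal and p = 0 when trivially different.

**Network route.** The gene set of interest is projected onto the edge
list (STRING-style integer scores are rescaled by 1/1000; edges below
`min_score`, default 0.4, are dropped; isolated genes stay as singleton
nodes). MCL runs on the column-stochastic flow matrix with unit
self-loops: expansion (matrix power 2), inflation (entrywise power 1.5
then column renormalization), pruning (entries < 1e-5 zeroed,
renormalized), until the matrix changes by < 1e-6 or 100 iterations
(non-convergence is flagged, not fatal). Clusters are read from attractor
rows; a node claimed by several attractors goes to the one holding more
flow mass, ties lexicographic. These loop constants are common MCL
practice and all exposed. Sub-networks strictly larger than 10 genes are
highlighted. Enrichment uses the one-sided hypergeometric tail
P(X ≥ overlap) against a background defaulting to the analyzable gene
set rather than the genome — the input list is already heavily selected,
and a genome background would mostly re-detect that selection. BH runs
within each sub-network by default (a global-family switch exists).
Overlap between gene sets is reported as Jaccard × 100, with |∩|/|A| and
|∩|/|B| alongside since percentage conventions vary.

**Pipeline.** A flat, module-prefixed configuration (unknown keys
rejected) drives simulate → load → HAC → dependency model → networks →
compare. Stage order, record counts, selected k values, warnings and
SHA-256 digests of every output table go into `report.json`; identical
configuration reproduces identical bytes. The CLI is a thin veneer: exit
code 2 for configuration errors, 3 for data errors, 4 for stage failures.

## The synthetic generator

The generator emulates the statistical shape of a large GDD cohort at
desk scale so that every stage has testable ground truth.

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 1000 | cohort size (scaled down from thousands) |
| `n_pheno_clusters` | 4 | planted clusters, one dominant marker each |
| `n_phenotypes` | 6 | term universe: K markers + noise terms |
| `dominant_penetrance` | 0.9 | P(member carries its cluster's marker) |
| `background_rate` | 0.02 | per noise term carriage probability |
| `gdd_anchor_rate` | 0.5 | P(carries the GDD anchor term) |
| `pheno_set_size_range` | [1, 15] | set sizes clipped into this range |
| `gene_module_sizes` | 4 × 12 | planted gene modules |
| association probability | 0.8 | P(carrier of marker h draws a gene from h's module) |
| `baseline_gene_rate` | 0.03 | module-gene draw rate for non-carriers |
| `genes_per_individual_median` | 3 | median candidate-gene count |
| `zero_gene_fraction` | 0.035 | individuals with no candidate gene |

Gene counts are zero-inflated shifted Poisson (0 with probability
`zero_gene_fraction`, else 1 + Poisson(median − 1)), which hits the
configured median and zero fraction with two parameters. For each carried
marker phenotype, one gene is drawn from the associated module with the
association probability; non-carriers draw from the module at the
baseline rate; remaining slots fill uniformly from the gene universe.
Morphological terms are generated separately and merged only into the
written phenotype table, so the loader's functional/morphological filter
has something to strip. All randomness flows through a single seeded
generator; regeneration from an identical spec is byte-identical.

Two generator design points deserve emphasis. First, background noise
draws only from non-marker terms: an individual carrying two clusters'
markers would have a genuinely ill-defined planted label, and with
iid background over the whole universe the label noise alone caps
full-cohort recovery well below the level at which recovery is a useful
test. Second, the default universe is deliberately lean (6 terms), which
keeps the expected background load near 0.04 terms per individual; at the
default penetrance of 0.9 this is what makes the planted partition the
unambiguous dendrogram-scale optimum. With these defaults, automatic
cutting selects the planted K and recovers labels at ARI 0.91–0.98
across seeds, and k-means on the dependency matrix recovers the planted
gene modules at ARI ≥ 0.94.

**What passing tests do and do not show.** The generator's clusters are
idealized: real cohorts have hundreds of terms, clusters defined by
partially overlapping phenotype combinations, silhouettes barely above
zero for some groups, and a large residual cluster with no dominant
phenotype. Recovery of planted structure demonstrates that the
implementation is correct, not that real cohorts separate this cleanly;
on real data the choice of k, the treatment of the residual cluster and
the interpretation of low-silhouette clusters remain analyst decisions.
The generator also simulates no sequencing reads, variant calls, pedigree
structure, or HPO graph topology.

## Numerical conventions

- Ward recurrence on squared dissimilarities; heights as square roots;
  among equal minimal pairs the first in node-creation order merges. The
  test oracle recomputes cluster-pair Ward costs from the raw matrix via
  the generalized centroid identity, independently of the recurrence.
- Silhouette: singletons score 0; a_i = b_i = 0 scores 0; aggregates are
  unweighted means.
- Dependency columns with zero support are left as zeros, not normalized.
- k selection ties resolve toward smaller k everywhere.
- Prevalence rounding is half-up (Decimal), not banker's.
- MCL flow matrices are column-renormalized after every inflate and prune
  step; column sums are property-tested to 1e-9.
- Dominant-phenotype computation in cluster diagnostics can exclude the
  configured anchor term, since every cluster trivially contains it.

## Known limitations

- Ward linkage is O(N²) memory and roughly O(N³) time in the naive
  scan used here; fine for cohorts up to a few thousand, not for
  biobank scale.
- MCL is dense; networks beyond a few thousand genes would need a sparse
  implementation.
- The minimal VCF reader handles a sites-only dialect with GENE/AF/CLNSIG
  INFO keys; richer VCFs should be pre-flattened to the variant TSV.
- Enrichment treats gene sets as flat; GO/REACTOME hierarchy is not
  modeled.
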