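# gddclust

Dual clustering of global-developmental-delay (GDD) cohorts for trial
stratification.

Children with GDD are phenotypically and genetically heterogeneous: each
causal gene is individually rare, which makes gene-by-gene trials
impractical. Basket trials instead group distinct diagnoses that share a
molecular mechanism. `gddclust` implements the two complementary ways of
building such groups from a phenotyped, exome-annotated cohort, plus the
network decomposition that splits each group into molecular sub-networks:

1. **Agglomerative phenotype clustering.** Each individual *I<sub>i</sub>*
   is a set of functional HPO terms *P<sub>i</sub>* (morphological terms
   are filtered out). Dissimilarity is the Jaccard distance

   D(I<sub>i</sub>, I<sub>j</sub>) = 1 − |P<sub>i</sub> ∩ P<sub>j</sub>| / |P<sub>i</sub> ∪ P<sub>j</sub>|,

   clustered bottom-up with Ward linkage applied directly to the
   dissimilarity matrix. Cuts are validated with the silhouette index
   SIL<sub>i</sub> = (b<sub>i</sub> − a<sub>i</sub>)/max(a<sub>i</sub>, b<sub>i</sub>),
   and the automatic cut is placed at the largest merge-height gap.

2. **Divisive gene clustering through a dependency model.** A
   gene × phenotype-condition matrix P(G|H) ∝ Σ<sub>j</sub>
   P(G|I<sub>j</sub>)·P(H|I<sub>j</sub>)·P(I<sub>j</sub>) is accumulated
   over individuals with prior weights P(I<sub>j</sub>) (uniform by
   default) and column-normalized; conditions are "phenotype present" and
   optionally "phenotype absent" columns. Genes are clustered with
   k-means, k chosen by elbow + silhouette, and conditions are contrasted
   per gene cluster with Welch t-tests under Bonferroni correction.

3. **Gene sub-networks.** Each cluster's gene set is projected onto a
   STRING-style interaction edge list and decomposed with the Markov
   clustering algorithm (inflation 1.5). Sub-networks with more than 10
   genes are highlighted and tested for over-representation against GMT
   gene sets (one-sided hypergeometric, Benjamini–Hochberg within each
   sub-network). Overlaps between the gene sets the two clustering routes
   identify are reported as Jaccard percentages (with both one-sided
   denominators for inspection).

The real cohorts this targets are controlled-access, so the package ships
a **synthetic cohort generator** that plants phenotype clusters (one
dominant marker phenotype each), gene modules probabilistically associated
with those markers, a GDD anchor term carried by about half the cohort,
and DDD-like marginals (median 3 candidate genes per individual, ~3.5%
with none). Every downstream stage is tested against this generator's
ground truth.

## Worked example

```sh
python examples/02_phenotype_clustering.py
```

```
clustered individuals: 901 (of 1000)
selected k: 4  (planted K = 4)
overall mean silhouette: 0.915
adjusted Rand index vs planted labels: 0.921
cluster 1: size 210, dominant phenotype HP:SYN0002 carried by 210, mean silhouette 1.000
cluster 2: size 209, dominant phenotype HP:SYN0001 carried by 209, mean silhouette 1.000
cluster 3: size 211, dominant phenotype HP:SYN0003 carried by 211, mean silhouette 1.000
cluster 4: size 271, dominant phenotype HP:SYN0004 carried by 243, mean silhouette 0.717
```

99 of 1000 simulated individuals carry no functional phenotype beyond the
GDD anchor and are excluded (they hold no stratification signal). The
automatic cut finds the four planted clusters; each is dominated by one
marker phenotype, and the adjusted Rand index of 0.92 against the planted
labels means the stratification was recovered almost exactly. The other
`examples/` scripts walk through the generator, the dependency model
(module-recovery ARI 1.0 on the same cohort), the MCL sub-network
decomposition with enrichment, and the end-to-end pipeline; the pipeline
is also exposed as a thin CLI:

```sh
gddclust run-all --out-dir run1 --seed 7
```

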