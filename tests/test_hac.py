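"""Phenotype clustering: Jaccard distances, Ward linkage vs a first-
principles oracle, silhouettes, cuts, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from conftest import random_cohort
from gddclust import hac
from gddclust.cohort import Individual
from gddclust.simulate import GDD_ANCHOR_TERM, CohortSpec, generate_cohort
from oracles import silhouette_direct, ward_bruteforce


def _inds(*sets):
    return [Individual(f"I{i}", frozenset(s)) for i, s in enumerate(sets)]


class TestJaccardMatrix:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"h1", "h2"}, {"h1", "h2"}, 0.0),
            ({"h1"}, {"h2"}, 1.0),
            ({"h1", "h2", "h3"}, {"h2", "h3", "h4"}, 0.5),  # 1 - 2/4
        ],
    )
    def test_pairwise_values(self, a, b, expected):
        dist = hac.jaccard_matrix(_inds(a, b))
        assert dist.matrix[0, 1] == pytest.approx(expected)

    def test_empty_sets_rejected_with_ids(self):
        with pytest.raises(ValueError, match="I1"):
            hac.jaccard_matrix(_inds({"h1"}, set()))

    def test_exclude_strips_terms_before_distance(self):
        dist = hac.jaccard_matrix(
            _inds({"h1", "X"}, {"h1"}), exclude={"X"}
        )
        assert dist.matrix[0, 1] == 0.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_distance_axioms_on_random_cohorts(self, seed):
        """Symmetry, zero diagonal, [0,1] range, identity-of-indiscernibles
        and the Jaccard triangle inequality."""
        rng = np.random.default_rng(seed)
        cohort = random_cohort(rng, int(rng.integers(3, 12)))
        d = hac.jaccard_matrix(cohort).matrix
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        assert d.min() >= 0 and d.max() <= 1
        for i, a in enumerate(cohort):
            for j, b in enumerate(cohort):
                assert (d[i, j] == 0) == (a.phenotypes == b.phenotypes)
        n = len(cohort)
        for i in range(n):
            for j in range(n):
                assert np.all(d[i, :] <= d[i, j] + d[j, :] + 1e-12)


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        dist = hac.jaccard_matrix(_inds({"h1", "h2"}, {"h2", "h3"}))
        dend = hac.ward_linkage(dist)
        assert dend.merges[0, 2] == pytest.approx(dist.matrix[0, 1])

    def test_identical_triples_merge_first_at_zero(self):
        cohort = _inds(*([{"a"}] * 3 + [{"b"}] * 3))
        dend = hac.ward_linkage(hac.jaccard_matrix(cohort))
        assert np.all(dend.merges[:4, 2] == 0)
        assert dend.merges[-1, 2] > 0

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            cohort = random_cohort(rng, n)
            dist = hac.jaccard_matrix(cohort)
            got = hac.ward_linkage(dist).merges
            want = ward_bruteforce(dist.matrix)
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_merge_heights_monotone(self, default_cohort):
        sub = default_cohort.clusterable()[:200]
        dend = hac.ward_linkage(hac.jaccard_matrix(sub, exclude={GDD_ANCHOR_TERM}))
        assert np.all(np.diff(dend.merges[:, 2]) >= -1e-9)

    def test_nan_rejected(self):
        dist = hac.jaccard_matrix(_inds({"a"}, {"b"}, {"a", "b"}))
        bad = dist.matrix.copy()
        bad[0, 1] = bad[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            hac.PhenotypeDistanceMatrix(ids=dist.ids, matrix=bad)


class TestSilhouette:
    def test_hand_computed_toy(self):
        """1-D points {0,1 | 10,11}: SIL(0) = (10.5-1)/10.5."""
        x = np.array([0.0, 1.0, 10.0, 11.0])
        d = np.abs(x[:, None] - x[None, :]) / 11.0  # scaled into [0,1]
        dist = hac.PhenotypeDistanceMatrix(ids=("a", "b", "c", "d"), matrix=d)
        sil, _, _ = hac.silhouette(dist, [1, 1, 2, 2])
        assert sil[0] == pytest.approx((10.5 - 1) / 10.5)

    def test_matches_direct_formula_and_sklearn(self):
        rng = np.random.default_rng(7)
        cohort = random_cohort(rng, 30)
        dist = hac.jaccard_matrix(cohort)
        labels = rng.integers(1, 4, size=30)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 + labels[0] % 3
        sil, by_cluster, overall = hac.silhouette(dist, labels)
        np.testing.assert_allclose(sil, silhouette_direct(dist.matrix, labels), atol=1e-12)
        np.testing.assert_allclose(
            sil, silhouette_samples(dist.matrix, labels, metric="precomputed"), atol=1e-9
        )
        assert overall == pytest.approx(sil.mean())
        assert np.all(sil >= -1) and np.all(sil <= 1)

    def test_perfect_blocks_score_one(self, two_block_cohort):
        dist = hac.jaccard_matrix(two_block_cohort.individuals)
        labels = [two_block_cohort.true_pheno_labels[i] for i in dist.ids]
        _, _, overall = hac.silhouette(dist, labels)
        assert overall == 1.0

    def test_single_cluster_rejected(self):
        dist = hac.jaccard_matrix(_inds({"a"}, {"b"}))
        with pytest.raises(ValueError, match="two clusters"):
            hac.silhouette(dist, [1, 1])


class TestCutDendrogram:
    def test_two_block_cut_matches_planted(self, two_block_cohort):
        dist = hac.jaccard_matrix(two_block_cohort.individuals)
        dend = hac.ward_linkage(dist)
        res = hac.cut_dendrogram(dend, dist, k=2)
        truth = [two_block_cohort.true_pheno_labels[i] for i in res.ids]
        assert adjusted_rand_score(truth, res.labels) == 1.0
        assert res.sil_overall == 1.0

    def test_all_singletons_by_convention(self):
        cohort = _inds({"a"}, {"b"}, {"a", "b"}, {"b", "c"})
        dist = hac.jaccard_matrix(cohort)
        res = hac.cut_dendrogram(hac.ward_linkage(dist), dist, k=4)
        assert res.k == 4
        assert np.all(res.sil_samples == 0)

    def test_auto_recovers_planted_k(self, default_cohort):
        sub = default_cohort.clusterable()
        dist = hac.jaccard_matrix(sub, exclude={GDD_ANCHOR_TERM})
        dend = hac.ward_linkage(dist)
        res = hac.cut_dendrogram(dend, dist, k="auto")
        assert res.k == default_cohort.spec.n_pheno_clusters
        # brute-force height-gap scan agrees with the selection
        heights = np.concatenate([[0.0], dend.merges[:, 2]])
        n = len(sub)
        gaps = [
            (heights[n - kk + 1] - heights[n - kk], kk) for kk in range(2, 31)
        ]
        best_k = max(gaps, key=lambda g: (g[0], -g[1]))[1]
        assert res.k == best_k

    def test_k_out_of_range_rejected(self, two_block_cohort):
        dist = hac.jaccard_matrix(two_block_cohort.individuals)
        dend = hac.ward_linkage(dist)
        with pytest.raises(ValueError):
            hac.cut_dendrogram(dend, dist, k=len(two_block_cohort.individuals) + 1)


class TestDiagnosticsAndGenes:
    @pytest.fixture()
    def clustered(self):
        cohort = _inds(
            {"d", "x"}, {"d"}, {"d", "y"}, {"d"},  # cluster of 4, dominant d
            {"e", "y"}, {"e"},  # cluster of 2
        )
        cohort = [
            Individual(ind.id, ind.phenotypes, frozenset({"G1"} if i < 2 else {"G1", "G2"}))
            for i, ind in enumerate(cohort)
        ]
        dist = hac.jaccard_matrix(cohort)
        res = hac.cut_dendrogram(hac.ward_linkage(dist), dist, k=2)
        return cohort, res

    def test_dominant_and_histograms(self, clustered):
        cohort, res = clustered
        diag = hac.cluster_diagnostics(cohort, res)
        big = max(diag.values(), key=lambda d: d["size"])
        assert big["size"] == 4
        assert big["dominant"] == "d" and big["dominant_count"] == 4
        assert sum(big["pheno_count_hist"].values()) == 4
        assert sum(big["shared_count_hist"].values()) == 6  # C(4,2) pairs
        small = min(diag.values(), key=lambda d: d["size"])
        assert small["shared_count_hist"] == {1: 1}

    def test_anchor_excluded_from_dominant(self, clustered):
        cohort, res = clustered
        diag = hac.cluster_diagnostics(cohort, res, exclude_anchor="d")
        big = max(diag.values(), key=lambda d: d["size"])
        assert big["dominant"] in {"x", "y"}

    def test_gene_union_and_counts(self, clustered):
        cohort, res = clustered
        big_id = max(res.sil_by_cluster, key=lambda c: len(res.members(c)))
        union, counts = hac.cluster_gene_union(cohort, res, big_id)
        assert union == {"G1", "G2"}
        assert counts["G1"] == 4 and counts["G2"] == 2
        with pytest.raises(KeyError):
            hac.cluster_gene_union(cohort, res, 99)

    def test_planted_cluster_union_covers_expressed_module_genes(self, default_cohort):
        spec = default_cohort.spec
        sub = default_cohort.clusterable()
        dist = hac.jaccard_matrix(sub, exclude={GDD_ANCHOR_TERM})
        res = hac.cut_dendrogram(hac.ward_linkage(dist), dist, k="auto")
        diag = hac.cluster_diagnostics(sub, res, exclude_anchor=GDD_ANCHOR_TERM)
        by_id = {i.id: i for i in sub}
        assoc = spec.resolved_assoc()
        for c, d in diag.items():
            dom = d["dominant"]
            modules = [m for m, (term, _) in assoc.items() if term == dom]
            if not modules:
                continue
            union, _ = hac.cluster_gene_union(sub, res, c)
            expressed = {
                g
                for iid, ind in by_id.items()
                if res.label_of()[iid] == c
                for g in ind.genes
                if default_cohort.true_gene_modules.get(g) in modules
            }
            assert expressed <= union


def test_permutation_invariance(default_cohort):
    sub = default_cohort.clusterable()[:120]
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(sub))
    shuffled = [sub[i] for i in perm]
    r1 = hac.cut_dendrogram(
        hac.ward_linkage(hac.jaccard_matrix(sub, exclude={GDD_ANCHOR_TERM})),
        hac.jaccard_matrix(sub, exclude={GDD_ANCHOR_TERM}),
        k=4,
    )
    r2 = hac.cut_dendrogram(
        hac.ward_linkage(hac.jaccard_matrix(shuffled, exclude={GDD_ANCHOR_TERM})),
        hac.jaccard_matrix(shuffled, exclude={GDD_ANCHOR_TERM}),
        k=4,
    )
    l1 = {i: c for i, c in zip(r1.ids, r1.labels)}
    l2 = {i: c for i, c in zip(r2.ids, r2.labels)}
    ids = list(l1)
    assert adjusted_rand_score([l1[i] for i in ids], [l2[i] for i in ids]) == 1.0
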