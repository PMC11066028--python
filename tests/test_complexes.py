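"""Adaptive-thresholding tests: trace bookkeeping, plateau (root) detection
on planted and constructed inputs, the c*d/k score, pairwise F1 against
hand-counted confusion, Fisher enrichment against exact tail enumeration,
and the baseline grids."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.special import comb

from cellfp import complexes
from cellfp.complexes import (
    AdaptiveThresholdClustering,
    ComplexStandard,
    RootCluster,
    find_root_clusters,
    high_confidence_clusters,
    pairwise_f1,
    trace_dendrogram,
)


def blob_scfps(centers, n_per=10, sd=0.02, seed=0):
    """scFPs around archetype centers; protein i gets its own sub-seed."""
    g = np.random.default_rng(seed)
    X, pids = [], []
    for pid, c in centers.items():
        X.append(np.asarray(c) + g.normal(0, sd, size=(n_per, len(c))))
        pids += [pid] * n_per
    return np.vstack(X), np.array(pids)


class TestTrace:
    def test_thresholds_descend_in_steps(self, rng):
        X = rng.normal(size=(12, 5))
        Z = linkage(pdist(X, "correlation"), "average")
        trace = trace_dendrogram(Z, [f"P{i}" for i in range(12)])
        ts = [t for t, _ in trace]
        assert ts == sorted(ts, reverse=True)
        np.testing.assert_allclose(np.diff(ts), -0.05, atol=1e-9)
        assert ts[0] < Z[:, 2].max()  # starts below the final merge

    def test_counts_match_direct_flat_clustering(self, rng):
        X = rng.normal(size=(15, 6))
        ids = np.array([f"P{i % 5}" for i in range(15)])
        Z = linkage(pdist(X, "correlation"), "average")
        trace = trace_dendrogram(Z, ids)
        for t, labels in trace:
            direct = fcluster(Z, t=max(t, 0.0), criterion="distance")
            assert len(np.unique(labels)) == len(np.unique(direct))

    def test_protein_counts_refine_monotonically(self, rng):
        X = rng.normal(size=(20, 6))
        ids = np.array([f"P{i % 4}" for i in range(20)])
        Z = linkage(pdist(X, "correlation"), "average")
        trace = trace_dendrogram(Z, ids)
        # the largest cluster's unique-protein count never grows as the
        # threshold decreases
        counts = []
        for t, labels in trace:
            sizes = [np.sum(labels == u) for u in np.unique(labels)]
            biggest = np.unique(labels)[int(np.argmax(sizes))]
            counts.append(len(set(ids[labels == biggest])))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestRoots:
    def test_two_planted_blobs_two_roots(self):
        X, pids = blob_scfps(
            {"A1": [1, 0, 0, 1], "A2": [1, 0.02, 0, 1],
             "B1": [0, 1, 1, 0], "B2": [0.02, 1, 1, 0]},
            n_per=8,
        )
        Z = linkage(pdist(X, "correlation"), "average")
        trace = trace_dendrogram(Z, pids)
        roots = find_root_clusters(trace, pids)
        assert len(roots) == 2
        assert {frozenset(r.proteins) for r in roots} == {
            frozenset({"A1", "A2"}), frozenset({"B1", "B2"}),
        }
        # disjoint membership
        all_members = np.concatenate([r.members for r in roots])
        assert len(all_members) == len(set(all_members.tolist()))

    def test_unstructured_profiles_yield_no_confident_clusters(self, rng):
        """Unstructured scFPs produce no high-confidence clusters: chance
        plateaus can appear in finite noise, but their cell ratios are far
        too low to survive the c*d/k score cutoff."""
        X = rng.normal(size=(40, 60))
        pids = np.array([f"P{i % 8}" for i in range(40)])
        clus = AdaptiveThresholdClustering().fit(X, pids)
        assert clus.high_confidence_ == []
        assert (clus.labels_ == -1).all()

    def test_plateau_tolerates_small_churn(self):
        """A constructed trace whose branch loses one of twenty proteins
        (5% churn at the protein level is within the 95% plateau rule only
        when Jaccard >= 0.95, i.e. at most ~4% churn)."""
        pids = np.array([f"P{i}" for i in range(25)])
        full = np.zeros(25, dtype=int)
        # level 0: {0..19} vs {20..24}; level 1: {0..19} splits off nothing
        # (stable); deeper: splits in half
        l0 = np.where(np.arange(25) < 20, 1, 2)
        l1 = l0.copy()
        l2 = np.where(np.arange(25) < 10, 1, np.where(np.arange(25) < 20, 3, 2))
        trace = [(0.30, l0), (0.25, l1), (0.20, l2)]
        roots = find_root_clusters(trace, pids)
        # the 20-protein branch divides 10/10 at its first division -> no
        # plateau there; the 5-protein branch never divides -> stable root
        assert {frozenset(r.proteins) for r in roots} == {
            frozenset({f"P{i}" for i in range(20, 25)})
        }

    def test_churn_within_tolerance_accepted(self):
        pids = np.array([f"P{i}" for i in range(25)])
        l0 = np.where(np.arange(25) < 20, 1, 2)
        # the 20-protein cluster sheds exactly one protein: Jaccard 19/20
        l1 = l0.copy()
        l1[19] = 3
        trace = [(0.30, l0), (0.25, l1)]
        roots = find_root_clusters(trace, pids)
        assert frozenset({f"P{i}" for i in range(20)}) in {
            frozenset(r.proteins) for r in roots
        }


class TestScoring:
    def test_score_formula_arithmetic(self):
        root = RootCluster(
            members=np.arange(4), proteins=frozenset({"A", "B"}), elbow_point=0.2,
            cell_ratio=0.9, descendant_ratio=0.8,
        )
        root.score = root.cell_ratio * root.descendant_ratio / root.elbow_point
        assert root.score == pytest.approx(3.6)

    def test_full_capture_score_is_inverse_k(self):
        X, pids = blob_scfps({"A": [1, 0, 0.5, 1], "B": [1, 0.02, 0.5, 1]}, n_per=10)
        clus = AdaptiveThresholdClustering().fit(X, pids)
        root = clus.roots_[0]
        assert root.cell_ratio == pytest.approx(1.0)
        assert root.descendant_ratio == pytest.approx(1.0)
        assert root.score == pytest.approx(1.0 / root.elbow_point)

    def test_high_confidence_filter_and_sorting(self):
        roots = []
        for s in (3.6, 0.59, 0.7):
            r = RootCluster(members=np.arange(2), proteins=frozenset({"A", "B"}),
                            elbow_point=0.1)
            r.score = s
            roots.append(r)
        kept = high_confidence_clusters(roots, cutoff=0.6)
        assert [r.score for r in kept] == [3.6, 0.7]
        assert len(high_confidence_clusters(roots, cutoff=0.0)) == 3
        assert high_confidence_clusters(roots, cutoff=99.0) == []

    def test_tiny_elbow_floored_with_flag(self):
        X, pids = blob_scfps({"A": [1, 0, 0, 1], "B": [1, 0, 0, 1]}, n_per=6, sd=0.0)
        clus = AdaptiveThresholdClustering().fit(X, pids)
        assert all(r.elbow_point >= 0 for r in clus.roots_)
        for r in clus.roots_:
            if r.k_floored:
                assert r.score == pytest.approx(
                    r.cell_ratio * r.descendant_ratio / clus.k_floor
                )


class TestPairwiseF1:
    def test_perfect_clustering_of_planted_complexes(self):
        labels = np.array([0] * 6 + [1] * 6)
        pids = np.array(["A1"] * 3 + ["A2"] * 3 + ["B1"] * 3 + ["B2"] * 3)
        std = ComplexStandard(
            {"C1": frozenset({"A1", "A2"}), "C2": frozenset({"B1", "B2"})},
            min_members=2,
        )
        f1, precision, recall = pairwise_f1(labels, pids, std)
        assert (f1, precision, recall) == (1.0, 1.0, 1.0)

    def test_all_singletons_zero_recall(self):
        labels = -np.ones(8, dtype=int)
        pids = np.array(["A1", "A1", "A2", "A2", "B1", "B1", "B2", "B2"])
        std = ComplexStandard({"C1": frozenset({"A1", "A2"})}, min_members=2)
        f1, precision, recall = pairwise_f1(labels, pids, std)
        assert recall == 0.0 and f1 == 0.0

    def test_hand_counted_confusion(self):
        # cluster 0 = {a1, a1, b1}; cluster 1 = {a2}; truth: a1,a2 in C1
        labels = np.array([0, 0, 0, 1])
        pids = np.array(["a1", "a1", "b1", "a2"])
        std = ComplexStandard(
            {"C1": frozenset({"a1", "a2"}), "C2": frozenset({"b1", "b2"})},
            min_members=1,
        )
        # pairs among annotated scFPs: positives = {a1-a1, a1-a2 x2} = 3
        # predicted positives: within cluster0 pairs = 3 (a1a1, a1b1 x2);
        # true positives among them = 1 (a1-a1)
        f1, precision, recall = pairwise_f1(labels, pids, std)
        assert precision == pytest.approx(1 / 3)
        assert recall == pytest.approx(1 / 3)
        assert f1 == pytest.approx(1 / 3)

    def test_no_positive_pairs_is_error(self):
        # one scFP per annotated protein, different complexes: zero positives
        std = ComplexStandard(
            {"C1": frozenset({"a"}), "C2": frozenset({"b"})}, min_members=1
        )
        with pytest.raises(ValueError):
            pairwise_f1(np.zeros(2, int), np.array(["a", "b"]), std)
        std2 = ComplexStandard({}, min_members=3)
        with pytest.raises(ValueError):
            pairwise_f1(np.zeros(3, int), np.array(["a", "b", "c"]), std2)


class TestFoldEnrichment:
    def test_cluster_equals_complex_fold(self):
        background = {f"P{i}" for i in range(40)}
        cluster = {"P0", "P1", "P2", "P3"}
        std = ComplexStandard({"C1": frozenset(cluster)}, min_members=3)
        cid, fold, p = complexes.fold_enrichment(cluster, std, background)
        assert cid == "C1"
        assert fold == pytest.approx((4 / 4) / (4 / 40))  # = 10

    def test_disjoint_cluster_fold_at_most_one(self):
        background = {f"P{i}" for i in range(30)}
        std = ComplexStandard({"C1": frozenset({"P0", "P1", "P2"})}, min_members=3)
        cid, fold, p = complexes.fold_enrichment({"P10", "P11"}, std, background)
        assert fold <= 1.0

    def test_fisher_p_matches_exact_tail_sum(self):
        # 2x2 table [[3,1],[2,34]]: one-sided (greater) tail of the
        # hypergeometric: drawing k >= 3 of the 5 "marked" in 4 draws from 40
        table = [[3, 1], [2, 34]]
        from scipy.stats import fisher_exact

        _, p_lib = fisher_exact(table, alternative="greater")
        n = 40
        marked = 5
        draws = 4
        tail = sum(
            comb(marked, k, exact=True) * comb(n - marked, draws - k, exact=True)
            for k in range(3, draws + 1)
        ) / comb(n, draws, exact=True)
        assert p_lib == pytest.approx(tail, abs=1e-12)

    def test_empty_background_rejected(self):
        std = ComplexStandard({"C1": frozenset({"a"})}, min_members=1)
        with pytest.raises(ValueError):
            complexes.fold_enrichment({"a"}, std, set())


class TestStandard:
    def test_restriction_to_imaged_members(self):
        std = ComplexStandard(
            {"C1": frozenset({"a", "b", "c", "d"}), "C2": frozenset({"x", "y", "z"})},
            min_members=3,
        )
        r = std.restrict({"a", "b", "c", "x", "y"})
        assert set(r.mapping) == {"C1"}

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "std.tsv"
        path.write_text("complex_id\tprotein_id\nC1\ta\nC1\tb\nC1\tc\n")
        std = ComplexStandard.from_tsv(path)
        assert std.mapping["C1"] == frozenset({"a", "b", "c"})


class TestBaselines:
    def test_kmeans_recovers_well_separated_blobs(self):
        X, pids = blob_scfps(
            {"A1": [1, 0, 0, 1], "A2": [1, 0.02, 0, 1],
             "B1": [0, 1, 1, 0], "B2": [0.02, 1, 1, 0]},
            n_per=8, sd=0.01,
        )
        std = ComplexStandard(
            {"C1": frozenset({"A1", "A2"}), "C2": frozenset({"B1", "B2"})},
            min_members=2,
        )
        # k-means at k = number of planted complexes is essentially perfect
        from sklearn.cluster import KMeans

        direct = KMeans(n_clusters=2, n_init=5, random_state=0).fit_predict(X)
        assert complexes.per_cluster_f1(direct, pids, std).median() > 0.9
        table = complexes.baseline_grid(X, pids, std)
        assert set(table.method) == {"kmeans", "dbscan", "hierarchical"}
        km = table[table.method == "kmeans"].iloc[0]
        # grid values come from the specified ranges
        assert km.param in range(5, 501, 5)
        db = table[table.method == "dbscan"].iloc[0]
        assert round((db.param - 0.1) / 0.1, 6) == int(round((db.param - 0.1) / 0.1))
        hi = table[table.method == "hierarchical"].iloc[0]
        assert hi.param in np.round(np.arange(0.05, 0.501, 0.025), 10)

    def test_adaptive_at_least_matches_best_baseline_on_planted_blobs(self):
        X, pids = blob_scfps(
            {"A1": [1, 0, 0, 1], "A2": [1, 0.03, 0, 1], "A3": [1, 0, 0.03, 1],
             "B1": [0, 1, 1, 0], "B2": [0.03, 1, 1, 0], "B3": [0, 1, 1, 0.03],
             "N1": [1, 1, 0, 0], "N2": [0, 0, 1, 1]},
            n_per=8, sd=0.02,
        )
        std = ComplexStandard(
            {"C1": frozenset({"A1", "A2", "A3"}), "C2": frozenset({"B1", "B2", "B3"})}
        )
        clus = AdaptiveThresholdClustering().fit(X, pids)
        ours = complexes.per_cluster_f1(clus.labels_, pids, std)
        table = complexes.baseline_grid(X, pids, std)
        assert float(ours.median()) >= float(table.median_f1.max()) - 1e-9
        f1, _, _ = pairwise_f1(clus.labels_, pids, std)
        assert f1 >= 0.8
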