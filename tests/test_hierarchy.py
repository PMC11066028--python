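"""Dendrogram analysis tests: linkage against a hand agglomeration, the
AMI-derivative cutoff rule on constructed curves, silhouette arithmetic, and
the embedding outlier filter."""

import numpy as np
import pandas as pd
import pytest

from cellfp import hierarchy


def make_profiles(vectors: dict):
    df = pd.DataFrame.from_dict(vectors, orient="index")
    df.columns = [f"f{i}" for i in range(df.shape[1])]
    df.index.name = "protein_id"
    return df


class TestBuildDendrogram:
    def test_identical_profiles_merge_at_zero(self):
        d = hierarchy.build_dendrogram(
            make_profiles({"A": [1, 2, 3.0], "B": [1, 2, 3.0]})
        )
        assert d.Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_identical_pair_merges_before_anticorrelated(self):
        d = hierarchy.build_dendrogram(
            make_profiles({"A": [1, 2, 3.0], "B": [1, 2, 3.0], "C": [3, 2, 1.0]})
        )
        first = d.Z[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_constant_profile_rejected_by_name(self):
        with pytest.raises(ValueError, match="B"):
            hierarchy.build_dendrogram(make_profiles({"A": [1, 2, 3.0], "B": [5, 5, 5.0]}))

    def test_flat_clusters_match_naive_agglomeration(self, rng):
        """Average-linkage flat clusters agree with a brute-force
        agglomeration implemented directly from the definition."""
        X = rng.normal(size=(10, 6))
        profiles = make_profiles({f"P{i}": X[i] for i in range(10)})
        dend = hierarchy.build_dendrogram(profiles)

        # naive average-linkage on correlation distances
        def corr_dist(u, v):
            return 1 - np.corrcoef(u, v)[0, 1]

        D = {
            frozenset([i]): None for i in range(10)
        }
        clusters = [frozenset([i]) for i in range(10)]
        base = {(i, j): corr_dist(X[i], X[j]) for i in range(10) for j in range(10)}
        merges = []
        while len(clusters) > 1:
            best, pair = None, None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    dist = np.mean(
                        [base[(i, j)] for i in clusters[a] for j in clusters[b]]
                    )
                    if best is None or dist < best:
                        best, pair = dist, (a, b)
            a, b = pair
            merged = clusters[a] | clusters[b]
            merges.append((merged, best))
            clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]

        for h in (0.3, 0.6, 0.9):
            naive = [frozenset([i]) for i in range(10)]
            for merged, dist in merges:
                if dist <= h:
                    naive = [c for c in naive if not c <= merged] + [merged]
            naive_sets = {frozenset(c) for c in naive}
            labels = dend.cut(h)
            lib_sets = {
                frozenset(np.where(labels == u)[0].tolist()) for u in np.unique(labels)
            }
            assert lib_sets == naive_sets

    def test_cut_extremes(self, rng):
        X = rng.normal(size=(8, 5))
        dend = hierarchy.build_dendrogram(make_profiles({f"P{i}": X[i] for i in range(8)}))
        assert len(np.unique(dend.cut(0.0))) == 8  # singletons
        assert len(np.unique(dend.cut(dend.max_height + 0.01))) == 1


class TestDerivativeRule:
    def grid(self):
        return np.round(np.arange(0, 1.001, 0.01), 10)

    def test_rise_then_plateau_selects_plateau_onset(self):
        t = self.grid()
        # scanning down from 1: flat at 0.8 for t <= 0.7, rising above
        ami = np.where(t <= 0.7, 0.8, 0.8 - 2.0 * (t - 0.7))
        chosen, saturated = hierarchy.apply_derivative_rule(t, ami)
        assert saturated
        assert chosen == pytest.approx(0.50, abs=1e-9)  # window fully inside plateau

    def test_constant_curve_selects_first_evaluated_threshold(self):
        t = self.grid()
        chosen, saturated = hierarchy.apply_derivative_rule(t, np.full_like(t, 0.5))
        assert saturated and chosen == pytest.approx(0.80)

    def test_never_saturating_returns_max_ami_with_warning(self):
        t = self.grid()
        ami = 1.0 - t  # constant slope magnitude 1 everywhere
        with pytest.warns(UserWarning):
            chosen, saturated = hierarchy.apply_derivative_rule(t, ami)
        assert not saturated and chosen == pytest.approx(0.0)

    def test_deterministic_and_order_invariant_cutoff(self, rng):
        X = np.vstack(
            [rng.normal(c, 0.05, size=(5, 6)) for c in ([0, 1, 0, 1, 0, 1], [1, 0, 1, 0, 1, 0])]
        )
        names = [f"P{i}" for i in range(10)]
        labels = {n: ("a" if i < 5 else "b") for i, n in enumerate(names)}
        p1 = make_profiles(dict(zip(names, X)))
        perm = rng.permutation(10)
        p2 = p1.iloc[perm]
        r1 = hierarchy.select_cutoff(hierarchy.build_dendrogram(p1), labels)
        r2 = hierarchy.select_cutoff(hierarchy.build_dendrogram(p2), labels)
        assert r1.threshold == r2.threshold


class TestSubcompartment:
    def test_hand_worked_silhouette(self):
        # four profiles, two tight pairs; silhouette computed by hand from
        # the correlation-distance matrix
        X = np.array(
            [[1.0, 2.0, 3.0], [1.0, 2.1, 3.0], [3.0, 2.0, 1.0], [3.0, 1.9, 1.0]]
        )
        labels = np.array([0, 0, 1, 1])

        def cd(u, v):
            return 1 - np.corrcoef(u, v)[0, 1]

        sils = []
        for i in range(4):
            same = [j for j in range(4) if labels[j] == labels[i] and j != i]
            other = [j for j in range(4) if labels[j] != labels[i]]
            a = np.mean([cd(X[i], X[j]) for j in same])
            b = np.mean([cd(X[i], X[j]) for j in other])
            sils.append((b - a) / max(a, b))
        assert hierarchy.silhouette_correlation(X, labels) == pytest.approx(
            np.mean(sils), abs=1e-12
        )

    def test_separated_subgroups_high_silhouette(self, rng):
        group = {}
        for i in range(6):
            group[f"A{i}"] = np.array([1, 2, 3, 4, 5.0]) + rng.normal(0, 0.02, 5)
        for i in range(6):
            group[f"B{i}"] = np.array([5, 3, 1, 4, 2.0]) + rng.normal(0, 0.02, 5)
        clusters, table, best = hierarchy.subcompartment_clusters(
            {"loc": make_profiles(group)}
        )
        assert table.median_silhouette.max() > 0.9
        assert clusters["loc"].nunique() == 2

    def test_single_homogeneous_group_one_cluster(self, rng):
        group = {f"A{i}": np.array([1, 2, 3, 4.0]) + rng.normal(0, 0.01, 4) for i in range(5)}
        clusters, table, best = hierarchy.subcompartment_clusters(
            {"loc": make_profiles(group)}, grid=[0.5]
        )
        assert clusters["loc"].nunique() == 1

    def test_small_group_skipped_with_warning(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                hierarchy.subcompartment_clusters(
                    {"tiny": make_profiles({"A": [1, 2, 3.0], "B": [2, 1, 3.0]})}
                )


class TestEmbedding:
    def test_outlier_filter_exact_on_constructed_cloud(self):
        pts = np.zeros((50, 2))
        pts[:48] = np.random.default_rng(0).normal(0, 1.0, (48, 2))
        pts[48] = [50.0, 0.0]
        pts[49] = [0.0, -60.0]
        keep = hierarchy.filter_2sd_outliers(pts)
        assert not keep[48] and not keep[49]
        v = pts[:, 0]
        expected = np.abs(v - v.mean()) <= 2 * v.std()
        w = pts[:, 1]
        expected &= np.abs(w - w.mean()) <= 2 * w.std()
        np.testing.assert_array_equal(keep, expected)

    def test_identical_profiles_near_coincident_and_kde_normalized(self, rng):
        vectors = {}
        for i in range(20):
            vectors[f"A{i}"] = np.array([1, 0, 2, 1.0]) + rng.normal(0, 0.01, 4)
        for i in range(20):
            vectors[f"B{i}"] = np.array([0, 2, 0, 1.0]) + rng.normal(0, 0.01, 4)
        profiles = make_profiles(vectors)
        labels = {p: p[0] for p in profiles.index}
        coords, densities = hierarchy.embed_annotate(
            profiles, labels, perplexity=5, random_state=0
        )
        assert coords.shape[0] == 40
        # same-group points cluster together relative to the global spread
        a = coords[coords.label == "A"][["tsne1", "tsne2"]].to_numpy()
        spread = np.linalg.norm(coords[["tsne1", "tsne2"]].to_numpy().std(axis=0))
        assert np.linalg.norm(a.std(axis=0)) < spread
        for dens in densities.values():
            dx = dens["x"][1] - dens["x"][0]
            dy = dens["y"][1] - dens["y"][0]
            mass = dens["density"].sum() * dx * dy
            assert mass == pytest.approx(1.0, abs=0.05)

    def test_too_few_points_for_perplexity(self):
        profiles = make_profiles({f"P{i}": np.arange(4.0) + i for i in range(5)})
        with pytest.raises(ValueError, match="perplexity"):
            hierarchy.embed_annotate(profiles, perplexity=40)
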