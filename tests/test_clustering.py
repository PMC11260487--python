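"""k-means partitioning and ward classification against exhaustive oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ribohet.clustering import (
    ClassAssignment,
    LatentEncodings,
    auto_cut,
    class_mean_occupancy,
    hierarchical_cluster,
    kmeans_partition,
    order_heatmap,
    select_representatives,
)
from ribohet.errors import ParameterError
from ribohet.occupancy import occupancy_values
from ribohet.synthetic import delta_yjga_templates, template_matrix


def _matrix(values, counts=None):
    values = np.asarray(values, dtype=float)
    counts = [1] * len(values) if counts is None else counts
    df = pd.DataFrame(values, columns=[f"b{j}" for j in range(values.shape[1])])
    df.insert(0, "particle_count", counts)
    df.insert(0, "volume_id", [f"v{i}" for i in range(len(values))])
    return df


class TestKmeans:
    def test_k_equals_n_singletons(self):
        latent = LatentEncodings(np.arange(5.0)[:, None] * 10)
        part = kmeans_partition(latent, K=5, seed=0)
        assert sorted(part.counts.tolist()) == [1] * 5
        # each representative is the cluster's only member
        for k in range(5):
            member = np.flatnonzero(part.assignment == k)[0]
            assert part.representatives[k] == latent.particle_ids[member]

    def test_two_cluster_exhaustive_bipartition(self):
        # oracle: enumerate the 7 bipartitions of 4 points, minimize within-SS
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        best_cost, best_split = np.inf, None
        for mask in range(1, 8):
            a = pts[[bool(mask >> i & 1) for i in range(4)]]
            b = pts[[not bool(mask >> i & 1) for i in range(4)]]
            cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            if cost < best_cost:
                best_cost, best_split = cost, frozenset(map(float, a))
        assert best_split == frozenset({0.0, 0.1})
        part = kmeans_partition(LatentEncodings(pts), K=2, seed=0)
        groups = {frozenset(pts[part.assignment == k]) for k in range(2)}
        assert groups == {frozenset({0.0, 0.1}), frozenset({10.0, 10.1})}
        np.testing.assert_allclose(sorted(part.centers.ravel()), [0.05, 10.05])

    @pytest.mark.parametrize("trial", range(5))
    def test_four_point_instances_reach_exhaustive_optimum(self, trial):
        rng = np.random.default_rng(trial)
        pts = rng.normal(size=(4, 2)) * 3
        part = kmeans_partition(LatentEncodings(pts), K=2, seed=trial)
        cost = sum(
            ((pts[part.assignment == k] - pts[part.assignment == k].mean(axis=0)) ** 2).sum()
            for k in range(2)
        )
        best = min(
            ((pts[list(s)] - pts[list(s)].mean(axis=0)) ** 2).sum()
            + ((pts[list(c)] - pts[list(c)].mean(axis=0)) ** 2).sum()
            for s, c in (
                (s, tuple(set(range(4)) - set(s)))
                for r in (1, 2)
                for s in itertools.combinations(range(4), r)
            )
        )
        assert cost == pytest.approx(best, abs=1e-9)

    def test_separated_mixture_counts_recovered_exactly(self):
        # 4 well-separated 8-D centers; separation >> noise guarantees recovery
        rng = np.random.default_rng(1)
        centers = np.zeros((4, 8))
        for i in range(4):
            centers[i, i] = 100.0
        idx = rng.integers(0, 4, size=4000)
        latent = LatentEncodings(centers[idx] + rng.normal(0, 1, size=(4000, 8)))
        part = kmeans_partition(latent, K=4, seed=1)
        assert sorted(part.counts.tolist()) == sorted(np.bincount(idx).tolist())

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ParameterError):
            kmeans_partition(LatentEncodings(np.zeros((3, 1))), K=4, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(50, 3))
        a = kmeans_partition(LatentEncodings(vals), K=5, seed=9)
        b = kmeans_partition(LatentEncodings(vals), K=5, seed=9)
        np.testing.assert_array_equal(a.assignment, b.assignment)


class TestRepresentatives:
    def test_tie_broken_by_lowest_id(self):
        latent = LatentEncodings(np.array([[0.0, 0.0], [2.0, 0.0]]))
        part = kmeans_partition(latent, K=1, seed=0)
        assert part.representatives[0] == 0  # both at distance 1 from (1,0)

    def test_singleton_cluster(self):
        latent = LatentEncodings(np.array([[5.0]]))
        part = kmeans_partition(latent, K=1, seed=0)
        assert part.representatives[0] == 0

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(100, 4))
        latent = LatentEncodings(vals)
        part = kmeans_partition(latent, K=1, seed=3)
        d = np.linalg.norm(vals - vals.mean(axis=0), axis=1)
        assert part.representatives[0] == int(np.argmin(d))


def _oracle_ward(points):
    """Greedy agglomeration minimizing the within-cluster variance increase.

    Heights reported on the same scale as scipy (sqrt of twice the ESS
    increase); independent of scipy.cluster.
    """
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = points[clusters[i]], points[clusters[j]]
            na, nb = len(a), len(b)
            delta = (
                na * nb / (na + nb)
                * np.sum((a.mean(axis=0) - b.mean(axis=0)) ** 2)
            )
            if best is None or delta < best[0]:
                best = (delta, i, j)
        delta, i, j = best
        heights.append(np.sqrt(2 * delta))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestHierarchical:
    def test_two_pairs_exhaustive(self):
        matrix = _matrix([[0, 0], [0, 1], [10, 0], [10, 1]])
        classes = hierarchical_cluster(matrix, n_classes=2)
        assert classes.labels[0] == classes.labels[1]
        assert classes.labels[2] == classes.labels[3]
        assert classes.labels[0] != classes.labels[2]

    def test_cut_at_n_gives_singletons(self):
        rng = np.random.default_rng(0)
        matrix = _matrix(rng.normal(size=(6, 3)))
        classes = hierarchical_cluster(matrix, n_classes=6)
        assert sorted(classes.labels) == [1, 2, 3, 4, 5, 6]

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_heights_match_exhaustive_ward(self, n):
        rng = np.random.default_rng(n)
        pts = rng.normal(size=(n, 3))
        classes = hierarchical_cluster(_matrix(pts), n_classes=2)
        np.testing.assert_allclose(
            np.sort(classes.merge_tree[:, 2]), np.sort(_oracle_ward(pts)), rtol=1e-9
        )

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        classes = hierarchical_cluster(_matrix(rng.normal(size=(30, 5))), n_classes=3)
        assert np.all(np.diff(classes.merge_tree[:, 2]) >= -1e-12)

    def test_coarser_cut_merges_exactly_two_classes(self):
        rng = np.random.default_rng(5)
        matrix = _matrix(rng.normal(size=(20, 4)))
        fine = hierarchical_cluster(matrix, n_classes=5)
        coarse = hierarchical_cluster(matrix, n_classes=4)
        # every coarse class is a union of fine classes; exactly one union of two
        merged = 0
        for c in range(1, 5):
            fine_members = set(fine.labels[coarse.labels == c])
            merged += len(fine_members) - 1
        assert merged == 1

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(6)
        vals = np.repeat(rng.normal(size=(4, 3)), 5, axis=0) + rng.normal(
            0, 0.01, size=(20, 3)
        )
        matrix = _matrix(vals)
        perm = rng.permutation(20)
        permuted = _matrix(vals[perm])
        a = hierarchical_cluster(matrix, n_classes=4).labels
        b = hierarchical_cluster(permuted, n_classes=4).labels
        # partitions agree after undoing the permutation, up to label renaming
        mapping = {}
        for la, lb in zip(a[perm], b):
            mapping.setdefault(la, lb)
            assert mapping[la] == lb

    def test_n_classes_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            hierarchical_cluster(_matrix(np.zeros((3, 2))), n_classes=5)

    def test_auto_cut_recovers_planted_count(self):
        # scaled-down planted-structure property: separation >= 6x noise sd
        rng = np.random.default_rng(0)
        templates = rng.uniform(0.1, 0.9, size=(5, 10))
        hits = 0
        for seed in range(1, 21):
            r = np.random.default_rng(seed)
            idx = r.integers(0, 5, size=120)
            rows = np.clip(templates[idx] + r.normal(0, 0.05, size=(120, 10)), 0, 1)
            classes = hierarchical_cluster(_matrix(rows), n_classes="auto")
            hits += classes.n_classes == 5
        assert hits >= 19  # >= 95% of 20 replicates


class TestHeatmapAndMeans:
    def test_identical_rows_adjacent_in_leaf_order(self):
        vals = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0], [9.0, 1.0]])
        matrix = _matrix(vals)
        classes = hierarchical_cluster(matrix, n_classes=3)
        order = list(classes.leaf_order)
        assert abs(order.index(0) - order.index(2)) == 1

    def test_ordered_output_is_permutation(self, tmp_path):
        matrix = template_matrix(delta_yjga_templates(), n_volumes=60, seed=0)
        classes = hierarchical_cluster(matrix, n_classes=5)
        ordered = order_heatmap(matrix, classes, image_path=tmp_path / "h.png")
        assert sorted(ordered["volume_id"]) == sorted(matrix["volume_id"])
        assert (tmp_path / "h.png").stat().st_size > 0

    def test_within_class_similarity_exceeds_between(self):
        matrix = template_matrix(delta_yjga_templates(), n_volumes=120, seed=1)
        classes = hierarchical_cluster(matrix, n_classes=11)
        vals = occupancy_values(matrix)
        d = np.linalg.norm(vals[:, None] - vals[None, :], axis=2)
        same = classes.labels[:, None] == classes.labels[None, :]
        off = ~np.eye(len(vals), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()

    def test_single_member_class_mean_is_row(self):
        vals = np.array([[0.2, 0.4], [0.8, 0.9]])
        matrix = _matrix(vals, counts=[10, 20])
        classes = hierarchical_cluster(matrix, n_classes=2)
        means = class_mean_occupancy(matrix, classes)
        got = means[["b0", "b1"]].to_numpy()
        assert {tuple(r) for r in np.round(got, 9)} == {(0.2, 0.4), (0.8, 0.9)}

    def test_particle_weighted_mean(self):
        vals = np.array([[0.0, 0.0], [1.0, 1.0]])
        matrix = _matrix(vals, counts=[100, 300])
        classes = ClassAssignment(
            labels=np.array([1, 1]),
            n_classes=1,
            merge_tree=np.array([[0.0, 1.0, 1.0, 2.0]]),
        )
        means = class_mean_occupancy(matrix, classes)
        assert means.loc[1, "b0"] == pytest.approx(0.75)

    def test_generator_class_means_close_to_templates(self):
        for seed in (1, 2, 3):
            templates = delta_yjga_templates()
            # enough volumes that even the rarest class keeps >= 20 members
            matrix = template_matrix(templates, n_volumes=1000, noise_sd=0.05, seed=seed)
            classes = hierarchical_cluster(matrix, n_classes=11)
            means = class_mean_occupancy(matrix, classes)
            tvecs = np.array([t.occupancy for t in templates])
            got = means.drop(columns="particle_count").to_numpy()
            # match each planted template to its nearest recovered class mean
            for tv in tvecs:
                err = np.abs(got - tv).max(axis=1).min()
                assert err <= 0.03
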