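"""AV classification: fuzzy C-means, margin rule, pairing, grouping, voting."""

import numpy as np
import pytest

from retivessel import avclass
from retivessel.avclass import (
    FuzzyClusterResult,
    assign_pixels,
    classify_pair,
    compute_features,
    fuzzy_cmeans,
    group_unpaired,
    label_clusters,
    pair_trees,
)


def two_blob_data(rng, n=50, sep=10.0, spread=0.3, d=4):
    a = rng.normal(0, spread, size=(n, d))
    b = rng.normal(0, spread, size=(n, d)) + sep / np.sqrt(d)
    return np.vstack([a, b])


class TestFuzzyCMeans:
    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(0)
        res = fuzzy_cmeans(two_blob_data(rng))
        assert np.abs(res.membership.sum(axis=1) - 1.0).max() < 1e-9

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        res = fuzzy_cmeans(rng.normal(size=(120, 4)))
        diffs = np.diff(res.objective_history)
        assert (diffs <= 1e-8).all()

    def test_separated_clusters_recovered(self):
        rng = np.random.default_rng(2)
        X = two_blob_data(rng, sep=12.0, spread=0.2)
        res = fuzzy_cmeans(X)
        own = np.maximum(res.membership[:, 0], res.membership[:, 1])
        assert (own[:50] > 0.99).all() and (own[50:] > 0.99).all()
        lab = np.argmax(res.membership, axis=1)
        assert len(set(lab[:50])) == 1 and len(set(lab[50:])) == 1
        assert lab[0] != lab[-1]

    def test_equidistant_point_half_membership(self):
        X = np.vstack([
            np.tile([0.0, 0.0], (20, 1)),
            np.tile([2.0, 0.0], (20, 1)),
            [[1.0, 0.0]],
        ])
        res = fuzzy_cmeans(X, standardize=False)
        assert res.membership[-1] == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_identical_points_raise(self):
        with pytest.raises(ValueError):
            fuzzy_cmeans(np.ones((30, 4)))

    def test_deterministic_without_seed(self):
        rng = np.random.default_rng(3)
        X = two_blob_data(rng)
        r1, r2 = fuzzy_cmeans(X), fuzzy_cmeans(X)
        assert np.array_equal(r1.membership, r2.membership)
        assert np.array_equal(r1.centroids, r2.centroids)


def fake_result(membership, mu_g=(200.0, 100.0)):
    membership = np.asarray(membership, float)
    raw = np.zeros((2, 4))
    raw[:, 0] = mu_g
    return FuzzyClusterResult(
        centroids=raw.copy(), raw_centroids=raw, membership=membership,
        objective_history=[0.0], n_iter=1,
    )


class TestMarginRule:
    def test_decisive_membership_assigned(self):
        cls = assign_pixels(fake_result([[0.39, 0.61]]), margin=0.2)
        assert cls.tolist() == [1]

    def test_indeterminate_membership_is_noise(self):
        cls = assign_pixels(fake_result([[0.45, 0.55]]), margin=0.2)
        assert cls.tolist() == [-1]

    def test_certain_membership(self):
        cls = assign_pixels(fake_result([[0.0, 1.0]]), margin=0.2)
        assert cls.tolist() == [1]


class TestClusterLabeling:
    def test_higher_green_is_arterial(self):
        assert label_clusters(fake_result([[1, 0]], mu_g=(0.7, 0.4))) == 0
        assert label_clusters(fake_result([[1, 0]], mu_g=(0.4, 0.7))) == 1

    def test_tie_is_undecidable(self):
        assert label_clusters(fake_result([[1, 0]], mu_g=(0.5, 0.5))) is None


class TestClassifyPair:
    def test_proportions_decide(self):
        a = np.array([0, 0, 0, 0, 1])
        b = np.array([1, 1, 1, 0, 1])
        assert classify_pair(a, b, arterial_cluster=0) == ("artery", "vein")
        assert classify_pair(a, b, arterial_cluster=1) == ("vein", "artery")

    def test_all_noise_tree_is_unknown(self):
        a = np.array([-1, -1])
        b = np.array([0, 1])
        assert classify_pair(a, b, 0) == ("unknown", "unknown")


class TestFeatures:
    def test_constant_window(self):
        green = np.full((9, 9), 100.0)
        hue = np.full((9, 9), 0.25)
        F = compute_features([(4, 4)], green, hue)
        assert F[0] == pytest.approx([100.0, 0.0, 0.25, 0.0])

    def test_mixed_window_population_stdev(self):
        green = np.zeros((5, 5))
        green[1, 1] = 90.0
        F = compute_features([(2, 2)], green, np.zeros((5, 5)))
        assert F[0][0] == pytest.approx(10.0)
        assert F[0][1] == pytest.approx(np.sqrt(((90 - 10) ** 2 + 8 * 100) / 9))

    def test_corner_window_clipped(self):
        green = np.arange(16, dtype=float).reshape(4, 4)
        F = compute_features([(0, 0)], green, np.zeros((4, 4)))
        window = green[:2, :2]
        assert F[0][0] == pytest.approx(window.mean())
        assert F[0][1] == pytest.approx(window.std())


class TestGrouping:
    def test_all_within_threshold_single_group(self):
        cents = {1: (0, 0), 2: (0, 5), 3: (5, 0)}
        assert group_unpaired(cents, threshold_px=10) == [[1, 2, 3]]

    def test_chain_links_transitively(self):
        """A-B close, B-C close, A-C far: still one group."""
        cents = {1: (0, 0), 2: (0, 8), 3: (0, 16)}
        assert group_unpaired(cents, threshold_px=10) == [[1, 2, 3]]

    def test_singleton_merged_into_nearest_group(self):
        cents = {1: (0, 0), 2: (0, 5), 3: (50, 50), 4: (100, 100), 5: (100, 104)}
        groups = group_unpaired(cents, threshold_px=10)
        assert [1, 2, 3] in groups and [4, 5] in groups

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            group_unpaired({1: (0, 0)}, threshold_px=0)


class TestPairTrees:
    def test_crossing_pair_detected(self, default_result):
        pairs, unpaired = pair_trees(
            default_result.labeling, default_result.segment_map
        )
        assert len(pairs) == 1
        a, b, _ = pairs[0]
        assert a != b
        assert set(unpaired) == set(default_result.labeling.roots) - {a, b}


class TestEndToEndLabels:
    def test_crossing_pairs_oppositely_labeled(self, scene_batch):
        for scene, res in scene_batch:
            for a, b, _ in res.pairing.pairs:
                la, lb = res.av.tree_labels[a], res.av.tree_labels[b]
                assert {la, lb} == {"artery", "vein"}

    def test_label_permutation_invariance(self, default_scene):
        """Shifting the generator seed base (hence tree draw order) aside,
        relabeling predicted tree ids must not change AV labels: run the
        classifier twice on the same inputs and compare."""
        from conftest import run_on_scene

        r1 = run_on_scene(default_scene)
        r2 = run_on_scene(default_scene)
        assert r1.av.tree_labels == r2.av.tree_labels

    def test_noise_pixels_are_subset_of_centerlines(self, default_result):
        skel_px = {
            p
            for seg in default_result.segment_map.segments.values()
            for p in seg.path
        }
        assert default_result.av.noise_pixels <= skel_px
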