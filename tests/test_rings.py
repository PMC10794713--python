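"""Contact graphs, triangle enumeration and the packing order parameter."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capsidmorph.rings import (
    RingPose,
    classify_packing,
    detect_contacts,
    find_triplets,
    frame_summary,
    normal_from_points,
    order_parameter,
    triplet_time_series,
)
from capsidmorph.synthetic import TrajectorySpec, gen_ring_trajectory


def random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestOrderParameter:
    def test_orthogonal_packing_is_one(self):
        assert order_parameter((1, 0, 0), (0, 1, 0), (0, 0, 1)) == 1.0

    def test_coplanar_packing_is_zero(self):
        s = np.sqrt(0.5)
        assert order_parameter((1, 0, 0), (s, s, 0), (0, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_half_tilted_triple(self):
        s = np.sqrt(0.5)
        p = order_parameter((1, 0, 0), (0, 1, 0), (0, s, s))
        assert p == pytest.approx(0.7071, abs=5e-5)

    def test_non_unit_input_rejected_unless_normalized(self):
        with pytest.raises(ValueError, match="unit length"):
            order_parameter((2, 0, 0), (0, 1, 0), (0, 0, 1))
        assert order_parameter((2, 0, 0), (0, 1, 0), (0, 0, 1), normalize=True) == 1.0

    def test_permutation_invariance(self, rng):
        for _ in range(200):
            n1, n2, n3 = random_unit(rng, 3)
            p = order_parameter(n1, n2, n3)
            for perm in permutations((n1, n2, n3)):
                assert order_parameter(*perm) == pytest.approx(p, abs=1e-12)

    def test_sign_flip_invariance(self, rng):
        """Ring normals have no preferred direction; p must not care."""
        for _ in range(200):
            n1, n2, n3 = random_unit(rng, 3)
            p = order_parameter(n1, n2, n3)
            for signs in [(-1, 1, 1), (1, -1, 1), (1, 1, -1), (-1, -1, -1)]:
                assert order_parameter(
                    signs[0] * n1, signs[1] * n2, signs[2] * n3
                ) == pytest.approx(p, abs=1e-12)

    def test_rotation_invariance(self, rng):
        """p is a rotation invariant: checked against scipy rotation matrices."""
        for seed in range(100):
            n1, n2, n3 = random_unit(rng, 3)
            p = order_parameter(n1, n2, n3)
            R = Rotation.random(rng=seed).as_matrix()
            assert np.linalg.det(R) == pytest.approx(1.0)
            assert order_parameter(R @ n1, R @ n2, R @ n3) == pytest.approx(p, abs=1e-9)

    def test_bounded_by_hadamard(self, rng):
        for _ in range(2000):
            n1, n2, n3 = random_unit(rng, 3)
            assert 0.0 <= order_parameter(n1, n2, n3) <= 1.0


class TestContacts:
    def make_poses(self, centers):
        return [
            RingPose(ring_id=i, center=tuple(c), normal=(0.0, 0.0, 1.0))
            for i, c in enumerate(centers)
        ]

    def test_close_pair_in_contact(self):
        g = detect_contacts(self.make_poses([(0, 0, 0), (8, 0, 0)]), threshold=12)
        assert g.has_edge(0, 1)

    def test_initial_spacing_gives_no_contacts(self):
        g = detect_contacts(self.make_poses([(0, 0, 0), (16, 0, 0)]), threshold=12)
        assert g.number_of_edges() == 0

    def test_matches_brute_force_all_pairs(self, rng):
        centers = rng.uniform(0, 30, size=(5, 3))
        threshold = 12.0
        g = detect_contacts(self.make_poses(centers), threshold)
        expected = {
            (i, j)
            for i, j in combinations(range(5), 2)
            if np.linalg.norm(centers[i] - centers[j]) <= threshold
        }
        assert {tuple(sorted(e)) for e in g.edges} == expected

    def test_duplicate_ids_rejected(self):
        poses = [
            RingPose(0, (0, 0, 0), (0, 0, 1.0)),
            RingPose(0, (20, 0, 0), (0, 0, 1.0)),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            detect_contacts(poses, 12)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(ValueError, match="unit length"):
            RingPose(0, (0, 0, 0), (0, 0, 2.0))


class TestTriplets:
    def graph(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        return g

    def test_single_triangle(self):
        assert find_triplets(self.graph([(1, 2), (2, 3), (1, 3), (3, 4)])) == [(1, 2, 3)]

    def test_complete_graph_k4(self):
        g = nx.complete_graph(4)
        assert find_triplets(g) == sorted(combinations(range(4), 3))

    def test_path_has_no_triangle(self):
        assert find_triplets(self.graph([(1, 2), (2, 3)])) == []

    @pytest.mark.parametrize("n, p_edge", [(6, 0.5), (9, 0.4), (12, 0.3), (12, 0.7)])
    def test_matches_brute_force_enumeration(self, n, p_edge, rng):
        """Triangle listing agrees with checking every C(n,3) id triple."""
        g = nx.gnp_random_graph(n, p_edge, seed=int(rng.integers(1 << 16)))
        expected = sorted(
            trip
            for trip in combinations(range(n), 3)
            if g.has_edge(trip[0], trip[1])
            and g.has_edge(trip[1], trip[2])
            and g.has_edge(trip[0], trip[2])
        )
        assert find_triplets(g) == expected


class TestTrajectoryAnalysis:
    def test_orthogonal_cluster_round_trip(self):
        spec = TrajectorySpec(cluster_mode="orthogonal", cluster_onset=0.5, n_frames=40, seed=7)
        traj = gen_ring_trajectory(spec)
        records = triplet_time_series(traj, threshold=12.0)
        final = records[records["frame"] == traj["frame"].max()]
        persistent = final[(final["i"] == 0) & (final["j"] == 1) & (final["k"] == 2)]
        assert len(persistent) == 1
        assert persistent["p"].iloc[0] >= 0.9

    def test_planar_cluster_round_trip(self):
        spec = TrajectorySpec(cluster_mode="planar", cluster_onset=0.5, n_frames=40, seed=7)
        traj = gen_ring_trajectory(spec)
        records = triplet_time_series(traj, threshold=12.0)
        after = records[records["frame"] >= 20]
        persistent = after[(after["i"] == 0) & (after["j"] == 1) & (after["k"] == 2)]
        assert len(persistent) > 0
        assert (persistent["p"] <= 0.1).all()

    def test_two_rings_yield_no_records(self):
        spec = TrajectorySpec(n_rings=2, cluster_mode="none", n_frames=5, seed=1)
        records = triplet_time_series(gen_ring_trajectory(spec), threshold=12.0)
        assert len(records) == 0

    def test_frame_summary_counts(self):
        spec = TrajectorySpec(cluster_mode="orthogonal", cluster_onset=0.0, n_frames=3, seed=3)
        summary = frame_summary(gen_ring_trajectory(spec), threshold=12.0)
        assert len(summary) == 3
        assert (summary["n_triplets"] >= 1).all()
        assert (summary["max_p"] >= 0.9).all()

    def test_empty_trajectory_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            triplet_time_series(pd.DataFrame(), threshold=12.0)


class TestClassifyPacking:
    @pytest.mark.parametrize(
        "p, expected", [(1.0, "orthogonal"), (0.0, "planar"), (0.5, "intermediate")]
    )
    def test_default_bands(self, p, expected):
        assert classify_packing(p) == expected

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            classify_packing(1.5)

    def test_bad_band_limits_rejected(self):
        with pytest.raises(ValueError):
            classify_packing(0.5, lo=0.8, hi=0.2)


class TestNormalFromPoints:
    def test_plane_fit_recovers_ring_normal(self, rng):
        theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = np.stack([5 * np.cos(theta), 5 * np.sin(theta), np.zeros(8)], axis=1)
        R = Rotation.random(rng=42).as_matrix()
        n = normal_from_points(ring @ R.T)
        expected = R @ np.array([0.0, 0.0, 1.0])
        assert abs(np.dot(n, expected)) == pytest.approx(1.0, abs=1e-9)
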