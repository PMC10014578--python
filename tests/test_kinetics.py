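"""Clustering kinetics: distances, hulls, speeds and fragment classes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ooclust import (
    classify_fragments,
    clustering_speed,
    convex_hull_volume,
    largest_pairwise_distance,
    mean_distance_to_membrane,
    time_to_complete_clustering,
)
from ooclust.types import ClusterKinetics, LabeledFoci, SurfaceMask

VOX = (1.0, 1.0, 1.0)


def foci_from_points(points, volumes=None, kt=None):
    """Centroid-only foci container (no label map) for geometry tests."""
    points = np.atleast_2d(points)
    n = len(points)
    return LabeledFoci(
        frame=0,
        labels=np.zeros((1, 1, 1), dtype=np.int32),
        centroids=points,
        volumes=np.ones(n) if volumes is None else np.asarray(volumes),
        has_kinetochore=np.zeros(n, bool) if kt is None else np.asarray(kt),
        voxel_size=VOX,
    )


def brute_force_hull_volume(points):
    """O(n³) facet-sum oracle: find hull facets by the all-on-one-side
    test, then sum signed tetrahedron volumes against the centroid."""
    from itertools import combinations

    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    volume = 0.0
    for i, j, k in combinations(range(len(pts)), 3):
        a, b, c = pts[i], pts[j], pts[k]
        n = np.cross(b - a, c - a)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            continue
        side = (pts - a) @ n
        if np.all(side <= 1e-9) or np.all(side >= -1e-9):
            # facet of the hull; orient the normal outward from the centroid
            if (centroid - a) @ n > 0:
                a, b, c = a, c, b
            volume += np.dot(a - centroid, np.cross(b - centroid, c - centroid)) / 6.0
    return abs(volume)


class TestLargestPairwiseDistance:
    def test_three_point_example(self):
        pts = [(0, 0, 0), (3, 4, 0), (0, 0, 1)]
        d = largest_pairwise_distance(foci_from_points(pts), use_vertices=False)
        assert d == pytest.approx(np.sqrt(26), abs=1e-12)

    def test_single_focus_is_zero(self):
        assert largest_pairwise_distance(foci_from_points([(1, 2, 3)])) == 0.0

    def test_axis_separation_equals_distance(self):
        for axis in range(3):
            a = np.zeros(3)
            b = np.zeros(3)
            b[axis] = 7.25
            d = largest_pairwise_distance(
                foci_from_points([a, b]), use_vertices=False
            )
            assert d == pytest.approx(7.25)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 5, (8, 3))
        rot = Rotation.random(random_state=seed).as_matrix()
        d0 = largest_pairwise_distance(foci_from_points(pts), use_vertices=False)
        d1 = largest_pairwise_distance(
            foci_from_points(pts @ rot.T), use_vertices=False
        )
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestConvexHull:
    def test_unit_tetrahedron(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        v = convex_hull_volume(foci_from_points(pts), use_vertices=False)
        assert v == pytest.approx(1 / 6, abs=1e-12)

    def test_cube_of_side_two(self):
        pts = [(z, y, x) for z in (0, 2) for y in (0, 2) for x in (0, 2)]
        v = convex_hull_volume(foci_from_points(pts), use_vertices=False)
        assert v == pytest.approx(8.0, abs=1e-12)

    def test_degenerate_coplanar_set_is_zero(self):
        pts = [(0, y, x) for y in range(3) for x in range(3)]
        assert convex_hull_volume(foci_from_points(pts), use_vertices=False) == 0.0

    def test_random_ball_points_match_facet_sum_oracle(self, rng):
        pts = rng.normal(0, 1, (50, 3))
        pts /= np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1.0)
        v = convex_hull_volume(foci_from_points(pts), use_vertices=False)
        assert v < 4 / 3 * np.pi
        assert v == pytest.approx(brute_force_hull_volume(pts), abs=1e-9)

    def test_all_points_inside_or_on_hull(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.normal(0, 3, (40, 3))
        hull = ConvexHull(pts)
        # every point satisfies all facet inequalities up to tolerance
        ok = (pts @ hull.equations[:, :3].T + hull.equations[:, 3]) <= 1e-9
        assert ok.all()


class TestClusteringSpeed:
    @staticmethod
    def _kin(times, distances):
        n = len(times)
        return ClusterKinetics(
            time_from_nebd=np.asarray(times, float),
            largest_pairwise_distance=np.asarray(distances, float),
            convex_hull_volume=np.zeros(n),
            n_foci=np.full(n, 2),
        )

    def test_porcine_interval_slope(self):
        # linear fall from 20 to 7.1 µm over 30 min ⇒ 0.43 µm/min
        t = np.arange(0, 35, 5.0)
        d = np.linspace(20.0, 7.1, len(t))
        kin = self._kin(t, d)
        assert clustering_speed(kin, (0.0, 30.0)) == pytest.approx(0.43)

    def test_constant_series_gives_zero(self):
        kin = self._kin([0, 5, 10, 15], [9.0] * 4)
        assert clustering_speed(kin, (0.0, 15.0)) == 0.0

    @pytest.mark.parametrize("phase", [0.0, 1.0, 1.7])
    def test_phase_invariance_of_linear_series(self, phase):
        t = phase + np.arange(0, 20, 2.0)
        d = 30.0 - 0.5 * t
        kin = self._kin(t, d)
        assert clustering_speed(kin, (phase, phase + 18)) == pytest.approx(0.5)

    def test_insufficient_frames_raises(self):
        kin = self._kin([0, 40], [10, 5])
        with pytest.raises(ValueError, match="insufficient"):
            clustering_speed(kin, (0.0, 30.0))

    def test_slope_method_agrees_on_linear_series(self):
        t = np.arange(0, 30, 5.0)
        kin = self._kin(t, 25.0 - 0.43 * t)
        assert clustering_speed(kin, (0, 30), method="slope") == pytest.approx(0.43)


class TestTimeToCompleteClustering:
    def test_first_single_focus_frame(self):
        out = time_to_complete_clustering([3, 2, 1, 1], [0, 10, 20, 30])
        assert out.clustered and out.time_min == 20.0 and not out.non_monotone

    def test_never_single_reports_not_clustered(self):
        out = time_to_complete_clustering([2, 2, 2], [0, 10, 20])
        assert not out.clustered and out.time_min is None

    def test_recurrence_flags_non_monotone(self):
        out = time_to_complete_clustering([3, 1, 2, 1], [0, 10, 20, 30])
        assert out.clustered and out.time_min == 10.0 and out.non_monotone

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            time_to_complete_clustering([], [])


class TestFragmentClasses:
    @pytest.mark.parametrize(
        "volume,kt,expected",
        [
            (10.0, False, "small_KT_free"),
            (30.0, False, "large_KT_free"),  # boundary is inclusive-large
            (50.0, True, "large_KT"),
            (29.99, True, "small_KT"),
        ],
    )
    def test_class_assignment(self, volume, kt, expected):
        foci = foci_from_points([(0, 0, 0)], volumes=[volume], kt=[kt])
        assert classify_fragments(foci) == [expected]


class TestMembraneDistance:
    @staticmethod
    def _shell_mask(radius_vox=15, shape=(41, 41, 41)):
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        c = (np.array(shape) - 1) / 2
        r = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        return np.abs(r - radius_vox) < 0.5

    def test_centre_of_shell_reads_shell_radius(self):
        mask = self._shell_mask()
        surf = SurfaceMask(mask=mask, voxel_size=(1.0, 1.0, 1.0))
        foci = foci_from_points([(20.0, 20.0, 20.0)])
        assert mean_distance_to_membrane(foci, surf) == pytest.approx(15.0, abs=1.0)

    def test_focus_on_membrane_is_zero(self):
        mask = self._shell_mask()
        surf = SurfaceMask(mask=mask, voxel_size=(1.0, 1.0, 1.0))
        z, y, x = np.argwhere(mask)[0]
        foci = foci_from_points([(float(z), float(y), float(x))])
        assert mean_distance_to_membrane(foci, surf) == 0.0

    def test_matches_brute_force_voxel_search(self, rng):
        mask = self._shell_mask(radius_vox=12, shape=(33, 33, 33))
        vox = (1.0, 0.8, 0.8)
        surf = SurfaceMask(mask=mask, voxel_size=vox)
        pts = rng.uniform(8, 20, (10, 3)) * np.asarray(vox)
        surf_pts = np.argwhere(mask) * np.asarray(vox)
        half_diag = np.linalg.norm(vox) / 2
        for p in pts:
            foci = foci_from_points([p])
            got = mean_distance_to_membrane(foci, surf)
            brute = np.min(np.linalg.norm(surf_pts - p, axis=1))
            assert got == pytest.approx(brute, abs=half_diag)

    def test_empty_membrane_raises(self):
        surf = SurfaceMask(mask=np.zeros((4, 4, 4), bool), voxel_size=VOX)
        with pytest.raises(ValueError):
            mean_distance_to_membrane(foci_from_points([(1, 1, 1)]), surf)
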