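"""Colocalization: spot–surface distances, mirrored control, ROI tools."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ooclust import (
    actin_intensity_near_chromosomes,
    expected_random_overlap,
    generate_kinetochore_actin_volume,
    interaction_fraction,
    mirrored_control,
    roi_crop,
    segment_surface,
    shortest_distance_spot_surface,
)
from ooclust.types import SpotSet, SurfaceMask

VOX = (0.5, 0.5, 0.5)


def _plane_surface(shape=(32, 32, 32), z_plane=10):
    mask = np.zeros(shape, dtype=bool)
    mask[z_plane] = True
    return SurfaceMask(mask=mask, voxel_size=VOX)


class TestShortestDistance:
    def test_spot_inside_surface_is_zero(self):
        surf = _plane_surface()
        spots = SpotSet(points=np.array([[10 * VOX[0], 4.0, 4.0]]))
        d = shortest_distance_spot_surface(spots, surf)
        assert d.distances[0] == 0.0

    def test_spot_three_microns_from_plane(self):
        surf = _plane_surface()
        spots = SpotSet(points=np.array([[10 * VOX[0] + 3.0, 4.0, 4.0]]))
        d = shortest_distance_spot_surface(spots, surf)
        half_diag = np.linalg.norm(VOX) / 2
        assert d.distances[0] == pytest.approx(3.0, abs=half_diag)

    def test_matches_brute_force_voxel_search(self, rng):
        mask = rng.random((24, 24, 24)) > 0.995
        mask[12, 12, 12] = True
        surf = SurfaceMask(mask=mask, voxel_size=VOX)
        spots = SpotSet(points=rng.uniform(0, 11.5, (50, 3)))
        d = shortest_distance_spot_surface(spots, surf).distances
        surf_pts = np.argwhere(mask) * np.asarray(VOX)
        half_diag = np.linalg.norm(VOX) / 2
        for p, got in zip(spots.points, d):
            brute = np.min(np.linalg.norm(surf_pts - p, axis=1))
            assert got == pytest.approx(brute, abs=half_diag)

    def test_empty_surface_raises(self):
        surf = SurfaceMask(mask=np.zeros((4, 4, 4), bool), voxel_size=VOX)
        with pytest.raises(ValueError):
            shortest_distance_spot_surface(SpotSet(points=np.ones((1, 3))), surf)


class TestMirroredControl:
    def test_double_mirror_is_identity(self, rng):
        spots = SpotSet(points=rng.uniform(0, 10, (20, 3)))
        extent = 15.5
        twice = mirrored_control(mirrored_control(spots, extent), extent)
        assert np.allclose(twice.points, spots.points)

    def test_spot_on_mirror_plane_unchanged(self):
        extent = 10.0
        spots = SpotSet(points=np.array([[1.0, 2.0, 5.0]]))
        assert mirrored_control(spots, extent).points[0, 2] == 5.0

    def test_mirroring_breaks_programmed_colocalization(self):
        series, gt = generate_kinetochore_actin_volume(
            seed=5, contact_prob=0.8, n_spots=30
        )
        surf = segment_surface(series.channel("actin", 0), series.voxel_size)
        spots = SpotSet(points=gt.spot_points)
        extent = (series.data.shape[-1] - 1) * series.voxel_size[2]
        real = shortest_distance_spot_surface(spots, surf).distances
        mirrored = shortest_distance_spot_surface(
            mirrored_control(spots, extent), surf
        ).distances
        assert np.median(mirrored) > np.median(real)


class TestRoiCrop:
    def test_stated_size_crops_exactly(self):
        vol = np.zeros((40, 40, 40))
        crop, origin = roi_crop(vol, VOX, size_um=(10.0, 10.0, 10.0), origin_um=(2.0, 2.0, 2.0))
        assert crop.shape == (20, 20, 20)
        assert origin == (4, 4, 4)

    def test_roi_overlapping_border_raises(self):
        with pytest.raises(ValueError):
            roi_crop(np.zeros((40, 40, 40)), VOX, (10.0, 10.0, 10.0), origin_um=(18.0, 2.0, 2.0))

    def test_automatic_placement_avoids_nucleus_mask(self):
        vol = np.zeros((48, 48, 48))
        nucleus = np.zeros_like(vol, dtype=bool)
        nucleus[:, :24, :24] = True
        crop, origin = roi_crop(vol, VOX, (8.0, 8.0, 8.0), exclude_mask=nucleus)
        size = np.array(crop.shape)
        region = np.zeros_like(nucleus)
        region[
            origin[0] : origin[0] + size[0],
            origin[1] : origin[1] + size[1],
            origin[2] : origin[2] + size[2],
        ] = True
        assert not (region & nucleus).any()


class TestInteractionFraction:
    def test_all_spots_inside_surface(self):
        surf = _plane_surface()
        pts = np.column_stack(
            [np.full(5, 10 * VOX[0]), np.linspace(1, 10, 5), np.linspace(1, 10, 5)]
        )
        assert interaction_fraction(SpotSet(points=pts), surf, cutoff=0.25) == 1.0

    def test_zero_cutoff_with_outside_spots(self):
        surf = _plane_surface()
        pts = np.array([[10 * VOX[0] + 2.0, 3.0, 3.0]])
        assert interaction_fraction(SpotSet(points=pts), surf, cutoff=0.0) == 0.0

    def test_programmed_contact_probability_recovered(self):
        fracs = []
        for seed in range(1, 11):
            series, gt = generate_kinetochore_actin_volume(
                seed=seed, contact_prob=0.18, n_spots=40
            )
            surf = segment_surface(series.channel("actin", 0), series.voxel_size)
            spots = SpotSet(points=gt.spot_points)
            fracs.append(interaction_fraction(spots, surf, cutoff=0.25))
        n = 40 * 10
        sd = np.sqrt(0.18 * 0.82 / n)
        assert abs(np.mean(fracs) - 0.18) < 4 * sd

    def test_empty_spot_set_raises(self):
        with pytest.raises(ValueError):
            interaction_fraction(SpotSet(points=np.empty((0, 3))), _plane_surface())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 1000))
    def test_fraction_non_decreasing_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        surf = _plane_surface()
        spots = SpotSet(points=rng.uniform(0, 15, (20, 3)))
        f = [
            interaction_fraction(spots, surf, cutoff=c) for c in (0.0, 0.5, 2.0, 8.0)
        ]
        assert all(a <= b for a, b in zip(f, f[1:]))

    def test_mirror_invariance_of_fraction(self, rng):
        mask = rng.random((20, 20, 20)) > 0.99
        mask[5, 5, 5] = True
        surf = SurfaceMask(mask=mask, voxel_size=VOX)
        spots = SpotSet(points=rng.uniform(0, 9.0, (30, 3)))
        f = interaction_fraction(spots, surf, cutoff=1.0)
        surf_m = SurfaceMask(mask=mask[:, :, ::-1].copy(), voxel_size=VOX)
        extent = (mask.shape[2] - 1) * VOX[2]
        f_m = interaction_fraction(mirrored_control(spots, extent), surf_m, cutoff=1.0)
        assert f == f_m


class TestExpectedRandomOverlap:
    def test_product_rule(self):
        assert expected_random_overlap(0.18, 0.50) == pytest.approx(0.09)
        assert expected_random_overlap(0.7, 0.0) == 0.0
        assert expected_random_overlap(1.0, 1.0) == 1.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            expected_random_overlap(1.2, 0.5)


class TestActinIntensity:
    def test_background_subtraction(self):
        img = np.full((40, 40), 20.0)
        img[5:15, 5:15] = 100.0
        value, clamped = actin_intensity_near_chromosomes(
            img, (slice(5, 15), slice(5, 15)), (slice(25, 35), slice(25, 35))
        )
        assert value == pytest.approx(80.0)
        assert not clamped

    def test_identical_texture_is_near_zero(self, rng):
        img = rng.normal(50, 3, (40, 40))
        value, _ = actin_intensity_near_chromosomes(
            img, (slice(0, 10), slice(0, 10)), (slice(20, 30), slice(20, 30))
        )
        assert abs(value) < 3.0 or value == 0.0

    def test_programmed_amplitude_recovered_without_noise(self):
        amp = 37.0
        img = np.full((60, 60), 12.0)
        img[10:25, 10:25] += amp
        value, _ = actin_intensity_near_chromosomes(
            img, (slice(10, 25), slice(10, 25)), (slice(40, 55), slice(40, 55))
        )
        assert value == pytest.approx(amp, rel=0.05)

    def test_overlapping_rois_raise(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError, match="overlap"):
            actin_intensity_near_chromosomes(
                img, (slice(0, 10), slice(0, 10)), (slice(5, 15), slice(5, 15))
            )
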