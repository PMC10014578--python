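"""Flow analysis: stabilization, multipass PIV and circular statistics."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from ooclust import (
    OocyteScenario,
    circular_stats,
    classify_directions,
    generate_flow_frames,
    piv_multipass,
    stabilize_translation,
)
from ooclust.types import VelocityField, VolumeSeries


def _flow_scenario(**kw):
    base = dict(
        cell_radius=28.0,
        nucleus_radius=20.0,
        frame_interval=0.5,
        noise_gaussian_sd=0.0,
        noise_poisson_scale=0.0,
        seed=3,
    )
    base.update(kw)
    return OocyteScenario(**base)


class TestStabilization:
    def test_programmed_shift_recovered(self):
        series, _ = generate_flow_frames(
            _flow_scenario(noise_gaussian_sd=1.0), n_frames=2
        )
        data = series.data.copy()
        for c in range(data.shape[1]):
            data[1, c, 0] = ndi.shift(data[1, c, 0], (3.0, -2.0), order=1, mode="nearest")
        shifted = VolumeSeries(data, series.channels, series.voxel_size, series.frame_interval)
        _, shifts = stabilize_translation(shifted, "lamina")
        assert np.allclose(shifts[1], (-3.0, 2.0), atol=0.2)

    def test_identical_frames_give_zero_shift(self):
        series, _ = generate_flow_frames(_flow_scenario(), n_frames=1)
        data = np.repeat(series.data, 2, axis=0)
        twin = VolumeSeries(data, series.channels, series.voxel_size, series.frame_interval)
        _, shifts = stabilize_translation(twin, "lamina")
        assert np.allclose(shifts, 0.0, atol=0.05)

    def test_stabilization_reduces_frame_to_frame_residual(self):
        series, _ = generate_flow_frames(_flow_scenario(seed=9), n_frames=2)
        data = series.data.copy()
        for c in range(data.shape[1]):
            data[1, c, 0] = ndi.shift(data[1, c, 0], (4.0, 1.0), order=1, mode="nearest")
        shifted = VolumeSeries(data, series.channels, series.voxel_size, series.frame_interval)
        stab, _ = stabilize_translation(shifted, "lamina")

        def rms(s):
            a = np.asarray(s.channel("lamina", 0)[0], float)
            b = np.asarray(s.channel("lamina", 1)[0], float)
            return np.sqrt(np.mean((a - b) ** 2))

        assert rms(stab) < rms(shifted)

    def test_featureless_reference_warns_identity(self):
        data = np.zeros((2, 1, 1, 96, 96), dtype=np.float32)
        flat = VolumeSeries(data, ("lamina",), (1.0, 0.5, 0.5), 1.0)
        with pytest.warns(UserWarning, match="featureless"):
            _, shifts = stabilize_translation(flat, "lamina")
        assert np.allclose(shifts, 0.0)


class TestPiv:
    def test_uniform_translation_within_tolerance(self):
        series, _ = generate_flow_frames(
            _flow_scenario(), n_frames=2, uniform_shift_px=(2.0, 3.0)
        )
        px = series.voxel_size[2]
        fld = piv_multipass(
            series.channel("actin", 0)[0],
            series.channel("actin", 1)[0],
            px,
            series.frame_interval,
        )
        v_px = fld.vectors * series.frame_interval / px
        assert fld.valid.any()
        assert np.allclose(v_px[fld.valid], (2.0, 3.0), atol=0.2)

    def test_identical_frames_give_zero_field(self):
        series, _ = generate_flow_frames(_flow_scenario(), n_frames=1)
        a = np.asarray(series.channel("actin", 0)[0], float)
        fld = piv_multipass(a, a, 1.0, 1.0)
        assert np.allclose(fld.vectors[fld.valid], 0.0, atol=0.1)

    def test_solid_body_rotation_matches_analytic_field(self, rng):
        a = ndi.gaussian_filter(rng.normal(0, 1, (256, 256)), 2) * 50 + 100
        b = ndi.rotate(a, 1.0, reshape=False, order=3)
        fld = piv_multipass(a, b, 1.0, 1.0)
        c = (np.array(a.shape) - 1) / 2
        pos = fld.positions - c
        omega = np.deg2rad(1.0)
        expected = np.stack([-pos[:, 1] * omega, pos[:, 0] * omega], axis=1)
        r = np.hypot(pos[:, 0], pos[:, 1])
        sel = fld.valid & (r < a.shape[0] / 2 - 30)
        assert np.abs(fld.vectors[sel] - expected[sel]).max() < 0.3

    def test_frames_smaller_than_largest_window_raise(self):
        with pytest.raises(ValueError, match="smaller than"):
            piv_multipass(np.zeros((32, 32)), np.zeros((32, 32)), 1.0, 1.0)


class TestDirectionClassification:
    def test_all_inward_vectors(self, rng):
        pos = rng.uniform(10, 90, (500, 2))
        to_c = np.array([50.0, 50.0]) - pos
        u = to_c / np.linalg.norm(to_c, axis=1, keepdims=True)
        fld = VelocityField(pos, 3.0 * u, np.ones(500, bool))
        s = classify_directions(fld, (50.0, 50.0))
        assert s.category_fractions["inward"] == 1.0
        assert s.mean_direction == pytest.approx(0.0, abs=1e-6)

    def test_isotropic_field_matches_sector_binomial(self, rng):
        n = 10_000
        pos = rng.uniform(0, 100, (n, 2))
        ang = rng.uniform(0, 2 * np.pi, n)
        vec = 3.0 * np.stack([np.sin(ang), np.cos(ang)], axis=1)
        fld = VelocityField(pos, vec, np.ones(n, bool))
        s = classify_directions(fld, (50.0, 50.0))
        p = 120.0 / 360.0
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(s.category_fractions["inward"] - p) < 3 * sd
        assert sum(s.category_fractions.values()) == pytest.approx(1.0)

    def test_all_below_speed_floor_is_empty(self, rng):
        pos = rng.uniform(0, 50, (100, 2))
        fld = VelocityField(pos, 0.1 * np.ones((100, 2)), np.ones(100, bool))
        s = classify_directions(fld, (25.0, 25.0), speed_floor=1.8)
        assert s.empty and s.n_vectors == 0

    def test_rotation_equivariance_of_mean_direction(self, rng):
        pos = rng.uniform(10, 90, (800, 2))
        ang = rng.vonmises(np.deg2rad(40), 2.0, 800)
        vec = 3.0 * np.stack([np.sin(ang), np.cos(ang)], axis=1)
        centre = np.array([50.0, 50.0])
        fld = VelocityField(pos, vec, np.ones(800, bool))
        s0 = classify_directions(fld, tuple(centre))
        # rotate positions and vectors about the centre by 90 degrees
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        fld_r = VelocityField(
            (pos - centre) @ rot.T + centre, vec @ rot.T, np.ones(800, bool)
        )
        s1 = classify_directions(fld_r, tuple(centre))
        dev = (s1.mean_direction - s0.mean_direction + 180) % 360 - 180
        assert abs(dev) < 1.0


class TestCircularStats:
    def test_two_identical_angles(self):
        m, _, r = circular_stats(np.array([10.0, 10.0]))
        assert m == pytest.approx(10.0)
        assert r == pytest.approx(1.0)

    def test_antipodal_pair_is_undefined(self):
        m, ci, r = circular_stats(np.array([0.0, 180.0]))
        assert np.isnan(m)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert ci == (0.0, 360.0)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            circular_stats(np.array([]))

    def test_von_mises_ci_coverage(self):
        from scipy.stats import vonmises

        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            sample = np.rad2deg(
                vonmises.rvs(2.0, loc=np.deg2rad(30.0), size=1000, random_state=rep)
            )
            m, (lo, hi), _ = circular_stats(sample, seed=rep)
            half = (hi - m) % 360.0
            dev = abs((30.0 - m + 180.0) % 360.0 - 180.0)
            covered += dev <= half
        assert covered >= 93


class TestInwardBiasRecovery:
    def test_generative_inward_excess_recovered(self):
        # inward probability f = 0.7 plus isotropic remainder ⇒ expected
        # inward-classified fraction f + (1 − f)/3 = 0.8
        from ooclust import segment_lamina_contour

        fracs = []
        for seed in range(1, 11):
            s = _flow_scenario(
                seed=seed, actin_inward_fraction=0.7, noise_gaussian_sd=4.0,
                noise_poisson_scale=0.05,
            )
            series, _ = generate_flow_frames(s, n_frames=3)
            px = series.voxel_size[2]
            contour = segment_lamina_contour(
                np.asarray(series.channel("lamina", 0)[0], float), px, expansion=1.5
            )
            inward = []
            for t in range(2):
                fld = piv_multipass(
                    series.channel("actin", t)[0],
                    series.channel("actin", t + 1)[0],
                    px,
                    series.frame_interval,
                )
                summ = classify_directions(
                    fld, contour.centre_of_mass, contour, speed_floor=1.8
                )
                inward.append(summ.category_fractions["inward"])
            fracs.append(np.mean(inward))
        assert abs(np.mean(fracs) - 0.8) < 0.1
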