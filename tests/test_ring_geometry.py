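"""Helical axis fitting and lattice parameter estimation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ringstat.ring_geometry import (
    AnchorSet,
    AxisFitError,
    HelicalParams,
    HelixAxis,
    compare_lattices,
    extract_anchors,
    fit_axis,
    helical_parameters,
)
from ringstat.synthetic import RingSpec, make_ring


def _params_for(spec: RingSpec) -> HelicalParams:
    model, truth = make_ring(spec)
    anchors = extract_anchors(model, truth.chain_ids, 12, "CA")
    return helical_parameters(anchors, fit_axis(anchors))


class TestFitAxis:
    def test_planar_octagon_axis_is_z(self):
        theta = np.radians(45.0 * np.arange(8))
        pts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta), np.zeros(8)])
        axis = fit_axis(AnchorSet(points=pts))
        assert abs(abs(axis.d[2]) - 1.0) < 1e-6
        assert np.linalg.norm(axis.o[:2]) < 1e-6

    def test_noise_free_helix_axis_recovered(self):
        spec = RingSpec(radius=102.5, twist=27.6, rise=9.2, seed=0)
        model, truth = make_ring(spec)
        anchors = extract_anchors(model, truth.chain_ids, 12, "CA")
        axis = fit_axis(anchors)
        assert abs(np.dot(axis.d, truth.axis_direction)) > 1.0 - 1e-8
        # origin lies on the true axis (z-axis): zero in-plane offset
        offset = axis.o - np.dot(axis.o, truth.axis_direction) * truth.axis_direction
        assert np.linalg.norm(offset) < 1e-6

    def test_noisy_axis_direction_median_error_below_one_degree(self):
        errors = []
        for seed in range(100):
            model, truth = make_ring(RingSpec(noise_sd=0.5, seed=seed))
            anchors = extract_anchors(model, truth.chain_ids, 12, "CA")
            axis = fit_axis(anchors)
            cosang = abs(np.dot(axis.d, truth.axis_direction))
            errors.append(np.degrees(np.arccos(min(cosang, 1.0))))
        assert np.median(errors) < 1.0

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(6), [1.0, 0.0, 0.0])
        with pytest.raises(AxisFitError):
            fit_axis(AnchorSet(points=pts))

    def test_too_few_points_rejected(self):
        with pytest.raises(AxisFitError):
            fit_axis(AnchorSet(points=np.eye(3)))


class TestHelicalParameters:
    def test_planar_octagon_params(self):
        theta = np.radians(45.0 * np.arange(8))
        pts = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta), np.zeros(8)])
        anchors = AnchorSet(points=pts)
        p = helical_parameters(anchors, fit_axis(anchors))
        assert p.radius_mean == pytest.approx(50.0, abs=1e-6)
        assert p.twist_mean == pytest.approx(45.0, abs=1e-6)
        assert p.rise_mean == pytest.approx(0.0, abs=1e-6)
        assert max(p.radius_sd, p.twist_sd, p.rise_sd) < 1e-6

    def test_noise_free_ring_recovers_spec_exactly(self):
        p = _params_for(RingSpec(radius=102.5, twist=27.6, rise=9.2, seed=0))
        assert p.radius_mean == pytest.approx(102.5, abs=1e-6)
        assert p.twist_mean == pytest.approx(27.6, abs=1e-6)
        assert p.rise_mean == pytest.approx(9.2, abs=1e-6)
        assert max(p.radius_sd, p.twist_sd, p.rise_sd) < 1e-6
        assert p.n_steps == 13  # 14 anchors define 13 steps

    @pytest.mark.parametrize("radius", [20.0, 102.5, 150.0])
    @pytest.mark.parametrize("twist", [10.0, 27.6, 40.0])
    @pytest.mark.parametrize("rise", [0.0, 9.2, 15.0])
    @pytest.mark.parametrize("n", [5, 14, 20])
    def test_parameter_recovery_grid(self, radius, twist, rise, n):
        p = _params_for(RingSpec(n_spokes=n, radius=radius, twist=twist, rise=rise, seed=0))
        assert p.radius_mean == pytest.approx(radius, abs=1e-5)
        assert p.twist_mean == pytest.approx(twist, abs=1e-5)
        assert p.rise_mean == pytest.approx(rise, abs=1e-5)
        assert max(p.radius_sd, p.twist_sd, p.rise_sd) < 1e-6

    def test_rigid_motion_invariance(self):
        base = RingSpec(seed=0)
        p0 = _params_for(base)
        rng = np.random.default_rng(42)
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-200, 200, size=3)
            p = _params_for(RingSpec(seed=0, pose=(R, t)))
            assert p.radius_mean == pytest.approx(p0.radius_mean, abs=1e-6)
            assert p.twist_mean == pytest.approx(p0.twist_mean, abs=1e-6)
            assert p.rise_mean == pytest.approx(p0.rise_mean, abs=1e-6)
            assert p.handedness == p0.handedness

    def test_mirror_flips_handedness_keeps_magnitudes(self):
        model, truth = make_ring(RingSpec(seed=0))
        anchors = AnchorSet(points=truth.anchors)
        p = helical_parameters(anchors, fit_axis(anchors))
        mirrored = AnchorSet(points=truth.anchors * np.array([-1.0, 1.0, 1.0]))
        pm = helical_parameters(mirrored, fit_axis(mirrored))
        assert pm.handedness != p.handedness
        assert pm.radius_mean == pytest.approx(p.radius_mean, abs=1e-6)
        assert pm.twist_mean == pytest.approx(p.twist_mean, abs=1e-6)
        assert pm.rise_mean == pytest.approx(p.rise_mean, abs=1e-6)

    def test_twist_sum_equals_total_angular_span(self):
        # 14 anchors at 27.6 deg/step span 13 steps = 358.8 deg; a 15th
        # spoke would overshoot the full turn (lockwasher geometry)
        p = _params_for(RingSpec(seed=0))
        assert p.twist_mean * p.n_steps == pytest.approx(358.8, abs=1e-6)
        assert p.twist_mean * (p.n_steps + 1) > 360.0

    def test_noisy_twist_mean_absolute_error(self):
        errors = []
        for seed in range(100):
            p = _params_for(RingSpec(noise_sd=0.5, seed=seed))
            errors.append(abs(p.twist_mean - 27.6))
        assert np.mean(errors) < 0.5


class TestExtractAnchors:
    def test_anchors_match_generator_positions(self):
        model, truth = make_ring(RingSpec(seed=3))
        anchors = extract_anchors(model, truth.chain_ids, 12, "CA")
        assert np.allclose(anchors.points, truth.anchors, atol=1e-3)
        assert [c for _, c in anchors.labels] == truth.chain_ids

    def test_single_chain_anchor_is_atom_position(self):
        model, truth = make_ring(RingSpec(seed=3))
        anchors = extract_anchors(model, truth.chain_ids[:1], 12, "CA")
        assert len(anchors) == 1
        assert np.allclose(anchors.points[0], model.atoms[0].position)

    def test_missing_anchor_names_chain_and_residue(self):
        model, truth = make_ring(RingSpec(seed=3))
        with pytest.raises(ValueError, match="chain 'A' residue 99"):
            extract_anchors(model, ["A"], 99, "CA")

    def test_chain_order_defines_spoke_order(self):
        model, truth = make_ring(RingSpec(seed=3))
        fwd = extract_anchors(model, truth.chain_ids, 12, "CA")
        rev = extract_anchors(model, truth.chain_ids[::-1], 12, "CA")
        assert np.allclose(rev.points, fwd.points[::-1])


class TestCompareLattices:
    def _p(self, r, rsd, t, tsd, z, zsd):
        return HelicalParams(14, r, rsd, t, tsd, z, zsd)

    def test_identical_params_compatible(self):
        p = self._p(102.5, 1.5, 27.6, 0.7, 9.2, 0.8)
        c = compare_lattices(p, p)
        assert (c.radius_diff, c.twist_diff, c.rise_diff) == (0.0, 0.0, 0.0)
        assert c.compatible

    def test_printed_ring_vs_mt_lattice_compatible(self):
        # ring 102.5±1.5 / 27.6±0.7 / 9.2±0.8 against MT 101.8±0.1 /
        # 27.6±0.0 / 9.6±0.1: differences 0.7 A, 0.0 deg, 0.4 A, all within
        # the summed SDs
        ring = self._p(102.5, 1.5, 27.6, 0.7, 9.2, 0.8)
        mt = self._p(101.8, 0.1, 27.6, 0.0, 9.6, 0.1)
        c = compare_lattices(ring, mt)
        assert c.radius_diff == pytest.approx(0.7)
        assert c.twist_diff == pytest.approx(0.0)
        assert c.rise_diff == pytest.approx(0.4)
        assert c.compatible

    def test_shifted_twist_incompatible(self):
        ring = self._p(102.5, 1.5, 27.6, 0.7, 9.2, 0.8)
        shifted = self._p(102.5, 1.5, 32.6, 0.7, 9.2, 0.8)
        c = compare_lattices(shifted, ring)
        assert c.twist_diff == pytest.approx(5.0)
        assert not c.compatible


class TestValidation:
    def test_axis_must_be_unit(self):
        with pytest.raises(ValueError):
            HelixAxis(origin=(0, 0, 0), direction=(0, 0, 2))

    def test_params_reject_nonpositive_radius(self):
        with pytest.raises(ValueError):
            HelicalParams(14, -1.0, 0.0, 27.6, 0.0, 9.2, 0.0)

    def test_spoke_index_strictly_increasing(self):
        with pytest.raises(ValueError):
            AnchorSet(points=np.eye(3), labels=[(1, "A"), (1, "B"), (2, "C")])
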