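"""Geometric primitives and kinematic variable extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import compens2d as c2
from compens2d import body25
from compens2d.cleansing import clean_sequence
from compens2d.kinematics import DegenerateGeometryError, HeadModel


class TestAngle:
    @pytest.mark.parametrize("j1,j2,j3,expected", [
        ((0, 1), (0, 0), (1, 0), 90.0),
        ((2, 0), (0, 0), (5, 0), 0.0),
        ((1, 0), (0, 0), (1, 1), 45.0),
        ((0, 1), (0, 0), (0, -3), 180.0),
    ])
    def test_known_configurations(self, j1, j2, j3, expected):
        assert c2.angle(j1, j2, j3) == pytest.approx(expected)

    def test_zero_length_ray_is_error(self):
        with pytest.raises(DegenerateGeometryError):
            c2.angle((0, 0), (0, 0), (1, 0))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.floats(-180, 180), st.floats(0.1, 10), st.floats(0.1, 10),
           st.floats(-90, 90))
    def test_recovers_constructed_rotation(self, base, r1, r2, delta):
        """Rays built at a known angular separation."""
        a1 = math.radians(base)
        a2 = math.radians(base + delta)
        j2 = (3.0, -2.0)
        j1 = (j2[0] + r1 * math.cos(a1), j2[1] + r1 * math.sin(a1))
        j3 = (j2[0] + r2 * math.cos(a2), j2[1] + r2 * math.sin(a2))
        # arccos loses ~sqrt(eps) precision near collinearity
        assert c2.angle(j1, j2, j3) == pytest.approx(abs(delta), abs=1e-4)


class TestDistanceDisplacement:
    def test_three_four_five(self):
        assert c2.distance((3, 4), (0, 0)) == 5.0

    def test_identical_points(self):
        assert c2.displacement((2, 2), (2, 2)) == (0.0, 0.0)
        assert c2.distance((2, 2), (2, 2)) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
           st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)))
    def test_pythagorean_identity(self, p, q):
        dx, dy = c2.displacement(p, q)
        assert c2.distance(p, q) ** 2 == pytest.approx(dx ** 2 + dy ** 2,
                                                       rel=1e-9, abs=1e-9)


class TestHeadArea:
    def _call(self, pts, model=HeadModel()):
        xy = np.zeros((25, 2))
        conf = np.zeros(25)
        for j, p in zip(model.joint_ids, pts):
            xy[j] = p
            conf[j] = 0.9
        return c2.head_area(xy, conf, model)

    def test_unit_right_triangle(self):
        assert self._call([(0, 0), (1, 0), (0, 1)]) == pytest.approx(0.5)

    def test_area_scales_quadratically(self):
        pts = [(0, 0), (2, 0.2), (1.1, 1.5), (0.3, 1.2)]
        a1 = self._call(pts)
        a2 = self._call([(2 * x, 2 * y) for x, y in pts])
        assert a2 == pytest.approx(4 * a1)

    def test_two_points_fall_back_to_squared_intereye(self):
        model = HeadModel(joint_ids=(body25.R_EYE, body25.L_EYE))
        assert self._call([(0, 0), (3, 4)], model) == pytest.approx(25.0)

    def test_single_point_is_error(self):
        model = HeadModel(joint_ids=(body25.NOSE,))
        with pytest.raises(DegenerateGeometryError):
            self._call([(1, 1)], model)


def _series(seq):
    cleaned, _ = clean_sequence(seq)
    return c2.compute_series(c2.scale_by_spine(cleaned))


class TestComputeSeries:
    def test_static_sequence_gives_zero_series(self, static_sequence):
        seq, _ = static_sequence
        series = _series(seq)
        for var in series.values.columns:
            np.testing.assert_allclose(series[var], 0.0, atol=1e-9)

    def test_trunk_rotation_raises_both_shoulder_angles(self):
        tpl = c2.SubjectTemplate(scenario="S1", noise_sigma=0.0)
        script = c2.CompensationScript(
            episodes=(c2.Episode(label=1, start=30, end=60),))
        seq, _ = c2.generate_sequence(tpl, script, 90, seed=2)
        series = _series(seq)
        mid = slice(39, 50)   # plateau frames
        assert np.all(series["shoulder_angle_affected"][mid] > 15)
        assert np.all(series["shoulder_angle_unaffected"][mid] > 15)

    def test_side_view_forward_lean_geometry(self):
        """Spine sweep equals the scripted lean angle; neck moves with
        the lean direction."""
        tpl = c2.SubjectTemplate(scenario="S2", noise_sigma=0.0)
        script = c2.CompensationScript(
            episodes=(c2.Episode(label=0, start=30, end=60,
                                 magnitude=2.0),))
        seq, _ = c2.generate_sequence(tpl, script, 90, seed=2)
        series = _series(seq)
        plateau = slice(39, 50)
        # magnitude 2 x 10 deg threshold
        np.testing.assert_allclose(series["spine_angle"][plateau], 20.0,
                                   atol=1e-6)
        # analytic neck displacement of a 20 deg lean of a unit spine
        np.testing.assert_allclose(series["neck_x_disp"][plateau],
                                   math.sin(math.radians(20.0)), atol=1e-6)
        assert np.all(series["shoulder_x_disp"][plateau] > 0)

    def test_series_invariant_to_pixel_similarity_transform(self,
                                                            s1_sequence):
        seq, _ = s1_sequence
        frames = []
        for frame in seq.frames:
            joints = frame.skeletons[0].joints.copy()
            joints[:, :2] = joints[:, :2] * 1.7 + [31.0, -12.0]
            frames.append(c2.FrameObservation(
                t=frame.t, skeletons=(c2.Skeleton(joints),),
                image_size=frame.image_size))
        a = _series(seq)
        b = _series(seq.with_frames(frames))
        for var in a.values.columns:
            np.testing.assert_allclose(a[var], b[var], atol=1e-8)

    def test_head_area_change_symmetric_for_equal_leans(self):
        """Forward and backward head-size changes of equal scripted
        magnitude have equal absolute plateau values."""
        tpl = c2.SubjectTemplate(scenario="S1", noise_sigma=0.0)
        fwd = c2.CompensationScript(
            episodes=(c2.Episode(label=0, start=30, end=60),))
        back = c2.CompensationScript(
            episodes=(c2.Episode(label=3, start=30, end=60,
                                 mode="shrink"),))
        sa, _ = c2.generate_sequence(tpl, fwd, 90, seed=2)
        sb, _ = c2.generate_sequence(tpl, back, 90, seed=2)
        plateau = slice(39, 50)
        va = _series(sa)["head_area_change"][plateau]
        vb = _series(sb)["head_area_change"][plateau]
        np.testing.assert_allclose(va, -vb, atol=1e-9)

    def test_mirrored_input_rejected(self, static_sequence):
        seq, _ = static_sequence
        cleaned, _ = clean_sequence(seq)
        mirrored = c2.mirror_to_reference(c2.scale_by_spine(cleaned))
        with pytest.raises(ValueError, match="mirror"):
            c2.compute_series(mirrored)
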