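"""Angle conventions, orientation relationships, layer statistics, helices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sed3d import datasets
from sed3d.analysis import (
    angles_from_axis,
    axis_from_angles,
    circular_mean_180,
    classify_handedness,
    helix_pitch,
    layer_stats,
    mean_consecutive_relationship,
    orientation_relationship,
)
from sed3d.datamodel import GeometryError
from sed3d.reconstruct import OrientationField


def field_from_angle_list(angle_list):
    """One pixel per angle pair, labeled 1..n."""
    axes = np.array([axis_from_angles(a) for a in angle_list])[None, :, :]
    shape = axes.shape[:2]
    labels = np.arange(1, len(angle_list) + 1)[None, :]
    field = OrientationField(
        axis=axes,
        residual=np.zeros(shape),
        valid=np.ones(shape, bool),
        degenerate=np.zeros(shape, bool),
    )
    return field, labels


class TestAngleConventions:
    def test_beam_parallel_axis_has_zero_out_of_plane(self):
        ang = angles_from_axis(np.array([0.0, 0.0, 1.0]))
        assert ang.out_of_plane_deg == pytest.approx(0.0)

    def test_in_plane_axis_with_zero_y_is_flagged(self):
        ang = angles_from_axis(np.array([1.0, 0.0, 0.0]))
        assert ang.in_plane_deg == pytest.approx(0.0)
        assert abs(ang.out_of_plane_deg) == pytest.approx(90.0)
        assert ang.zero_y

    def test_layer1_angles_round_trip(self):
        a = axis_from_angles((33.0, 56.0))
        ang = angles_from_axis(a)
        assert ang.in_plane_deg == pytest.approx(33.0)
        assert ang.out_of_plane_deg == pytest.approx(56.0)

    def test_negative_out_of_plane_flips_y(self):
        a = axis_from_angles((47.0, -61.0))
        assert a[1] < 0
        assert a[2] == pytest.approx(np.cos(np.radians(61.0)))

    @settings(max_examples=50, deadline=None)
    @given(
        phi=st.floats(min_value=0, max_value=179.99),
        theta=st.floats(min_value=-89.9, max_value=89.9),
    )
    def test_round_trip_identity_for_nonzero_y(self, phi, theta):
        a = axis_from_angles((phi, theta))
        if abs(a[1]) < 1e-9:  # zero-y axes lose the sign of theta
            return
        ang = angles_from_axis(a)
        assert ang.in_plane_deg == pytest.approx(phi, abs=1e-6)
        assert ang.out_of_plane_deg == pytest.approx(theta, abs=1e-6)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            angles_from_axis(np.array([0.0, 0.0, 2.0]))


class TestOrientationRelationship:
    def test_identical_axes(self):
        a = axis_from_angles((33.0, 56.0))
        assert orientation_relationship(a, a) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_axes(self):
        assert orientation_relationship([1, 0, 0], [0, 0, 1]) == pytest.approx(90.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetric_bounded_sign_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        r = orientation_relationship(a, b)
        assert 0.0 <= r <= 90.0
        assert orientation_relationship(b, a) == pytest.approx(r)
        assert orientation_relationship(-a, b) == pytest.approx(r)
        assert orientation_relationship(a, -b) == pytest.approx(r)

    def test_longitudinal_consecutive_pairs_average(self):
        """Mean inter-layer relationship in the longitudinal section is 77°."""
        r = mean_consecutive_relationship(
            datasets.OAT_LONGITUDINAL_LAYERS, datasets.OAT_LONGITUDINAL_PAIRS
        )
        assert round(r) == 77

    def test_transverse_opposite_handed_pairs_average(self):
        """Mean relationship between opposite-handed transverse layers is 60°."""
        r = mean_consecutive_relationship(
            datasets.OAT_TRANSVERSE_LAYERS, datasets.OAT_TRANSVERSE_PAIRS
        )
        assert round(r) == 60


class TestLayerStats:
    def test_constant_region(self):
        field, labels = field_from_angle_list([(33.0, 56.0)] * 5)
        stats = layer_stats(field, np.ones_like(labels))
        assert len(stats) == 1
        s = stats[0]
        assert s.n_pixels == 5
        assert s.in_plane_mean_deg == pytest.approx(33.0, abs=1e-9)
        assert s.out_of_plane_mean_deg == pytest.approx(56.0, abs=1e-9)
        assert s.in_plane_std_deg == pytest.approx(0.0, abs=1e-6)
        assert s.handedness == "left"

    def test_in_plane_wraparound(self):
        field, labels = field_from_angle_list([(179.0, 45.0), (1.0, 45.0)])
        s = layer_stats(field, np.ones_like(labels))[0]
        assert s.in_plane_mean_deg == pytest.approx(0.0, abs=1e-9) or (
            s.in_plane_mean_deg == pytest.approx(180.0, abs=1e-9)
        )

    def test_handedness_group_averages(self):
        """Left-handed transverse layers average to (29°, 60°); right-handed
        to (45°, −63°), to the printed precision."""
        rows = datasets.OAT_TRANSVERSE_LAYERS
        left = [rows[i] for i in datasets.OAT_TRANSVERSE_LEFT]
        right = [rows[i] for i in datasets.OAT_TRANSVERSE_RIGHT]
        field, _ = field_from_angle_list(left + right)
        labels = np.array([[1, 1, 1, 2, 2, 2]])
        s_left, s_right = layer_stats(field, labels)
        assert round(s_left.in_plane_mean_deg) == 29
        assert round(s_left.out_of_plane_mean_deg) == 60
        assert s_left.handedness == "left"
        assert round(s_right.in_plane_mean_deg) == 45
        assert round(s_right.out_of_plane_mean_deg) == -63
        assert s_right.handedness == "right"

    def test_empty_region_entry(self):
        field, labels = field_from_angle_list([(33.0, 56.0)])
        stats = layer_stats(field, np.full_like(labels, 2))
        # region 2 holds the pixel; a requested region with no pixels is absent
        assert stats[0].label == 2
        field.valid[:] = False
        stats = layer_stats(field, np.full_like(labels, 2))
        assert stats[0].n_pixels == 0
        assert np.isnan(stats[0].in_plane_mean_deg)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_circular_mean_invariant_to_adding_180(self, seed):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0, 180, size=12)
        mask = rng.integers(0, 2, size=12).astype(bool)
        shifted = angles + 180.0 * mask
        d = abs(circular_mean_180(angles) - circular_mean_180(shifted))
        assert min(d, 180 - d) < 1e-9


class TestHandedness:
    CELL = np.array([0.0, 0.0, 1.0])
    RADIAL = np.array([1.0, 0.0, 0.0])
    TANGENT = np.cross(CELL, RADIAL)  # +y

    def test_tangent_plus_axis_is_right(self):
        a = (self.TANGENT + self.CELL) / np.sqrt(2)
        assert classify_handedness(a, self.CELL, self.RADIAL) == "right"

    def test_tangent_minus_axis_is_left(self):
        a = (self.TANGENT - self.CELL) / np.sqrt(2)
        assert classify_handedness(a, self.CELL, self.RADIAL) == "left"

    def test_pure_hoop_is_indeterminate(self):
        assert classify_handedness(self.TANGENT, self.CELL, self.RADIAL) == "indeterminate"

    def test_invariant_under_axis_flip(self):
        a = (self.TANGENT + self.CELL) / np.sqrt(2)
        assert classify_handedness(-a, self.CELL, self.RADIAL) == "right"

    def test_invariant_under_frame_flip(self):
        """Flipping cell axis and tangent together (radial fixed) keeps the
        winding sense."""
        a = (self.TANGENT + self.CELL) / np.sqrt(2)
        # flipping the cell axis flips the tangent t = cell × radial too
        assert classify_handedness(a, -self.CELL, self.RADIAL) == "right"

    def test_non_orthogonal_frame_rejected(self):
        with pytest.raises(GeometryError):
            classify_handedness(self.TANGENT, self.CELL, self.CELL)


class TestHelixGeometry:
    def test_45_degrees_pitch_equals_circumference(self):
        assert helix_pitch(45.0, 10.0) == pytest.approx(10.0)

    def test_steep_hoop_limit(self):
        assert helix_pitch(89.9, 10.0) < 0.02

    def test_inner_layer_worked_example(self):
        """pitch = C/tan(ψ) gives 47.7 μm for ψ=33°, C=31 μm (see the
        methods note: reported pitch values use a different per-layer
        parametrization and are not reproduced by this formula)."""
        assert helix_pitch(33.0, 31.0) == pytest.approx(47.7, abs=0.1)

    def test_boundary_angles_rejected(self):
        for bad in (0.0, 90.0, -5.0):
            with pytest.raises(ValueError):
                helix_pitch(bad, 10.0)
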