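"""Back-rotation geometry and the averaged-projections axis solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sed3d.azimuthal import AzimuthMap
from sed3d.reconstruct import (
    averaged_projections,
    axis_from_two,
    back_rotate,
    qvec_from_azimuth,
    reconstruct_field,
    rotation_y,
)
from sed3d.synth import forward_azimuth
from conftest import identity_series


def unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def angle_between_axes(a, b):
    return np.degrees(np.arccos(min(1.0, abs(float(np.dot(unit(a), unit(b)))))))


class TestGeometry:
    @pytest.mark.parametrize(
        "phi,expected",
        [(0.0, [1, 0, 0]), (90.0, [0, 1, 0]), (180.0, [-1, 0, 0])],
    )
    def test_qvec_examples(self, phi, expected):
        np.testing.assert_allclose(qvec_from_azimuth(phi), expected, atol=1e-12)

    def test_antipodal_azimuths_give_antiparallel_q(self):
        np.testing.assert_allclose(
            qvec_from_azimuth(37.0), -qvec_from_azimuth(217.0), atol=1e-12
        )

    def test_back_rotate_zero_tilt_is_identity(self, rng):
        q = unit(rng.normal(size=3))
        np.testing.assert_allclose(back_rotate(q, 0.0), q, atol=1e-15)

    def test_tilt_axis_direction_is_invariant(self):
        for omega in (-45.0, 13.0, 45.0):
            np.testing.assert_allclose(
                back_rotate([0.0, 1.0, 0.0], omega), [0, 1, 0], atol=1e-15
            )

    def test_back_rotate_x_by_45(self):
        # direct evaluation: R_y(-45°) x̂ = [cos 45°, 0, +sin 45°]
        c = np.cos(np.radians(45))
        np.testing.assert_allclose(
            back_rotate([1.0, 0.0, 0.0], 45.0), [c, 0.0, c], atol=1e-12
        )
        np.testing.assert_allclose(
            back_rotate([1.0, 0.0, 0.0], -45.0), [c, 0.0, -c], atol=1e-12
        )


class TestAxisFromTwo:
    def test_orthogonal_pair(self):
        est = axis_from_two([1, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(est.a_hat, [0, 0, 1], atol=1e-15)
        assert est.residual == pytest.approx(0.0, abs=1e-15)

    def test_parallel_pair_is_degenerate(self):
        q = unit([0.3, 0.5, 0.81])
        assert axis_from_two(q, q).degenerate

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_result_orthogonal_to_both_inputs(self, seed):
        rng = np.random.default_rng(seed)
        q1, q2 = unit(rng.normal(size=3)), unit(rng.normal(size=3))
        est = axis_from_two(q1, q2)
        if not est.degenerate:
            assert abs(est.a_hat @ q1) < 1e-12
            assert abs(est.a_hat @ q2) < 1e-12
            assert est.a_hat[2] >= 0


class TestAveragedProjections:
    def test_two_orthogonal_measurements_match_cross_product(self):
        q1, q2 = unit([1, 0.2, 0]), unit([-0.1, 1, 0.3])
        ref = axis_from_two(q1, q2)
        est = averaged_projections([q1, q2])
        assert angle_between_axes(est.a_hat, ref.a_hat) < np.degrees(1e-8)

    def test_exact_forward_model_recovery(self):
        """Three tilts of noiseless azimuths determine the axis to 1e-6 rad."""
        a_true = unit([0.6, 0.64, 0.48])
        qs = []
        for omega in (0.0, 45.0, -45.0):
            phi = forward_azimuth(a_true, omega)
            qs.append(back_rotate(qvec_from_azimuth(phi), omega))
        est = averaged_projections(qs)
        assert not est.degenerate
        assert angle_between_axes(est.a_hat, a_true) < np.degrees(1e-6)

    def test_matches_smallest_scatter_eigenvector(self):
        """Equivalent to the minimum-eigenvector solution on 100 random
        nondegenerate instances (N = 3..10)."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            n = int(rng.integers(3, 11))
            Q = rng.normal(size=(n, 3))
            Q /= np.linalg.norm(Q, axis=1, keepdims=True)
            w, v = np.linalg.eigh(Q.T @ Q / n)
            if w[1] - w[0] < 0.05:
                continue
            est = averaged_projections(Q)
            assert angle_between_axes(est.a_hat, v[:, 0]) < np.degrees(1e-6)
            checked += 1

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_to_measurement_sign_flips(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.normal(size=(4, 3))
        Q /= np.linalg.norm(Q, axis=1, keepdims=True)
        est = averaged_projections(Q)
        flip = rng.integers(0, 2, size=4) * 2 - 1
        est_flipped = averaged_projections(Q * flip[:, None])
        if not (est.degenerate or est_flipped.degenerate):
            assert angle_between_axes(est.a_hat, est_flipped.a_hat) < 1e-4

    def test_verbatim_projection_mode_is_not_sign_invariant(self):
        """The absolute-value projection form breaks q-sign invariance,
        which is why the signed form is the default."""
        rng = np.random.default_rng(3)
        Q = rng.normal(size=(3, 3))
        Q /= np.linalg.norm(Q, axis=1, keepdims=True)
        a = averaged_projections(Q, verbatim=True, max_iter=50)
        b = averaged_projections(Q * np.array([[-1.0], [1.0], [1.0]]), verbatim=True, max_iter=50)
        assert angle_between_axes(a.a_hat, b.a_hat) > 1e-3

    def test_needs_two_measurements(self):
        with pytest.raises(ValueError):
            averaged_projections([unit([1, 0, 0])])


class TestReconstructField:
    def _maps_from_axes(self, axes, tilts, valid=None):
        maps = []
        for omega in tilts:
            phi = forward_azimuth(axes, omega)
            v = np.isfinite(phi) if valid is None else valid & np.isfinite(phi)
            maps.append(
                AzimuthMap(
                    phi_deg=np.where(v, phi, np.nan),
                    quality=v.astype(float),
                    valid=v,
                    tilt_deg=omega,
                )
            )
        return identity_series(maps, tilts)

    def test_constant_axis_field_recovered(self):
        a_true = unit([0.6, 0.64, 0.48])
        axes = np.broadcast_to(a_true, (16, 16, 3)).copy()
        field = reconstruct_field(self._maps_from_axes(axes, [0.0, 45.0, -45.0]))
        ok = field.well_determined
        assert ok.mean() >= 0.99
        dots = np.abs(np.einsum("yxi,i->yx", np.nan_to_num(field.axis), a_true))
        err = np.degrees(np.arccos(np.clip(dots, 0, 1)))
        assert (err[ok] < 0.5).all()

    def test_zero_y_axis_is_degenerate_with_all_azimuths_90(self):
        a_true = unit([0.7, 0.0, 0.714])
        axes = np.broadcast_to(a_true, (4, 4, 3)).copy()
        series = self._maps_from_axes(axes, [0.0, 45.0, -45.0])
        for amap in series.maps:
            np.testing.assert_array_equal(amap.phi_deg[amap.valid], 90.0)
        field = reconstruct_field(series)
        assert field.degenerate.all()

    def test_pixel_with_single_tilt_is_invalid(self):
        a_true = unit([0.6, 0.64, 0.48])
        axes = np.broadcast_to(a_true, (4, 4, 3)).copy()
        valid0 = np.ones((4, 4), bool)
        valid1 = np.ones((4, 4), bool)
        valid1[0, 0] = False
        valid2 = np.ones((4, 4), bool)
        valid2[0, 0] = False
        maps = []
        for omega, v in zip([0.0, 45.0, -45.0], [valid0, valid1, valid2]):
            phi = forward_azimuth(axes, omega)
            maps.append(
                AzimuthMap(
                    phi_deg=np.where(v, phi, np.nan),
                    quality=v.astype(float),
                    valid=v,
                    tilt_deg=omega,
                )
            )
        field = reconstruct_field(identity_series(maps, [0.0, 45.0, -45.0]))
        assert not field.valid[0, 0]
        assert field.valid[1:].all()

    def test_axes_unit_norm_on_positive_z_hemisphere(self, rng):
        axes = rng.normal(size=(8, 8, 3))
        axes /= np.linalg.norm(axes, axis=-1, keepdims=True)
        axes[axes[..., 2] < 0] *= -1
        field = reconstruct_field(self._maps_from_axes(axes, [0.0, 45.0, -45.0]))
        ok = field.well_determined
        norms = np.linalg.norm(field.axis[ok], axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert (field.axis[ok][:, 2] >= 0).all()
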