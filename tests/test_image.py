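"""Rigid-transform algebra and resampling geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petpor.image import RigidTransform, Volume, compose, grid_like, resample

params_st = st.lists(
    st.floats(-20, 20, allow_nan=False, allow_infinity=False), min_size=6, max_size=6
)


def _random_transform(rng, t_scale=5.0, r_scale=30.0):
    return RigidTransform(
        rng.uniform(-t_scale, t_scale, 3), rng.uniform(-r_scale, r_scale, 3),
        rng.uniform(-10, 10, 3),
    )


class TestRigidTransform:
    def test_identity_matrix(self):
        T = RigidTransform.identity([1.0, 2.0, 3.0])
        assert np.allclose(T.matrix(), np.eye(4))

    def test_compose_with_identity(self):
        T = RigidTransform([1, -2, 3], [10, 20, -30], [5, 0, 0])
        out = compose(T, RigidTransform.identity([5, 0, 0]))
        assert np.allclose(out.matrix(), T.matrix())

    def test_compose_with_inverse_is_identity(self):
        T = RigidTransform([1, -2, 3], [10, 20, -30], [5, 0, 0])
        out = compose(T, T.inverse())
        assert np.linalg.norm(out.matrix() - np.eye(4)) < 1e-9

    def test_translations_add(self):
        a = RigidTransform([1, 0, 0], [0, 0, 0])
        b = RigidTransform([2, 0, 0], [0, 0, 0])
        out = compose(a, b)
        assert np.allclose(out.t_mm, [3, 0, 0])
        assert np.allclose(out.r_deg, 0)

    def test_compose_equals_matrix_product(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = _random_transform(rng), _random_transform(rng)
            assert np.allclose(compose(a, b).matrix(), b.matrix() @ a.matrix(), atol=1e-10)

    def test_compose_associative(self):
        rng = np.random.default_rng(8)
        a, b, c = (_random_transform(rng) for _ in range(3))
        lhs = compose(compose(a, b), c).matrix()
        rhs = compose(a, compose(b, c)).matrix()
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_rotations_wrapped_into_half_open_interval(self):
        T = RigidTransform([0, 0, 0], [190, -180, 540])
        assert np.allclose(T.r_deg, [-170, 180, 180])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(params_st)
    def test_matrix_decomposition_roundtrip(self, p):
        T = RigidTransform(p[:3], p[3:], [3.0, -4.0, 5.0])
        back = RigidTransform.from_matrix(T.matrix(), T.center_mm)
        assert np.allclose(back.matrix(), T.matrix(), atol=1e-9)

    def test_recentered_preserves_world_mapping(self):
        T = RigidTransform([1, 2, 3], [5, -10, 15], [0, 0, 0])
        pts = np.random.default_rng(0).uniform(-30, 30, (10, 3))
        assert np.allclose(T.apply(pts), T.recentered([7, -8, 9]).apply(pts), atol=1e-9)

    def test_json_roundtrip(self, tmp_path):
        T = RigidTransform([0.32, 0.65, 2.74], [3.02, 0.34, 0.35], [1, 2, 3])
        p = tmp_path / "t.json"
        T.to_json(p)
        back = RigidTransform.from_json(p)
        assert np.allclose(back.params, T.params)
        assert np.allclose(back.center_mm, T.center_mm)


class TestVolume:
    def test_rejects_singular_affine(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            Volume(np.zeros((4, 4, 4)), aff)

    def test_rejects_degenerate_axis(self):
        with pytest.raises(ValueError, match=">= 2"):
            Volume(np.zeros((1, 4, 4)), np.eye(4))

    def test_voxel_sizes_from_affine_columns(self):
        aff = np.diag([2.0, 3.0, 4.0, 1.0])
        v = Volume(np.zeros((4, 4, 4)), aff)
        assert np.allclose(v.voxel_sizes, [2, 3, 4])
        assert v.voxel_volume_mm3 == pytest.approx(24.0)


class TestResample:
    def test_identity_same_grid_is_bitwise_equal(self):
        g = grid_like((8, 8, 8), 1.0)
        v = g.with_data(np.random.default_rng(1).normal(size=(8, 8, 8)))
        out = resample(v, RigidTransform.identity(), v)
        assert np.array_equal(out.data, v.data)

    def test_integer_shift_moves_delta(self):
        g = grid_like((16, 16, 16), 1.0)
        data = np.zeros((16, 16, 16))
        data[5, 8, 8] = 1.0
        v = g.with_data(data)
        out = resample(v, RigidTransform([2, 0, 0], [0, 0, 0]), v, "nearest")
        assert out.data[7, 8, 8] == 1.0
        assert out.data.sum() == 1.0

    def test_half_voxel_shift_of_ramp_interpolates_linearly(self):
        g = grid_like((16, 8, 8), 1.0)
        slope = 2.0
        ramp = np.broadcast_to(
            slope * np.arange(16, dtype=float)[:, None, None], (16, 8, 8)
        ).copy()
        v = g.with_data(ramp)
        out = resample(v, RigidTransform([0.5, 0, 0], [0, 0, 0]), v, "trilinear")
        interior = out.data[2:-2, 2:-2, 2:-2]
        expected = ramp[2:-2, 2:-2, 2:-2] - 0.5 * slope
        assert np.allclose(interior, expected, atol=1e-12)

    def test_label_data_requires_nearest(self):
        g = grid_like((8, 8, 8), 1.0)
        lab = Volume(np.zeros((8, 8, 8), dtype=np.int32), g.affine, "unitless")
        with pytest.raises(ValueError, match="nearest"):
            resample(lab, RigidTransform.identity(), g, "trilinear")

    def test_roundtrip_exact_for_integer_voxel_shift(self):
        g = grid_like((16, 16, 16), 2.0)
        v = g.with_data(np.random.default_rng(2).normal(size=(16, 16, 16)))
        T = RigidTransform([4, -2, 6], [0, 0, 0])  # integer multiples of 2 mm
        back = resample(resample(v, T, g), T.inverse(), g)
        interior = (slice(4, -4),) * 3
        assert np.allclose(back.data[interior], v.data[interior], atol=1e-12)

    def test_roundtrip_small_error_for_smooth_volume(self):
        # trilinear interpolation applied twice is not the identity for
        # sub-voxel offsets; for a smooth volume the error is bounded by
        # curvature x voxel^2
        from petpor.psf import PSFModel, smooth

        g = grid_like((32, 32, 32), 2.0)
        data = np.zeros((32, 32, 32))
        data[16, 16, 16] = 1.0
        v = smooth(g.with_data(data), PSFModel(20.0))
        T = RigidTransform([0.7, -1.3, 0.4], [2.0, -1.0, 1.5])
        back = resample(resample(v, T, g), T.inverse(), g)
        interior = (slice(6, -6),) * 3
        err = np.abs(back.data[interior] - v.data[interior]).max()
        assert err < 0.05 * v.data.max()

    def test_quarter_turn_about_grid_axis_is_axis_permutation(self):
        n = 25  # odd: rotation center falls on a lattice point
        g = grid_like((n, n, n), 1.0)
        data = np.random.default_rng(3).integers(0, 10, (n, n, n)).astype(float)
        v = g.with_data(data)
        out = resample(v, RigidTransform([0, 0, 0], [0, 0, 90]), v, "nearest")
        ii, jj, kk = np.indices((n, n, n))
        expected = data[jj, n - 1 - ii, kk]
        # the outermost layer can fall a float-epsilon outside the grid
        # (cos 90 deg is not exactly 0 in floating point); interior is exact
        inner = (slice(1, -1),) * 3
        assert np.array_equal(out.data[inner], expected[inner])
        mismatch = out.data != expected
        assert mismatch.mean() < 0.05

    def test_out_of_field_fill_and_count(self):
        g = grid_like((10, 10, 10), 1.0)
        v = g.with_data(np.ones((10, 10, 10)))
        out, n_out = resample(
            v, RigidTransform([3, 0, 0], [0, 0, 0]), v, "nearest", count_outside=True
        )
        assert n_out == 3 * 10 * 10
        assert (out.data[:3] == 0).all()

    def test_simpleitk_resampling_oracle_agrees(self):
        # independent geometry oracle: apply the same world transform with
        # SimpleITK and compare interpolated values
        sitk = pytest.importorskip("SimpleITK")
        from petpor.psf import PSFModel, smooth

        g = grid_like((24, 24, 24), 2.0)
        data = np.zeros((24, 24, 24))
        data[12, 10, 14] = 1.0
        v = smooth(g.with_data(data), PSFModel(12.0))
        T = RigidTransform([1.5, -2.0, 3.0], [4.0, -3.0, 2.0], [0.0, 0.0, 0.0])
        ours = resample(v, T, g, "trilinear")

        # sitk indexes (z, y, x); world = origin + spacing * index here
        img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.T))
        img.SetSpacing((2.0, 2.0, 2.0))
        img.SetOrigin(tuple(v.affine[:3, 3]))
        M = T.inverse().matrix()
        at = sitk.AffineTransform(3)
        at.SetMatrix(M[:3, :3].ravel())
        at.SetTranslation(M[:3, 3])
        ref = sitk.Image(24, 24, 24, sitk.sitkFloat64)
        ref.SetSpacing((2.0, 2.0, 2.0))
        ref.SetOrigin(tuple(v.affine[:3, 3]))
        theirs = sitk.GetArrayFromImage(
            sitk.Resample(img, ref, at, sitk.sitkLinear, 0.0)
        ).T
        assert np.abs(ours.data - theirs).max() < 1e-10
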