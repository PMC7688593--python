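"""GTM matrix construction/solve and RBV voxel-wise correction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from petpor.image import Volume, grid_like
from petpor.phantom import GM_REGIONS, simulate_pet_scan
from petpor.psf import PSFModel, fwhm_to_sigma
from petpor.pvc import (
    compute_gtm_matrix,
    gtm_correct,
    make_synthetic,
    mass_fraction_matrix,
    rbv_correct,
)
from petpor.voi import LabelMap, region_stats


@pytest.fixture(scope="module")
def phantom_gtm(small_phantom, small_pet_clean):
    labels, truth, spec = small_phantom
    W, ids = compute_gtm_matrix(labels, PSFModel(spec.psf_fwhm_mm))
    return labels, truth, spec, W, ids


def _two_slabs(nx=80, voxel=1.0):
    data = np.zeros((nx, 8, 8), dtype=np.int32)
    data[: nx // 2] = 1
    data[nx // 2 :] = 2
    g = grid_like((nx, 8, 8), voxel)
    return LabelMap.from_volume(Volume(data, g.affine, "unitless"))


class TestGTMMatrix:
    def test_zero_fwhm_gives_identity(self, small_phantom):
        labels, _, _ = small_phantom
        W, _ = compute_gtm_matrix(labels, PSFModel(0.0))
        assert np.linalg.norm(W - np.eye(len(W))) < 1e-9

    def test_half_space_slabs_match_erf_closed_form(self):
        # 1-D analytic oracle: blurred indicator of the slab x > x0 is the
        # Gaussian CDF Phi((x - x0)/sigma); regional means follow directly
        nx = 80
        lm = _two_slabs(nx=nx, voxel=1.0)
        fwhm = 8.0
        W, ids = compute_gtm_matrix(lm, PSFModel(fwhm))
        sigma_vox = fwhm_to_sigma(fwhm) / 1.0
        centers = np.arange(nx, dtype=float)
        split = nx / 2 - 0.5
        blurred_b = norm.cdf((centers - split) / sigma_vox)
        expected_w12 = blurred_b[: nx // 2].mean()  # spill of region 2 into 1
        expected_w21 = (1.0 - blurred_b[nx // 2 :]).mean()
        i1, i2 = ids.index(1), ids.index(2)
        assert W[i1, i2] == pytest.approx(expected_w12, rel=0.01)
        assert W[i2, i1] == pytest.approx(expected_w21, rel=0.01)

    def test_entries_are_fractions_and_diagonal_dominant(self, phantom_gtm):
        labels, _, _, W, ids = phantom_gtm
        assert (W >= 0).all() and (W <= 1 + 1e-9).all()
        # regions thicker than the PSF see themselves most
        for rid in (1,):  # white matter core
            i = ids.index(rid)
            assert all(W[i, i] > W[i, j] for j in range(len(ids)) if j != i)

    def test_mass_fraction_columns_sum_to_at_most_one(self, phantom_gtm):
        labels, _, _, W, ids = phantom_gtm
        n = region_stats(labels.labels.with_data(np.zeros(labels.labels.shape)), labels)[
            "n_voxels"
        ].to_numpy()
        V = mass_fraction_matrix(W, n)
        # mirror-boundary reflection near the FOV edge (the shell reaches it)
        # can add ~1e-4 of apparent mass; interior regions are at 1e-6
        assert (V.sum(axis=0) <= 1.0 + 1e-3).all()

    def test_empty_region_rejected_by_name(self):
        data = np.zeros((6, 6, 6), dtype=np.int32)
        data[:2] = 1
        lm = LabelMap.from_volume(Volume(data, np.eye(4), "unitless"))
        table = pd.concat(
            [lm.regions, pd.DataFrame({"region_id": [5], "region_name": ["ghost"]})],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="ghost"):
            compute_gtm_matrix(LabelMap(lm.labels, table), PSFModel(4.0))


class TestGTMCorrect:
    def test_identity_matrix_returns_observed(self, small_phantom, small_pet_clean):
        labels, _, _ = small_phantom
        n = len(labels.region_ids)
        res = gtm_correct(small_pet_clean, labels, np.eye(n))
        assert np.allclose(res.corrected, res.observed)

    def test_recovers_truth_on_clean_phantom(self, phantom_gtm, small_pet_clean):
        labels, truth, _, W, ids = phantom_gtm
        res = gtm_correct(small_pet_clean, labels, W, ids)
        tv = np.array([truth[i] for i in ids])
        nz = tv != 0
        assert np.abs((res.corrected - tv)[nz] / tv[nz]).max() < 0.01
        assert np.abs(res.corrected[~nz]).max() < 0.01

    def test_singular_matrix_raises_with_diagnostic(self, small_phantom, small_pet_clean):
        labels, _, _ = small_phantom
        n = len(labels.region_ids)
        W = np.eye(n)
        W[1] = W[0]  # duplicate observing row -> rank deficient
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            gtm_correct(small_pet_clean, labels, W)

    def test_ill_conditioned_falls_back_to_least_squares(self, small_phantom, small_pet_clean):
        labels, _, _ = small_phantom
        n = len(labels.region_ids)
        W = np.eye(n)
        W[0, 1] = 1.0 - 1e-9
        W[1, 0] = 1.0 - 1e-9  # nearly dependent pair -> huge condition number
        with pytest.warns(UserWarning, match="ill-conditioned"):
            res = gtm_correct(small_pet_clean, labels, W)
        assert res.ill_conditioned

    def test_scale_equivariance(self, phantom_gtm, small_pet_clean):
        labels, _, _, W, ids = phantom_gtm
        res1 = gtm_correct(small_pet_clean, labels, W, ids)
        res2 = gtm_correct(small_pet_clean.with_data(3.0 * small_pet_clean.data), labels, W, ids)
        assert np.allclose(res2.observed, 3.0 * res1.observed)
        assert np.allclose(res2.corrected, 3.0 * res1.corrected)

    def test_random_activity_draws_recovered_within_one_percent(self, phantom_gtm):
        # the matrix is geometry-only, so each draw reuses it
        labels, _, spec, W, ids = phantom_gtm
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            acts = {rid: float(rng.uniform(0.5, 3.0)) for rid in ids}
            pet = simulate_pet_scan(labels, acts, None, PSFModel(spec.psf_fwhm_mm), 0.0)
            res = gtm_correct(pet, labels, W, ids)
            tv = np.array([acts[i] for i in ids])
            worst = max(worst, float(np.abs((res.corrected - tv) / tv).max()))
        assert worst < 0.01


class TestSynthetic:
    def test_single_region_value_one_is_binary_mask(self):
        data = np.zeros((6, 6, 6), dtype=np.int32)
        data[2:4] = 1
        lm = LabelMap.from_volume(Volume(data, np.eye(4), "unitless"))
        syn = make_synthetic(lm, np.array([1.0]))
        assert set(np.unique(syn.data)) == {0.0, 1.0}
        assert np.array_equal(syn.data > 0, data > 0)

    def test_region_means_equal_corrected_exactly(self, phantom_gtm, small_pet_clean):
        labels, _, _, W, ids = phantom_gtm
        res = gtm_correct(small_pet_clean, labels, W, ids)
        syn = make_synthetic(labels, res.corrected, ids)
        stats = region_stats(syn, labels)
        assert np.allclose(stats["mean"].to_numpy(), res.corrected)
        assert np.allclose(stats["sd"].to_numpy(), 0.0)

    def test_length_mismatch_rejected(self, small_phantom):
        labels, _, _ = small_phantom
        with pytest.raises(ValueError, match="regions"):
            make_synthetic(labels, np.ones(2))

    def test_negative_values_preserved(self, caplog):
        import logging

        data = np.zeros((6, 6, 6), dtype=np.int32)
        data[2:4] = 1
        lm = LabelMap.from_volume(Volume(data, np.eye(4), "unitless"))
        with caplog.at_level(logging.WARNING, logger="petpor.pvc"):
            syn = make_synthetic(lm, np.array([-0.5]))
        assert syn.data.min() == -0.5
        assert any("negative" in r.message for r in caplog.records)


class TestRBV:
    def test_whole_grid_region_constant_passthrough(self):
        data = np.ones((24, 24, 24), dtype=np.int32)
        g = grid_like((24, 24, 24), 1.0)
        lm = LabelMap.from_volume(Volume(data, g.affine, "unitless"))
        pet = g.with_data(np.random.default_rng(1).uniform(1, 2, (24, 24, 24)))
        syn = make_synthetic(lm, np.array([1.7]))
        out = rbv_correct(pet, syn, PSFModel(8.0))
        # s is constant so s/(s*h) == 1 everywhere (mirror boundaries)
        assert np.allclose(out.data, pet.data, atol=1e-10)

    def test_regional_means_match_gtm_within_two_percent(
        self, phantom_gtm, small_pet_clean
    ):
        labels, truth, spec, W, ids = phantom_gtm
        res = gtm_correct(small_pet_clean, labels, W, ids)
        syn = make_synthetic(labels, res.corrected, ids)
        rbv = rbv_correct(small_pet_clean, syn, PSFModel(spec.psf_fwhm_mm))
        means = region_stats(rbv, labels)["mean"].to_numpy()
        nz = res.corrected > 1e-6
        rel = np.abs(means[nz] - res.corrected[nz]) / res.corrected[nz]
        assert rel.max() < 0.02

    def test_zero_synthetic_voxels_output_zero(self, phantom_gtm, small_pet_clean):
        labels, _, spec, W, ids = phantom_gtm
        res = gtm_correct(small_pet_clean, labels, W, ids)
        syn = make_synthetic(labels, res.corrected, ids)
        out = rbv_correct(small_pet_clean, syn, PSFModel(spec.psf_fwhm_mm))
        corner = out.data[:2, :2, :2]  # far outside the brain and shell
        assert np.allclose(corner, 0.0)

    def test_epsilon_out_of_range_rejected(self, phantom_gtm, small_pet_clean):
        labels, _, spec, W, ids = phantom_gtm
        syn = make_synthetic(labels, np.ones(len(ids)), ids)
        for eps in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError, match="epsilon"):
                rbv_correct(small_pet_clean, syn, PSFModel(spec.psf_fwhm_mm), eps)

    def test_reduces_within_region_cov_in_gray_matter(
        self, phantom_gtm, small_pet_clean
    ):
        # spill-driven gradients across thin GM are exactly what RBV removes
        labels, _, spec, W, ids = phantom_gtm
        res = gtm_correct(small_pet_clean, labels, W, ids)
        syn = make_synthetic(labels, res.corrected, ids)
        rbv = rbv_correct(small_pet_clean, syn, PSFModel(spec.psf_fwhm_mm))
        cov_in = region_stats(small_pet_clean, labels).set_index("region_id")["cov_percent"]
        cov_out = region_stats(rbv, labels).set_index("region_id")["cov_percent"]
        for rid in GM_REGIONS:
            assert cov_out[rid] <= cov_in[rid]

    def test_scale_equivariance(self, phantom_gtm, small_pet_clean):
        labels, _, spec, W, ids = phantom_gtm
        res = gtm_correct(small_pet_clean, labels, W, ids)
        syn = make_synthetic(labels, res.corrected, ids)
        out1 = rbv_correct(small_pet_clean, syn, PSFModel(spec.psf_fwhm_mm))
        out2 = rbv_correct(
            small_pet_clean.with_data(2.5 * small_pet_clean.data), syn, PSFModel(spec.psf_fwhm_mm)
        )
        assert np.allclose(out2.data, 2.5 * out1.data, atol=1e-9)
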