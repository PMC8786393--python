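"""Tikhonov inversion, smoothing and hemoglobin spectroscopy."""

from __future__ import annotations

import numpy as np
import pytest

from dotkit import light_model as lm
from dotkit import reconstruction as rc
from dotkit import synthetic


def _model_from_A(A, voxel_size=1.0):
    """Wrap a dense matrix as a one-wavelength model over a 1D voxel line."""
    A = np.asarray(A, dtype=float)
    n_meas, n_vox = A.shape
    meas = lm.make_measurement_list([(1, i + 1) for i in range(n_meas)],
                                    [690.0])
    return lm.SensitivityModel(A=A, good_vox=np.arange(n_vox),
                               shape=(n_vox, 1, 1), voxel_size_mm=voxel_size,
                               measurements=meas, threshold_used=0.01)


class TestInversion:
    def test_identity_limit(self):
        model = _model_from_A(np.eye(4))
        op = rc.invert_sensitivity(model, lambda1=1e-12, lambda2=0.0)
        np.testing.assert_allclose(op.matrix, np.eye(4), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_measurement_and_voxel_forms_agree(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, size=(4, 6))
        model = _model_from_A(A)
        m = rc.invert_sensitivity(model, force_form="measurement").matrix
        v = rc.invert_sensitivity(model, force_form="voxel").matrix
        np.testing.assert_allclose(m, v, atol=1e-8)

    def test_l_reduces_to_column_norms_without_lambda2(self, rng):
        A = rng.uniform(0, 1, size=(3, 5))
        np.testing.assert_allclose(rc.spatially_variant_l(A, 0.0),
                                   np.sqrt((A ** 2).sum(axis=0)))

    def test_monotone_regularization(self, rng):
        A = rng.uniform(0, 1, size=(6, 12))
        y = rng.normal(size=(1, 6))
        model = _model_from_A(A)
        norms = []
        for lam1 in (1e-4, 1e-2, 1.0, 100.0):
            op = rc.invert_sensitivity(model, lambda1=lam1, lambda2=0.1)
            norms.append(np.linalg.norm(rc.reconstruct_img(op, y)))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_unregularized_rank_deficient_rejected(self):
        A = np.array([[1.0, 0.0], [1.0, 0.0]])  # zero-sensitivity voxel
        model = _model_from_A(A)
        with pytest.raises(np.linalg.LinAlgError):
            rc.invert_sensitivity(model, lambda1=0.0, lambda2=0.0)


class TestReconstructImg:
    def test_zero_measurements_give_zero_image(self):
        model = _model_from_A(np.eye(3))
        op = rc.invert_sensitivity(model)
        np.testing.assert_allclose(rc.reconstruct_img(op, np.zeros((5, 3))),
                                   0.0)

    def test_homogeneity(self, rng):
        model = _model_from_A(rng.uniform(0, 1, size=(4, 8)))
        op = rc.invert_sensitivity(model)
        y = rng.normal(size=(3, 4))
        np.testing.assert_allclose(rc.reconstruct_img(op, 2.5 * y),
                                   2.5 * rc.reconstruct_img(op, y),
                                   atol=1e-12)

    def test_forward_projected_source_peaks_at_its_voxel(self, rng):
        # well-conditioned random A, sparse source, weak regularization
        A = rng.uniform(0.1, 1.0, size=(12, 12))
        model = _model_from_A(A)
        x0 = np.zeros(12)
        x0[7] = 1.0
        y = (A @ x0)[None, :]
        op = rc.invert_sensitivity(model, lambda1=1e-8, lambda2=0.0)
        x = rc.reconstruct_img(op, y)[0]
        assert int(np.argmax(np.abs(x))) == 7

    def test_dimension_mismatch(self):
        model = _model_from_A(np.eye(3))
        op = rc.invert_sensitivity(model)
        with pytest.raises(ValueError, match="measurements"):
            rc.reconstruct_img(op, np.zeros((5, 4)))


class TestDepthWeighting:
    def test_lambda2_boosts_deep_voxels_on_phantom(self, phantom_bundle):
        """Spatially variant regularization counteracts superficial bias."""
        model = phantom_bundle["model"]
        head = phantom_bundle["head"]
        labels = head.labels.ravel(order="F")[model.good_vox]
        act = synthetic.pick_cortical_activation_voxel(model, head)
        rows = model.wavelength_rows(690.0)
        y = (model.A[rows] @ np.eye(model.n_voxels)[act])[None, :]
        ratios = {}
        for lam2 in (0.0, 0.1):
            op = rc.invert_sensitivity(model, lambda1=0.01, lambda2=lam2,
                                       wavelength_nm=690.0)
            x = np.abs(rc.reconstruct_img(op, y)[0])
            deep = x[labels >= 3].max()       # gray/white
            shallow = x[labels == 1].max()    # scalp/skull
            ratios[lam2] = deep / shallow
        assert ratios[0.1] > ratios[0.0]


class TestSmoothing:
    def test_impulse_matches_separable_gaussian_oracle(self, rng):
        shape = (25, 25, 25)
        c = 12
        good = np.arange(int(np.prod(shape)))
        meas = lm.make_measurement_list([(1, 1)], [690.0])
        model = lm.SensitivityModel(
            A=np.ones((1, good.size)), good_vox=good, shape=shape,
            voxel_size_mm=1.0, measurements=meas, threshold_used=0.01)
        frame = np.zeros(good.size)
        frame[np.ravel_multi_index((c, c, c), shape, order="F")] = 1.0
        out = rc.smooth_images(frame[None, :], 6.0, model)[0]
        vol = lm.embed_to_volume(out, good, shape)
        # independent separable-kernel oracle with the same discretization
        sigma = 6.0 * rc.FWHM_TO_SIGMA
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        expected = np.einsum("i,j,k->ijk", k, k, k)
        sl = slice(c - radius, c + radius + 1)
        np.testing.assert_allclose(vol[sl, sl, sl], expected, atol=1e-6)

    def test_narrow_kernel_is_near_identity(self, phantom_bundle, rng):
        model = phantom_bundle["model"]
        frame = rng.normal(size=(1, model.n_voxels))
        with pytest.warns(UserWarning, match="recommended"):
            out = rc.smooth_images(frame, 0.05, model)
        np.testing.assert_allclose(out, frame, atol=1e-6)

    def test_total_signal_conserved_away_from_boundary(self):
        shape = (21, 21, 21)
        good = np.arange(int(np.prod(shape)))
        meas = lm.make_measurement_list([(1, 1)], [690.0])
        model = lm.SensitivityModel(
            A=np.ones((1, good.size)), good_vox=good, shape=shape,
            voxel_size_mm=2.0, measurements=meas, threshold_used=0.01)
        frame = np.zeros(good.size)
        frame[np.ravel_multi_index((10, 10, 10), shape, order="F")] = 3.0
        out = rc.smooth_images(frame[None, :], 6.0, model)[0]
        assert out.sum() == pytest.approx(3.0, rel=1e-6)

    def test_non_positive_fwhm_rejected(self, phantom_bundle):
        with pytest.raises(ValueError):
            rc.smooth_images(np.zeros((1, phantom_bundle["model"].n_voxels)),
                             0.0, phantom_bundle["model"])


class TestSpectroscopy:
    def test_zero_absorption_gives_zero_hemoglobin(self):
        hbo, hbr, hbt = rc.spectroscopy(np.zeros(5), np.zeros(5),
                                        (690.0, 830.0))
        assert not hbo.any() and not hbr.any() and not hbt.any()

    def test_round_trip_recovers_known_concentrations(self):
        e = rc.DEFAULT_EXTINCTION.matrix((690.0, 830.0))
        hbo0, hbr0 = 1.0, -0.3
        dmua = e @ np.array([hbo0, hbr0])
        hbo, hbr, hbt = rc.spectroscopy(dmua[0], dmua[1], (690.0, 830.0))
        assert hbo == pytest.approx(hbo0, abs=1e-10)
        assert hbr == pytest.approx(hbr0, abs=1e-10)
        assert hbt == pytest.approx(hbo0 + hbr0, abs=1e-10)

    def test_hbt_is_sum_for_random_inputs(self, rng):
        a = rng.normal(size=(10, 4))
        b = rng.normal(size=(10, 4))
        hbo, hbr, hbt = rc.spectroscopy(a, b, (690.0, 830.0))
        np.testing.assert_allclose(hbt, hbo + hbr, atol=1e-12)

    def test_extinction_pair_well_conditioned(self):
        # the wavelength pair must separate the chromophores
        assert rc.DEFAULT_EXTINCTION.condition_number((690.0, 830.0)) < 20

    def test_missing_wavelength_rejected(self):
        with pytest.raises(KeyError):
            rc.DEFAULT_EXTINCTION.matrix((690.0, 555.0))
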