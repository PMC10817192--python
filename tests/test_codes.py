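"""Tests of the eigenface, decoupled and concatenated codes."""

import numpy as np
import pytest

from facecode.codes import (ConcatenatedCode, DecoupledCode, EigenfaceCode,
                            sample_faces)
from facecode.synth import generate_dataset


@pytest.fixture(scope="module")
def small_ds(exact_truth):
    return generate_dataset(exact_truth, 10, 2, seed=6)


class TestEigenface:
    def test_mean_image_encodes_to_zero(self, small_ds):
        code = EigenfaceCode(small_ds, p=5)
        enc = code.encode(code.model.mean)
        assert np.allclose(enc.texture, 0.0, atol=1e-9)

    def test_full_rank_roundtrip_is_exact(self, small_ds):
        code = EigenfaceCode(small_ds, p=small_ds.n - 1)
        img = small_ds.image(3)
        rec = code.reconstruct(img)
        assert np.allclose(rec, img, atol=1e-6)

    def test_zero_encoding_decodes_to_mean(self, small_ds):
        code = EigenfaceCode(small_ds, p=4)
        from facecode.codes import FaceEncoding
        img = code.decode(FaceEncoding("RE", texture=np.zeros(4)))
        assert np.allclose(img.ravel(), code.model.mean)

    def test_projection_idempotence(self, small_ds):
        code = EigenfaceCode(small_ds, p=6)
        once = code.reconstruct(small_ds.image(0))
        twice = code.reconstruct(once)
        assert np.allclose(once, twice, atol=1e-8)

    def test_reconstruction_error_nonincreasing_in_p(self, small_ds):
        img = small_ds.image(1)
        errs = []
        for p in (1, 3, 6, 10, 15):
            rec = EigenfaceCode(small_ds, p=p).reconstruct(img)
            errs.append(float(np.sum((rec - img) ** 2)))
        assert all(a >= b - 1e-6 for a, b in zip(errs, errs[1:]))


class TestDecoupled:
    def test_texture_coefficients_stable_across_expressions(self, small_ds):
        # decoupling-exact generator: expression moves shape only, so the
        # texture coefficients of a subject's two expressions agree within
        # the sensor-noise scale while shape coefficients differ
        code = DecoupledCode(small_ds, p_texture=8, p_shape=7)
        subj = sorted(set(small_ds.subject_id))[0]
        i_n = small_ds.rows_where(subject=subj, expression="neutral")[0]
        i_s = small_ds.rows_where(subject=subj, expression="smiling")[0]
        e_n = code.encode(small_ds.image(i_n), small_ds.landmarks[i_n])
        e_s = code.encode(small_ds.image(i_s), small_ds.landmarks[i_s])
        tex_gap = np.abs(e_n.texture - e_s.texture)
        tex_scale = np.sqrt(code.texture_model.eigenvalues)
        assert np.all(tex_gap < 0.35 * tex_scale)
        assert np.linalg.norm(e_n.shape - e_s.shape) > 1.0

    def test_full_rank_shape_roundtrip(self, small_ds):
        from facecode.ppca import data_rank
        p_s = data_rank(small_ds.landmarks)
        code = DecoupledCode(small_ds, p_texture=5, p_shape=p_s)
        lm = small_ds.landmarks[2]
        enc = code.encode(small_ds.image(2), lm)
        _, lm_dec = code.decode(enc)
        assert np.allclose(lm_dec, lm, atol=1e-6)

    def test_zero_encoding_gives_mean_texture_at_mean_landmarks(self, small_ds):
        from facecode.codes import FaceEncoding
        code = DecoupledCode(small_ds, p_texture=5, p_shape=4)
        img, lm = code.decode(FaceEncoding("RD", texture=np.zeros(5), shape=np.zeros(4)))
        assert np.allclose(lm, code.shape_model.mean, atol=1e-9)
        # mean landmarks equal the mean shape, so de-uniformation is a no-op
        assert np.allclose(img.ravel(), np.rint(np.clip(code.texture_model.mean, 0, 255)),
                           atol=1.0)


class TestConcatenated:
    def test_roundtrip_close_at_full_rank(self, small_ds):
        code = ConcatenatedCode(small_ds, p=small_ds.n - 1)
        img = small_ds.image(4)
        lm = small_ds.landmarks[4]
        rec, lm_dec = code.reconstruct(img, lm)
        assert np.allclose(lm_dec, lm, atol=1e-6)
        from facecode.warp import interior_psnr
        assert interior_psnr(rec, img) >= 30.0

    def test_unweighted_option(self, small_ds):
        code = ConcatenatedCode(small_ds, p=5, shape_weight=1.0)
        assert code.shape_weight == 1.0
        enc = code.encode(small_ds.image(0), small_ds.landmarks[0])
        assert enc.joint.shape == (5,)

    def test_balanced_weight_equalises_block_variance(self, small_ds):
        from facecode.warp import mean_shape_of, uniformize_dataset
        code = ConcatenatedCode(small_ds, p=5)
        ms = code.mean_shape
        uni = uniformize_dataset(small_ds, ms)
        v_tex = uni.images.var(axis=0).sum()
        v_shp = (small_ds.landmarks * code.shape_weight).var(axis=0).sum()
        assert np.isclose(v_tex, v_shp, rtol=1e-6)


class TestSampling:
    def test_zero_eigenvalues_give_mean_face(self, small_ds):
        code = EigenfaceCode(small_ds, p=8)
        code.model.eigenvalues = np.zeros_like(code.model.eigenvalues)
        imgs = sample_faces(code, p=4, pool=8, n=3, seed=0)
        for img in imgs:
            assert np.allclose(img.ravel(), code.model.mean)

    def test_seeded_determinism(self, small_ds):
        code = ConcatenatedCode(small_ds, p=10)
        a = sample_faces(code, p=5, pool=10, n=4, seed=9)
        b = sample_faces(code, p=5, pool=10, n=4, seed=9)
        assert np.array_equal(a, b)

    def test_retained_coefficient_covariance_matches_spectrum(self, small_ds):
        code = EigenfaceCode(small_ds, p=10)
        _, coeffs = sample_faces(code, p=6, pool=6, n=2000, seed=3,
                                 return_coefficients=True)
        sample_var = coeffs.var(axis=0)
        lam = code.model.eigenvalues[:6]
        assert np.all(np.abs(sample_var - lam) / lam < 0.10)

    def test_p_bounds_enforced(self, small_ds):
        code = EigenfaceCode(small_ds, p=8)
        with pytest.raises(ValueError):
            sample_faces(code, p=9, pool=8, n=1, seed=0)
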