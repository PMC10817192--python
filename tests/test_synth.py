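"""Tests of the synthetic face generator."""

import numpy as np
import pytest

from facecode.ppca import fit_ppca
from facecode.synth import (default_truth, downscale_dataset, generate_dataset,
                            low_correlation_truth, make_template)
from facecode.warp import mean_shape_of, uniformize_dataset


class TestTemplate:
    def test_shapes_and_bounds(self):
        img, lm = make_template(100, 120, 46)
        assert img.shape == (120 * 100,)
        assert lm.shape == (92,)
        assert img.min() >= 0 and img.max() <= 255
        assert lm[0::2].min() > 0 and lm[0::2].max() < 99
        assert lm[1::2].min() > 0 and lm[1::2].max() < 119

    def test_deterministic(self):
        a = make_template(100, 120, 46)
        b = make_template(100, 120, 46)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mouth_below_eyes(self):
        from facecode.synth import _eye_indices, _mouth_slice

        _, lm = make_template(100, 120, 46)
        pts = lm.reshape(-1, 2)
        assert pts[_mouth_slice(46), 1].mean() > pts[_eye_indices(46), 1].mean()

    def test_too_small_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_template(12, 12, 8)

    def test_too_few_landmarks_rejected(self):
        with pytest.raises(ValueError):
            make_template(100, 120, 6)

    @pytest.mark.parametrize("n_l", [8, 16, 46, 120, 400])
    def test_landmark_counts_allocate(self, n_l):
        _, lm = make_template(128, 152, n_l)
        assert lm.shape == (2 * n_l,)


class TestGroundTruth:
    def test_component_orthonormality(self, truth):
        assert np.allclose(truth.shape_components @ truth.shape_components.T,
                           np.eye(len(truth.shape_components)), atol=1e-10)
        assert np.allclose(truth.texture_components @ truth.texture_components.T,
                           np.eye(len(truth.texture_components)), atol=1e-10)
        assert np.isclose(np.linalg.norm(truth.expression_component), 1.0)

    def test_expression_confined_to_mouth(self, truth):
        vec = truth.expression_component.reshape(-1, 2)
        outside = np.ones(truth.n_landmarks, dtype=bool)
        outside[truth.mouth_slice] = False
        assert np.all(vec[outside] == 0)
        assert np.any(vec[~outside] != 0)


class TestGeneration:
    def test_seeded_determinism(self, exact_truth):
        a = generate_dataset(exact_truth, 3, 2, seed=11)
        b = generate_dataset(exact_truth, 3, 2, seed=11)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.landmarks, b.landmarks)

    def test_degenerate_generator_returns_template(self, exact_truth):
        import copy

        t = copy.deepcopy(exact_truth)
        t.shape_sds = t.shape_sds * 0.0
        t.texture_sds = t.texture_sds * 0.0
        t.expression_sd = 0.0
        t.pixel_noise_sd = 0.0
        t.gender_texture_sd = 0.0
        t.gender_shape_sd = 0.0
        ds = generate_dataset(t, 2, 2, seed=0)
        tmpl = np.rint(t.template_image.ravel())
        for i in range(ds.n):
            assert np.array_equal(ds.images[i], tmpl)
            assert np.allclose(ds.landmarks[i], t.template_landmarks)

    def test_expression_difference_only_on_mouth(self, exact_bench, exact_truth):
        ds = exact_bench
        sl = exact_truth.mouth_slice
        for s in sorted(set(ds.subject_id))[:5]:
            i_n = ds.rows_where(subject=s, expression="neutral")[0]
            i_s = ds.rows_where(subject=s, expression="smiling")[0]
            diff = (ds.landmarks[i_s] - ds.landmarks[i_n]).reshape(-1, 2)
            outside = np.ones(ds.n_landmarks, dtype=bool)
            outside[sl] = False
            assert np.allclose(diff[outside], 0.0)

    def test_uniformed_expression_pairs_differ_by_noise_only(self, exact_truth):
        """Decoupling-exact configuration: after uniformation the two
        expressions of a subject differ by sensor noise plus interpolation
        error; oracle = the same render with noise off."""
        import copy

        ds = generate_dataset(exact_truth, 6, 2, seed=9)
        t0 = copy.deepcopy(exact_truth)
        t0.pixel_noise_sd = 0.0
        ds0 = generate_dataset(t0, 6, 2, seed=9)
        ms = mean_shape_of(ds.landmarks, ds.width, ds.height)
        uni = uniformize_dataset(ds, ms)
        uni0 = uniformize_dataset(ds0, ms)
        m = 8
        for s in sorted(set(ds.subject_id)):
            i_n = ds.rows_where(subject=s, expression="neutral")[0]
            i_s = ds.rows_where(subject=s, expression="smiling")[0]
            msd = np.mean((uni.image(i_n) - uni.image(i_s))[m:-m, m:-m] ** 2)
            interp = np.mean((uni0.image(i_n) - uni0.image(i_s))[m:-m, m:-m] ** 2)
            assert msd <= 3 * (2 * exact_truth.pixel_noise_sd ** 2) + interp

    def test_metadata_and_invariants(self, bench100):
        assert bench100.n == 100
        assert bench100.d_s == 92
        assert set(bench100.expression) == {"neutral", "smiling"}
        assert set(bench100.gender) == {"f", "m"}

    def test_single_subject_rejected(self, exact_truth):
        with pytest.raises(ValueError):
            generate_dataset(exact_truth, 1, 2, seed=0)


class TestSpectrumRecovery:
    def test_planted_texture_components_dominate(self):
        """With q_t planted texture components the uniformed spectrum shows
        q_t eigenvalues separated from the noise floor."""
        t = default_truth(width=50, height=60, q_t=5)
        t.texture_sds = np.array([30.0, 26.0, 22.0, 19.0, 16.0]) * np.sqrt(50 * 60)
        t.texture_within_fraction = 0.0
        t.idiosyncratic_texture_sd = 0.0
        t.pose_translation_sd = 0.0
        t.pose_log_scale_sd = 0.0
        t.pose_rotation_sd = 0.0
        t.landmark_noise_sd = 0.0
        t.gender_texture_sd = 0.0  # gender would be a sixth planted component
        t.gender_shape_sd = 0.0
        ds = generate_dataset(t, 150, 2, seed=7)
        ms = mean_shape_of(ds.landmarks, ds.width, ds.height)
        uni = uniformize_dataset(ds, ms)
        model = fit_ppca(uni.images, 12)
        lam = model.eigenvalues
        assert lam[4] > 8 * lam[5]  # five dominant modes, clear noise floor


class TestDownscale:
    def test_native_width_is_identity(self, bench100):
        same = downscale_dataset(bench100, 100)
        assert np.array_equal(same.images, bench100.images)

    def test_dimension_bookkeeping(self, bench100):
        small = downscale_dataset(bench100, 25)
        assert small.d_t == bench100.d_t // 16
        assert small.d_s == bench100.d_s

    def test_landmark_scaling_is_linear(self, bench100):
        small = downscale_dataset(bench100, 50)
        assert np.allclose(small.landmarks.mean(axis=0),
                           0.5 * bench100.landmarks.mean(axis=0))

    def test_tiny_width_rejected(self, bench100):
        with pytest.raises(ValueError):
            downscale_dataset(bench100, 5)

    def test_non_divisor_width_rejected(self, bench100):
        with pytest.raises(ValueError):
            downscale_dataset(bench100, 33)


def test_low_correlation_variant_is_weaker(truth):
    weak = low_correlation_truth()
    assert np.all(weak.texture_sds < truth.texture_sds)
    assert weak.pixel_noise_sd > truth.pixel_noise_sd
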