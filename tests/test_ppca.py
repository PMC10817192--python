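"""Unit tests for p-PCA fitting, likelihood, evidence and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from facecode.ppca import (DescriptionLengthReport, bic_bits, data_rank,
                           fit_ppca, log_evidence_bits, log_likelihood_bits,
                           n_free_parameters, select_p, uniform_code_length)


def _anisotropic(rng, n, d, sds=None):
    sds = np.linspace(3.0, 0.5, d) if sds is None else np.asarray(sds)
    return rng.standard_normal((n, d)) * sds + rng.uniform(-2, 2, d)


class TestFit:
    def test_two_point_dataset(self):
        # rows (2,0), (0,2): mean (1,1); scatter [[2,-2],[-2,2]], unbiased
        # covariance equals it at N=2, eigenvalues (4, 0)
        x = 2.0 * np.eye(2)
        m = fit_ppca(x, 1)
        assert np.allclose(m.mean, [1.0, 1.0])
        assert np.isclose(m.eigenvalues[0], 4.0)
        cov = np.cov(x.T)  # independent route to the same eigenvalue
        assert np.isclose(np.linalg.eigvalsh(cov).max(), m.eigenvalues[0])

    def test_p_zero_keeps_mean_and_mean_eigenvalue(self, rng):
        x = _anisotropic(rng, 30, 4)
        m = fit_ppca(x, 0)
        assert m.p == 0 and m.axes.shape == (0, 4)
        cov = np.cov(x.T)
        assert np.isclose(m.residual_variance, np.trace(cov) / 4)

    def test_gram_route_matches_dense_eigendecomposition(self, rng):
        x = _anisotropic(rng, 20, 50)  # d > N triggers the Gram path
        m = fit_ppca(x, 10)
        dense = np.linalg.eigvalsh(np.cov(x.T))[::-1][:10]
        assert np.allclose(m.eigenvalues, dense, atol=1e-8)
        assert np.allclose(m.axes @ m.axes.T, np.eye(10), atol=1e-8)

    def test_p_above_rank_error_names_rank(self, rng):
        x = np.tile(rng.standard_normal(5), (8, 1)) + rng.standard_normal((8, 1))
        with pytest.raises(ValueError, match="rank"):
            fit_ppca(x, 4)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_ppca(np.ones((10, 3)), 1)


class TestLikelihood:
    def test_standard_normal_at_origin(self):
        m = fit_ppca(np.array([[1.0], [-1.0], [0.5], [-0.5]]), 0)
        m.mean[:] = 0.0
        m.residual_variance = 1.0
        s = log_likelihood_bits(m, np.array([[0.0]]), eps=1.0)
        assert np.isclose(s, 0.5 * np.log2(2 * np.pi), atol=1e-12)

    def test_halving_eps_adds_one_bit_per_coordinate(self, rng):
        x = _anisotropic(rng, 25, 6)
        m = fit_ppca(x, 2)
        s1 = log_likelihood_bits(m, x, eps=1.0)
        s2 = log_likelihood_bits(m, x, eps=0.5)
        assert np.isclose(s2 - s1, 25 * 6, atol=1e-9)

    def test_matches_dense_gaussian_density(self, rng):
        x = _anisotropic(rng, 40, 3)
        m = fit_ppca(x, 1)
        # oracle: dense multivariate normal with the reconstructed covariance
        cov = (m.axes.T * (m.eigenvalues - m.residual_variance)) @ m.axes \
            + m.residual_variance * np.eye(3)
        from scipy.stats import multivariate_normal
        ll = multivariate_normal(mean=m.mean, cov=cov).logpdf(x).sum()
        assert np.isclose(log_likelihood_bits(m, x, 1.0), -ll / np.log(2), atol=1e-6)

    def test_additive_over_disjoint_subsets(self, rng):
        x = _anisotropic(rng, 30, 4)
        m = fit_ppca(x, 2)
        total = log_likelihood_bits(m, x, 1.0)
        parts = log_likelihood_bits(m, x[:11], 1.0) + log_likelihood_bits(m, x[11:], 1.0)
        assert np.isclose(total, parts, atol=1e-8)

    def test_degenerate_residual_rejected(self, rng):
        x = _anisotropic(rng, 10, 3)
        m = fit_ppca(x, 1)
        m.residual_variance = 0.0
        with pytest.raises(ValueError, match="residual"):
            log_likelihood_bits(m, x, 1.0)


class TestEvidence:
    def test_decomposition_is_exact(self, rng):
        x = _anisotropic(rng, 30, 8)
        rep = log_evidence_bits(x, 3, 1.0)
        assert np.isclose(rep.total_bits, rep.empirical_entropy_bits + rep.occam_bits,
                          atol=1e-6)
        assert np.isclose(rep.bits_per_sample, rep.total_bits / 30)

    @pytest.mark.parametrize("n,d,p", [(20, 5, 1), (50, 10, 3), (30, 200, 4), (12, 4, 2)])
    def test_occam_length_positive(self, rng, n, d, p):
        x = _anisotropic(rng, n, d, sds=1 + 5 * np.exp(-np.arange(d) / 3))
        assert log_evidence_bits(x, p, 1.0).occam_bits > 0

    def test_halving_eps_adds_nd_bits(self, rng):
        x = _anisotropic(rng, 25, 6)
        r1 = log_evidence_bits(x, 2, 1.0)
        r2 = log_evidence_bits(x, 2, 0.5)
        assert np.isclose(r2.total_bits - r1.total_bits, 25 * 6, atol=1e-8)
        assert np.isclose(r2.occam_bits, r1.occam_bits, atol=1e-8)

    def test_rotation_invariance(self, rng):
        x = _anisotropic(rng, 30, 5)
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        a = log_evidence_bits(x - x.mean(0), 2, 1.0).total_bits
        b = log_evidence_bits((x - x.mean(0)) @ q, 2, 1.0).total_bits
        assert np.isclose(a, b, atol=1e-6)

    def test_undersampled_regime_is_finite_and_fast(self, rng):
        x = rng.standard_normal((40, 5000)) * 2 + 10
        rep = log_evidence_bits(x, 10, 1.0)
        assert np.isfinite(rep.total_bits)

    def test_p_at_rank_with_zero_residual_rejected(self, rng):
        z = rng.standard_normal((10, 2))
        x = z @ rng.standard_normal((2, 6))  # rank 2 in d=6
        with pytest.raises(ValueError, match="rank|residual"):
            log_evidence_bits(x, 2, 1.0)

    def test_report_rejects_non_finite(self):
        with pytest.raises(FloatingPointError):
            DescriptionLengthReport(total_bits=np.nan, empirical_entropy_bits=1.0,
                                    occam_bits=1.0, precision=1.0, n_vectors=2, d=1, p=0)


class TestBic:
    def test_parameter_count(self):
        assert n_free_parameters(1, 0) == 2          # mean + variance
        assert n_free_parameters(5, 2) == 5 + 10 - 3 + 2 + 1

    def test_doubling_n_adds_half_k_bits_to_penalty(self, rng):
        x = _anisotropic(rng, 40, 3)
        m = fit_ppca(x, 1)
        k = n_free_parameters(3, 1)
        pen1 = bic_bits(x, 1, 1.0) - log_likelihood_bits(m, x, 1.0)
        xx = np.vstack([x, x])
        m2 = fit_ppca(xx, 1)
        pen2 = bic_bits(xx, 1, 1.0) - log_likelihood_bits(m2, xx, 1.0)
        assert np.isclose(pen2 - pen1, k / 2, atol=1e-9)


class TestUniformBaseline:
    def test_eight_bits_per_coordinate(self):
        # R/eps = 256 -> exactly 8 bits per coordinate
        base = uniform_code_length(400, 75000, vbar=256.0 ** 2 / 12.0, eps=1.0)
        assert np.isclose(base.l0_bits_per_sample_coordinate, 8.0)
        assert np.isclose(base.total_bits, 240_000_000.0)

    @given(b=st.integers(min_value=1, max_value=16))
    @settings(deadline=None, max_examples=16)
    def test_variance_matching_algebra(self, b):
        eps = 0.25
        vbar = eps ** 2 * 2.0 ** (2 * b) / 12.0
        base = uniform_code_length(10, 3, vbar, eps)
        assert np.isclose(base.l0_bits_per_sample_coordinate, b)

    def test_range_equal_to_precision_costs_nothing(self):
        base = uniform_code_length(5, 2, vbar=0.5 ** 2 / 12.0, eps=0.5)
        assert np.isclose(base.total_bits, 0.0)


class TestSelectP:
    def test_singleton_grid(self, rng):
        x = _anisotropic(rng, 40, 6)
        p_star, curve = select_p(x, p_grid=[3], method="evidence")
        assert p_star == 3 and set(curve) >= {3}

    def test_planted_dimensionality_recovered(self, rng):
        d, q, n = 30, 5, 1000
        w = np.linalg.qr(rng.standard_normal((d, q)))[0]
        x = (rng.standard_normal((n, q)) * [6, 5, 4, 3.5, 3]) @ w.T \
            + rng.standard_normal((n, d))
        p_star, _ = select_p(x, p_grid=range(0, 12), method="evidence")
        assert p_star == q

    def test_crossval_close_to_evidence(self, rng):
        d, q, n = 20, 3, 400
        w = np.linalg.qr(rng.standard_normal((d, q)))[0]
        x = (rng.standard_normal((n, q)) * [6, 5, 4]) @ w.T + rng.standard_normal((n, d))
        p_ev, _ = select_p(x, p_grid=range(0, 8), method="evidence")
        p_cv, _ = select_p(x, p_grid=range(0, 8), method="crossval", K=5, seed=0)
        assert abs(p_ev - p_cv) <= 2

    def test_k_above_n_rejected(self, rng):
        x = _anisotropic(rng, 10, 3)
        with pytest.raises(ValueError, match="K"):
            select_p(x, p_grid=[1], method="crossval", K=11)

    def test_rank_helper(self, rng):
        z = rng.standard_normal((15, 3))
        x = z @ rng.standard_normal((3, 9))
        assert data_rank(x) == 3
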