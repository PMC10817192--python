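"""Probabilistic PCA with exact likelihood, Bayesian evidence and description length.

A ``p``-PCA model describes ``d``-dimensional vectors as Gaussian with covariance

    Sigma = sum_{i<=p} (lambda_i - sigma^2) e_i e_i^T + sigma^2 I,

i.e. ``p`` retained principal directions with individual variances and an
isotropic residual variance on the discarded subspace.  The description length
of a dataset ``D`` under the model at per-coordinate precision ``eps`` is

    L(D) = -log2 P(D) - N d log2(eps)   [bits]

where ``P(D)`` is the Bayesian evidence (marginal likelihood).  ``L`` splits as
``L = S + O`` with the empirical entropy ``S = -log2 P(D|theta*) - N d log2 eps``
and the Occam length ``O = L - S`` paying for the parameters.

The evidence integral uses: a uniform prior on the ``p``-frame (Stiefel
manifold), Jeffreys ``dl/l`` priors on the retained variances and on the
residual variance, constrained to the top-p ordering
``l_1 >= ... >= l_p >= v`` (both integrated exactly as inverse-Gamma
integrals around the dominant configuration), and a flat prior on the mean
with density ``(2 pi vbar)^{-d/2}`` where ``vbar`` is the mean per-coordinate
variance of the training data; the mean is integrated exactly as well.  Only
the integral over the axis frame is approximated: each axis-rotation mode is
integrated by 1-D quadrature when it pairs with a nonzero sample eigenvalue
and by Laplace's method otherwise.  With these choices the evidence is exactly covariant
under a joint rescaling of the data and the precision, so description lengths
of rescaled coordinate sets (e.g. landmarks at a lower resolution, with the
matching precision) are invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GaussianPCAModel",
    "DescriptionLengthReport",
    "UniformBaseline",
    "fit_ppca",
    "log_likelihood_bits",
    "log_evidence_bits",
    "bic_bits",
    "uniform_code_length",
    "select_p",
    "n_free_parameters",
]

_LN2 = np.log(2.0)

# eigenvalues this far (relatively) below the top one are treated as degenerate
_EIG_FLOOR_REL = 1e-12


@dataclass
class GaussianPCAModel:
    """A fitted p-PCA model.

    ``eigenvalues`` use the unbiased (N-1) normalisation of the sample
    covariance; ``residual_variance`` is the mean of the discarded eigenvalues.
    """

    mean: np.ndarray            # (d,)
    axes: np.ndarray            # (p, d), orthonormal rows
    eigenvalues: np.ndarray     # (p,), descending
    residual_variance: float
    n_train: int
    d: int
    p: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float).reshape(self.p, self.d)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.p:
            gram = self.axes @ self.axes.T
            if not np.allclose(gram, np.eye(self.p), atol=1e-8):
                raise ValueError("axes are not orthonormal")
            if np.any(np.diff(self.eigenvalues) > 1e-12):
                raise ValueError("eigenvalues must be non-increasing")


@dataclass
class DescriptionLengthReport:
    """Total description length and its entropy/Occam decomposition, in bits."""

    total_bits: float
    empirical_entropy_bits: float
    occam_bits: float
    precision: float
    n_vectors: int
    d: int
    p: int
    bits_per_sample: float = field(init=False)
    bits_per_sample_per_coordinate: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("total_bits", "empirical_entropy_bits", "occam_bits"):
            if not np.isfinite(getattr(self, name)):
                raise FloatingPointError(f"non-finite description length term: {name}")
        self.bits_per_sample = self.total_bits / self.n_vectors
        self.bits_per_sample_per_coordinate = self.bits_per_sample / self.d


@dataclass
class UniformBaseline:
    """Baseline cost of independent uniform coordinates matching the data variance."""

    R: float
    precision: float
    n_vectors: int
    d: int
    l0_bits_per_sample_coordinate: float = field(init=False)
    total_bits: float = field(init=False)

    def __post_init__(self) -> None:
        self.l0_bits_per_sample_coordinate = np.log2(self.R / self.precision)
        self.total_bits = self.n_vectors * self.d * self.l0_bits_per_sample_coordinate


# ---------------------------------------------------------------------------
# spectra


def _centered_spectrum(data: np.ndarray):
    """Scatter eigen-decomposition of centred data via the smaller Gram side.

    Returns ``(n, d, mean, s, vectors, trace)`` where ``s`` are the descending
    eigenvalues of the scatter matrix ``Xc^T Xc`` (length min(n-1, d), clipped
    at 0), ``vectors`` the matching orthonormal axes (rows), and ``trace`` the
    full scatter trace.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D (N, d) matrix")
    n, d = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    mean = x.mean(axis=0)
    xc = x - mean
    trace = float(np.sum(xc * xc))
    if trace <= 0.0:
        raise ValueError("data has zero variance (constant rows)")
    r_max = min(n - 1, d)
    if d <= n:
        scat = xc.T @ xc
        w, v = np.linalg.eigh(scat)
        order = np.argsort(w)[::-1][:r_max]
        s = np.clip(w[order], 0.0, None)
        vecs = v[:, order].T
    else:
        gram = xc @ xc.T
        w, u = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1][:r_max]
        s = np.clip(w[order], 0.0, None)
        nz = s > _EIG_FLOOR_REL * s[0]
        vecs = np.zeros((r_max, d))
        vecs[nz] = (xc.T @ u[:, order[nz]] / np.sqrt(s[nz])).T
    return n, d, mean, s, vecs, trace


def _rank(s: np.ndarray) -> int:
    if s.size == 0:
        return 0
    return int(np.sum(s > _EIG_FLOOR_REL * s[0]))


def data_rank(data: np.ndarray) -> int:
    """Numerical rank of the centred data matrix."""
    _, _, _, s, _, _ = _centered_spectrum(data)
    return _rank(s)


def fit_ppca(data: np.ndarray, p: int) -> GaussianPCAModel:
    """Fit a p-PCA model: mean, top-p axes of the unbiased covariance, residual.

    The covariance uses the unbiased (N-1) normalisation.  ``sigma^2`` is the
    mean of the discarded eigenvalues, ``(trace(C) - sum_i<=p lambda_i)/(d-p)``
    (zero when ``p`` equals the full dimension).
    """
    n, d, mean, s, vecs, trace = _centered_spectrum(data)
    rank = _rank(s)
    p = int(p)
    if p < 0 or p > min(d, n - 1):
        raise ValueError(f"p={p} outside [0, min(d, N-1)={min(d, n - 1)}]")
    if p > rank:
        raise ValueError(f"p={p} exceeds the data rank {rank}")
    lam = s[:p] / (n - 1)
    if p < d:
        resid = (trace / (n - 1) - lam.sum()) / (d - p)
    else:
        resid = 0.0
    return GaussianPCAModel(
        mean=mean,
        axes=vecs[:p],
        eigenvalues=lam,
        residual_variance=max(float(resid), 0.0),
        n_train=n,
        d=d,
        p=p,
    )


# ---------------------------------------------------------------------------
# likelihood


def log_likelihood_bits(model: GaussianPCAModel, data: np.ndarray, eps: float) -> float:
    """Empirical entropy S = -log2 P(D|theta*) - N d log2(eps), in bits.

    The density is the model's Gaussian (low-rank plus isotropic residual);
    the precision term is paid per coordinate of every vector.  Additive over
    rows at fixed parameters.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n, d = x.shape
    if d != model.d:
        raise ValueError(f"data width {d} != model dimension {model.d}")
    if eps <= 0:
        raise ValueError("precision must be positive")
    p = model.p
    sig2 = model.residual_variance
    xc = x - model.mean
    if p < d and sig2 <= 0.0:
        raise ValueError("degenerate density: residual variance is zero with p < d")
    if p:
        if np.any(model.eigenvalues <= 0):
            raise ValueError("degenerate density: non-positive retained eigenvalue")
        proj = xc @ model.axes.T                      # (n, p)
        q_proj = np.sum(proj * proj / model.eigenvalues, axis=1)
        logdet = float(np.sum(np.log(model.eigenvalues)))
    else:
        proj = None
        q_proj = np.zeros(n)
        logdet = 0.0
    if p < d:
        sq = np.sum(xc * xc, axis=1)
        if p:
            sq = sq - np.sum(proj * proj, axis=1)
        q_resid = np.clip(sq, 0.0, None) / sig2
        logdet += (d - p) * np.log(sig2)
    else:
        q_resid = 0.0
    neg_ll_nats = 0.5 * (n * d * np.log(2 * np.pi) + n * logdet + np.sum(q_proj + q_resid))
    return float(neg_ll_nats / _LN2 - n * d * np.log2(eps))


# ---------------------------------------------------------------------------
# evidence


def _ln_inv_stiefel_volume(d: int, p: int) -> float:
    """ln of the inverse volume of the Stiefel manifold V_p(R^d) (uniform axis prior)."""
    i = np.arange(1, p + 1)
    return float(-p * np.log(2.0) + np.sum(gammaln((d - i + 1) / 2.0) - ((d - i + 1) / 2.0) * np.log(np.pi)))


_MODE_NODES = 240     # quadrature nodes per axis-rotation mode
_MODE_HALFWIDTH = 9.0  # half-width in curvature-scaled units


def _ln_gauss_peak(kappa):
    """ln of the Gaussian single-peak integral sqrt(2*pi/kappa)."""
    return 0.5 * (np.log(2 * np.pi) - np.log(kappa))


def _mode_quadrature(s_i: float, s_j: np.ndarray, kappa: np.ndarray, n: int,
                     pool_c: float | None, a_v: float | None) -> np.ndarray:
    """Exact 1-D integrals of the axis-rotation mode factors around their peak.

    For a Givens rotation of angle phi mixing retained axis i (sample scatter
    eigenvalue ``s_i``) with direction j, the scale-marginalised integrand is

      retained-retained:  F = [a_i(phi) a_j(phi) / (s_i s_j)]^{-(N-1)/2}
      retained-residual:  F = [a_i(phi)/s_i]^{-(N-1)/2} [C(phi)/C]^{-a_v}

    with a_i = s_i cos^2 + s_j sin^2, a_j the mirror, and C(phi) = C +
    (s_i - s_j) sin^2 phi the rotated residual pool.  The integral runs over
    (-pi/4, pi/4); peaks swapped beyond that range are counted by the explicit
    multiplicity factor instead.  Vectorised over ``s_j``.
    """
    s_j = np.atleast_1d(np.asarray(s_j, dtype=float))
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    out = np.empty(s_j.shape)
    flat = kappa < 1e-10  # near-degenerate pair: integrand ~ 1
    out[flat] = np.log(np.pi / 2.0)
    if np.all(flat):
        return out
    kp = kappa[~flat]
    sj = s_j[~flat]
    half = np.minimum(_MODE_HALFWIDTH / np.sqrt(kp), np.pi / 4)
    t = np.linspace(-1.0, 1.0, _MODE_NODES)
    phi = half[:, None] * t[None, :]
    sin2 = np.sin(phi) ** 2
    a_i = s_i + (sj[:, None] - s_i) * sin2
    ln_f = -0.5 * (n - 1) * (np.log(a_i) - np.log(s_i))
    if pool_c is None:
        a_j = sj[:, None] + (s_i - sj[:, None]) * sin2
        ln_f = ln_f - 0.5 * (n - 1) * (np.log(a_j) - np.log(sj[:, None]))
    else:
        c_phi = pool_c + (s_i - sj[:, None]) * sin2
        ln_f = ln_f - a_v * (np.log(c_phi) - np.log(pool_c))
    mx = ln_f.max(axis=1, keepdims=True)
    dphi = 2.0 * half / (_MODE_NODES - 1)
    out[~flat] = mx[:, 0] + np.log(np.trapezoid(np.exp(ln_f - mx), axis=1) * dphi)
    return out


def _ln_axes_integral(s: np.ndarray, d: int, p: int, n: int) -> float:
    """Laplace/quadrature value of the axis (Stiefel) integral, peak-mass form.

    Modes paired with a nonzero sample eigenvalue are integrated exactly by
    quadrature; modes pointing into the sample null space use their Gaussian
    approximation.  The retained variances are constrained to be ordered and
    at least the residual variance (the top-p model class), so each covariance
    corresponds to exactly 2^p sign choices of the axes: that is the peak
    multiplicity.  The scale integrals themselves are evaluated without the
    ordering truncation, whose effect is exponentially small in the spectral
    gaps around the dominant configuration.
    """
    r = _rank(s)
    c_pool = float(np.sum(s[p:]))  # residual scatter pool
    a_v = 0.5 * (n - 1) * (d - p)
    total = _ln_inv_stiefel_volume(d, p)
    total += p * np.log(2.0)  # sign-flip peak multiplicity
    for i in range(p):
        s_i = float(s[i])
        # retained-retained pairs
        sj = s[i + 1 : p]
        if sj.size:
            kap = (n - 1) * (s_i - sj) * (1.0 / sj - 1.0 / s_i)
            total += float(np.sum(_mode_quadrature(s_i, sj, kap, n, None, None)))
        # retained-residual pairs with nonzero sample eigenvalue
        sj = s[p:r]
        if sj.size:
            kap = (n - 1) * (s_i - sj) * (1.0 / s_i + (d - p) / c_pool)
            total += float(np.sum(_mode_quadrature(s_i, sj, kap, n, c_pool, a_v)))
        # modes into the sample null space: Gaussian
        n_zero = d - max(r, p)
        if n_zero:
            kap0 = (n - 1) * s_i * (1.0 / s_i + (d - p) / c_pool)
            total += n_zero * float(_ln_gauss_peak(kap0))
    return total


def _log_evidence_nats(n: int, d: int, s: np.ndarray, trace: float, p: int) -> float:
    """ln of the Bayesian evidence P(D) of the p-PCA model (priors in module docstring).

    ``s`` are the descending eigenvalues of the scatter matrix ``Xc^T Xc``
    (implicitly padded with zeros up to ``d``); ``trace`` their full sum.
    """
    vbar = trace / (n * d)
    lnp = -0.5 * n * d * np.log(2 * np.pi) - 0.5 * d * np.log(n) - 0.5 * d * np.log(vbar)
    if p > 0:
        s_top = s[:p]
        if np.any(s_top <= 0):
            raise ValueError("retained eigenvalue is zero: p exceeds the effective rank")
        lnp += np.sum(gammaln((n - 1) / 2.0) - ((n - 1) / 2.0) * np.log(s_top / 2.0))
        lnp += _ln_axes_integral(s, d, p, n)
    if p < d:
        c_v = 0.5 * (trace - float(np.sum(s[:p])))
        if c_v <= 0:
            raise ValueError("residual variance is zero: p equals the data rank")
        a_v = 0.5 * (n - 1) * (d - p)
        lnp += gammaln(a_v) - a_v * np.log(c_v)
    if not np.isfinite(lnp):
        raise FloatingPointError("non-finite evidence (ill-conditioned spectrum)")
    return float(lnp)


def log_evidence_bits(train: np.ndarray, p: int, eps: float) -> DescriptionLengthReport:
    """Exact-marginal description length of ``train`` under p-PCA at precision ``eps``.

    Returns the evidence-based total ``L``, the empirical entropy ``S`` at the
    fitted parameters, and the Occam length ``O = L - S``.  Supports the
    strongly undersampled regime N << d (Gram-side eigendecomposition,
    log-domain arithmetic throughout).
    """
    if eps <= 0:
        raise ValueError("precision must be positive")
    n, d, mean, s, vecs, trace = _centered_spectrum(train)
    rank = _rank(s)
    p = int(p)
    if p < 0 or p > min(d, n - 1):
        raise ValueError(f"p={p} outside [0, min(d, N-1)={min(d, n - 1)}]")
    if p > rank:
        raise ValueError(f"p={p} exceeds the data rank {rank}")
    lnp = _log_evidence_nats(n, d, s, trace, p)
    total = -lnp / _LN2 - n * d * np.log2(eps)
    model = GaussianPCAModel(
        mean=mean, axes=vecs[:p], eigenvalues=s[:p] / (n - 1),
        residual_variance=max(float((trace / (n - 1) - s[:p].sum() / (n - 1)) / (d - p)), 0.0) if p < d else 0.0,
        n_train=n, d=d, p=p,
    )
    entropy = log_likelihood_bits(model, train, eps)
    return DescriptionLengthReport(
        total_bits=float(total),
        empirical_entropy_bits=float(entropy),
        occam_bits=float(total - entropy),
        precision=float(eps),
        n_vectors=n,
        d=d,
        p=p,
    )


def n_free_parameters(d: int, p: int) -> int:
    """Free parameters of p-PCA: mean d, axes pd - p(p+1)/2, p eigenvalues, 1 residual."""
    return d + d * p - p * (p + 1) // 2 + p + 1


def bic_bits(train: np.ndarray, p: int, eps: float) -> float:
    """BIC approximation to the description length: S(theta*) + (k/2) log2 N."""
    x = np.asarray(train, dtype=float)
    n, d = x.shape
    model = fit_ppca(x, p)
    s_bits = log_likelihood_bits(model, x, eps)
    k = n_free_parameters(d, p)
    return float(s_bits + 0.5 * k * np.log2(n))


def uniform_code_length(n: int, d: int, vbar: float, eps: float) -> UniformBaseline:
    """Cost of storing N*d independent uniform coordinates with variance ``vbar``.

    ``R = sqrt(12 vbar)`` so that a uniform density on an interval of length R
    has the empirical mean per-coordinate variance; each coordinate then costs
    ``l0 = log2(R/eps)`` bits.
    """
    if vbar <= 0 or eps <= 0:
        raise ValueError("vbar and eps must be positive")
    return UniformBaseline(R=float(np.sqrt(12.0 * vbar)), precision=float(eps), n_vectors=n, d=d)


# ---------------------------------------------------------------------------
# model selection


def default_p_grid(n: int, d: int) -> list[int]:
    """0..10 by 1, then ~25% geometric steps, up to min(d, N-1)."""
    cap = min(d, n - 1)
    grid = list(range(0, min(10, cap) + 1))
    g = 12
    while g < cap:
        grid.append(g)
        g = max(g + 1, int(round(g * 1.25)))
    if cap > 10 and cap not in grid:
        grid.append(cap)
    return sorted(set(grid))


def select_p(
    train: np.ndarray,
    p_grid=None,
    method: str = "evidence",
    K: int = 5,
    seed: int = 0,
    eps: float = 1.0,
):
    """Choose the number of components ``p*``; returns ``(p_star, curve)``.

    ``method="evidence"`` minimises the description length L (equivalently
    maximises the evidence); ``method="crossval"`` maximises the mean held-out
    log-likelihood over K folds.  Ties break toward smaller p.  ``curve`` maps
    each candidate p to its score (L bits, or mean held-out S bits per sample;
    for both, smaller is better).
    """
    x = np.asarray(train, dtype=float)
    n, d = x.shape
    n_, d_, mean, s, vecs, trace = _centered_spectrum(x)
    rank = _rank(s)
    densify = p_grid is None  # only refine the automatic grid, never a user's
    if p_grid is None:
        p_grid = default_p_grid(n, d)
    p_grid = sorted({int(p) for p in p_grid})
    if any(p < 0 or p > min(d, n - 1) for p in p_grid):
        raise ValueError("p_grid outside [0, min(d, N-1)]")

    if method == "evidence":
        curve = {}

        def feasible(p: int) -> bool:
            return p <= rank and not (p == rank and p < d)

        for p in p_grid:
            if not feasible(p):
                continue
            lnp = _log_evidence_nats(n, d, s, trace, p)
            curve[p] = -lnp / _LN2 - n * d * np.log2(eps)
        if not curve:
            raise ValueError("no feasible p in grid")
        if densify:  # refine the automatic grid around the running argmin
            p0 = min(curve, key=lambda p: (curve[p], p))
            for p in (p0 - 2, p0 - 1, p0 + 1, p0 + 2):
                if 0 <= p and feasible(p) and p not in curve:
                    lnp = _log_evidence_nats(n, d, s, trace, p)
                    curve[p] = -lnp / _LN2 - n * d * np.log2(eps)
        p_star = min(curve, key=lambda p: (curve[p], p))
        return p_star, curve

    if method == "crossval":
        if K > n:
            raise ValueError(f"K={K} exceeds N={n}")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, K)
        curve = {}
        for p in p_grid:
            scores = []
            ok = True
            for k in range(K):
                test_idx = folds[k]
                train_idx = np.concatenate([folds[j] for j in range(K) if j != k])
                xt = x[train_idx]
                try:
                    model = fit_ppca(xt, p)
                except ValueError:
                    ok = False
                    break
                if model.p < model.d and model.residual_variance <= 0:
                    ok = False
                    break
                s_bits = log_likelihood_bits(model, x[test_idx], eps)
                scores.append(s_bits / len(test_idx))
            if ok:
                curve[p] = float(np.mean(scores))
        if not curve:
            raise ValueError("no feasible p in grid")
        p_star = min(curve, key=lambda p: (curve[p], p))
        return p_star, curve

    raise ValueError(f"unknown method {method!r}")
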