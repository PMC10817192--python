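"""Face-processing task evaluations: identity recognition, reconstruction, gender.

All tasks score candidates with a rank-p Mahalanobis distance whose metric is
the training-fold p-PCA covariance: the distance between ``u`` and ``v`` is
the Euclidean distance of their first-p principal projections whitened by the
eigenvalues.  Every fit (PCA models, mean shapes, class centroids) uses
training folds only; targets never enter a fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codes import ConcatenatedCode, EigenfaceCode
from .ppca import GaussianPCAModel, data_rank, fit_ppca
from .synth import FaceDataset
from .warp import mean_shape_of, uniformize_dataset

__all__ = ["MahalanobisMetric", "mahalanobis", "chance_level", "recognition_error",
           "ReconEvalConfig", "reconstruct_and_score", "gender_error"]

COORDINATE_KINDS = ("raw", "uniformed", "shape", "concatenated")


@dataclass
class MahalanobisMetric:
    """Rank-p Mahalanobis metric derived from a fitted p-PCA model."""

    model: GaussianPCAModel
    p: int
    eigenvalue_floor: float = 1e-12   # relative to the top eigenvalue
    l2_weight: float = 0.0            # optional Euclidean blend, off by default

    def __post_init__(self) -> None:
        if self.p > self.model.p:
            raise ValueError(f"metric rank {self.p} exceeds model rank {self.model.p}")
        lam = self.model.eigenvalues[: self.p]
        keep = lam > self.eigenvalue_floor * lam[0]
        self._axes = self.model.axes[: self.p][keep]
        self._inv_sd = 1.0 / np.sqrt(lam[keep])

    def whiten(self, x: np.ndarray) -> np.ndarray:
        """Whitened rank-p projections of (rows of) ``x``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.model.mean) @ self._axes.T * self._inv_sd

    def distance(self, u: np.ndarray, v: np.ndarray) -> float:
        du = self.whiten(u) - self.whiten(v)
        d2 = float(np.sum(du * du))
        if self.l2_weight:
            diff = np.asarray(u, float).ravel() - np.asarray(v, float).ravel()
            d2 += self.l2_weight * float(np.sum(diff * diff))
        return float(np.sqrt(d2))


def mahalanobis(u: np.ndarray, v: np.ndarray, metric: MahalanobisMetric) -> float:
    """Rank-p Mahalanobis distance between two vectors under ``metric``."""
    return metric.distance(u, v)


def chance_level(n_identities: int) -> float:
    """Chance error of identity recognition: 1 - 1/N."""
    return 1.0 - 1.0 / n_identities


# ---------------------------------------------------------------------------
# coordinate extraction


def _coordinates(train: FaceDataset, test: FaceDataset, kind: str):
    """Training-fold and test-fold coordinate matrices for a coordinate kind.

    For warped kinds the training fold's mean shape drives the uniformation of
    every vector, including the test targets.
    """
    if kind == "raw":
        return train.images, test.images
    if kind == "shape":
        return train.landmarks, test.landmarks
    ms = mean_shape_of(train.landmarks, train.width, train.height)
    uni_tr = uniformize_dataset(train, ms)
    uni_te = uniformize_dataset(test, ms)
    if kind == "uniformed":
        return uni_tr.images, uni_te.images
    if kind == "concatenated":
        return (np.hstack([uni_tr.images, train.landmarks]),
                np.hstack([uni_te.images, test.landmarks]))
    raise ValueError(f"unknown coordinate kind {kind!r}; expected one of {COORDINATE_KINDS}")


def _subject_folds(subjects: list, K: int, seed: int):
    uniq = sorted(set(subjects))
    if K > len(uniq):
        raise ValueError(f"K={K} exceeds the number of subjects {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    return [{uniq[i] for i in chunk} for chunk in np.array_split(order, K)]


# ---------------------------------------------------------------------------
# identity recognition


def recognition_error(ds: FaceDataset, coordinate_kind: str = "uniformed",
                      p: int = 20, K: int = 5, seed: int = 0,
                      l2_weight: float = 0.0) -> float:
    """Cross-validated nearest-neighbour identity recognition error.

    Folds are over subjects; each fold's test split holds exactly one image
    per fold subject (alternating expressions, so half the targets smile),
    the other expression stays in the training split.  A target is recognised
    when its nearest training vector under the training-fold rank-p
    Mahalanobis metric belongs to the same subject.  Returns
    ``1 - n_success / (N_te * K)`` aggregated over folds.
    """
    for s in sorted(set(ds.subject_id)):
        exprs = {ds.expression[i] for i in ds.rows_where(subject=s)}
        if exprs != {"neutral", "smiling"}:
            raise ValueError(f"subject {s} lacks one of the two expressions")
    folds = _subject_folds(ds.subject_id, K, seed)
    n_success = 0
    n_targets = 0
    for fold_subjects in folds:
        ordered = sorted(fold_subjects)
        test_expr = {s: ("smiling" if i % 2 == 0 else "neutral") for i, s in enumerate(ordered)}
        te = [i for i in range(ds.n)
              if ds.subject_id[i] in fold_subjects and ds.expression[i] == test_expr[ds.subject_id[i]]]
        tr = sorted(set(range(ds.n)) - set(te))
        train = ds.subset(tr)
        test = ds.subset(te)
        x_tr, x_te = _coordinates(train, test, coordinate_kind)
        model = fit_ppca(x_tr, min(p, data_rank(x_tr)))
        metric = MahalanobisMetric(model, model.p, l2_weight=l2_weight)
        w_tr = metric.whiten(x_tr)
        w_te = metric.whiten(x_te)
        d2 = ((w_te[:, None, :] - w_tr[None, :, :]) ** 2).sum(axis=2)
        if l2_weight:
            raw_d2 = ((x_te[:, None, :] - x_tr[None, :, :]) ** 2).sum(axis=2)
            d2 = d2 + l2_weight * raw_d2
        nearest = np.argmin(d2, axis=1)
        for t_row, n_row in enumerate(nearest):
            n_targets += 1
            if test.subject_id[t_row] == train.subject_id[n_row]:
                n_success += 1
    return 1.0 - n_success / n_targets


# ---------------------------------------------------------------------------
# reconstruction


@dataclass
class ReconEvalConfig:
    """Configuration of the novel-face reconstruction benchmark.

    ``n_targets`` neutral images are held out; every code trains on the rest.
    The scoring metric is the rank-``p_d`` Mahalanobis distance built from the
    eigenface (raw-image) training covariance with ``p_d = N_tr - N_te - 2``.
    """

    p_grid: tuple = (5, 10, 20, 40)
    n_targets: int = 20
    seed: int = 0
    shape_weight: float | str = "balanced"   # concatenated-code shape-block weight

    def p_d(self, n_train: int) -> int:
        return n_train - self.n_targets - 2


def reconstruct_and_score(ds: FaceDataset, config: ReconEvalConfig | None = None,
                          codes=("RE", "Rc", "Rc-uniformed")) -> dict:
    """Mean perceptual distance between held-out targets and reconstructions.

    Targets are reconstructed with each code at each ``p`` of the grid and
    scored against the original with the fixed rank-p_d eigenface Mahalanobis
    metric.  ``Rc-uniformed`` is the concatenated code without the final
    de-uniformation (the uniformed reconstruction scored against the raw
    target).  Returns ``{"p_d": ..., code: {p: mean distance}}``.
    """
    config = config or ReconEvalConfig()
    rng = np.random.default_rng(config.seed)
    neutral = ds.rows_where(expression="neutral")
    if config.n_targets > len(neutral):
        raise ValueError("more targets requested than neutral images available")
    targets = rng.choice(neutral, size=config.n_targets, replace=False)
    tr = sorted(set(range(ds.n)) - set(targets.tolist()))
    train = ds.subset(tr)
    test = ds.subset(sorted(targets.tolist()))
    p_d = config.p_d(train.n)
    if p_d < 1 or p_d > min(train.n - 1, train.d_t):
        raise ValueError(f"metric rank p_d={p_d} infeasible for N_tr={train.n}")

    eigen_model = fit_ppca(train.images, p_d)
    metric = MahalanobisMetric(eigen_model, p_d)
    max_p = max(config.p_grid)
    if max_p > p_d:
        raise ValueError(f"reconstruction p={max_p} exceeds p_d={p_d}")

    out: dict = {"p_d": p_d, "n_train": train.n, "n_targets": test.n}
    re_code = EigenfaceCode(train, p=p_d)
    rc_code = ConcatenatedCode(train, p=min(train.n - 1, p_d),
                               shape_weight=config.shape_weight) if any(
        c.startswith("Rc") for c in codes) else None

    w_targets = metric.whiten(test.images)
    for code in codes:
        per_p = {}
        for p in sorted(set(list(config.p_grid) + ([p_d] if code == "RE" else []))):
            dists = []
            for row in range(test.n):
                img = test.image(row)
                lm = test.landmarks[row]
                if code == "RE":
                    coeff = re_code.model.axes[:p] @ (img.ravel() - re_code.model.mean)
                    rec = re_code.model.mean + coeff @ re_code.model.axes[:p]
                elif code in ("Rc", "Rc-uniformed"):
                    enc = rc_code.encode(img, lm)
                    enc.joint = enc.joint.copy()
                    enc.joint[p:] = 0.0
                    rec_img, _ = rc_code.decode(enc, deuniformize=(code == "Rc"))
                    rec = rec_img.ravel()
                else:
                    raise ValueError(f"unknown code {code!r}")
                dw = metric.whiten(rec) - w_targets[row]
                dists.append(float(np.sqrt(np.sum(dw * dw))))
            per_p[p] = float(np.mean(dists))
        out[code] = per_p
    return out


# ---------------------------------------------------------------------------
# gender classification


def gender_error(ds: FaceDataset, coordinate_kind: str = "uniformed",
                 p: int = 20, K: int = 5, seed: int = 0) -> float:
    """Cross-validated nearest-centroid gender classification error.

    Class centroids live in the whitened rank-p Mahalanobis space of the
    training fold; folds are over subjects so both images of a subject stay
    on the same side of the split.
    """
    folds = _subject_folds(ds.subject_id, K, seed)
    n_err = 0
    n_tot = 0
    for fold_subjects in folds:
        te = [i for i in range(ds.n) if ds.subject_id[i] in fold_subjects]
        tr = sorted(set(range(ds.n)) - set(te))
        train = ds.subset(tr)
        test = ds.subset(te)
        classes = sorted(set(train.gender))
        if len(classes) < 2:
            raise ValueError("training fold contains a single gender class")
        x_tr, x_te = _coordinates(train, test, coordinate_kind)
        model = fit_ppca(x_tr, min(p, data_rank(x_tr)))
        metric = MahalanobisMetric(model, model.p)
        w_tr = metric.whiten(x_tr)
        w_te = metric.whiten(x_te)
        centroids = np.stack([
            w_tr[[g == c for g in train.gender]].mean(axis=0) for c in classes
        ])
        d2 = ((w_te[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        pred = np.argmin(d2, axis=1)
        for row, cls in enumerate(pred):
            n_tot += 1
            if classes[cls] != test.gender[row]:
                n_err += 1
    return n_err / n_tot
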