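"""Information gap between decoupled and eigenface codings.

The texture information gap ``G1`` is the difference in description length
between the raw and the uniformed image datasets, each compressed by its own
p-PCA model at texture precision ``eps_t = 1`` gray level.  The shape cost
``G2`` is the description length of the landmark dataset at shape precision
``eps_s``.  The information gap ``G = G1 - G2`` is positive exactly when
storing shape coordinates costs less than the uniformation saves — i.e. when
the decoupled code is the more efficient one.

Out-of-sample description lengths charge the evaluated set its empirical
entropy under the trained model plus the trainer's Occam length (parameters
are paid once, by the trainer).

Precision conventions: ``eps_t = 1`` always; ``eps_s = 0.1 * h / h_max``
where ``h_max`` is the native resolution.  Landmarks at resolution ``h`` are
the native ones scaled by ``h/h_max``, and this matching precision makes
shape description lengths exactly independent of resolution; the 0.1 factor
deliberately overestimates the shape cost, making a positive gap a
conservative verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ppca import fit_ppca, log_evidence_bits, log_likelihood_bits, select_p
from .synth import FaceDataset, downscale_dataset, generate_dataset
from .warp import mean_shape_of, uniformize_dataset

__all__ = ["GapReport", "shape_precision", "out_of_sample_bits", "texture_gap",
           "shape_cost", "information_gap", "compute_gap", "resolution_sweep",
           "expression_design_compare", "testset_gap_cv", "landmark_sweep"]


def shape_precision(height: int, native_height: int, base: float = 0.1) -> float:
    """Shape precision at resolution ``height``, native grid ``native_height``."""
    return base * height / native_height


@dataclass
class GapReport:
    """G1, G2 and G in bits, with the model choices behind them."""

    G1: float
    G2: float
    n_eval: int
    d_t: int
    d_s: int
    p_raw: int
    p_uniformed: int
    p_shape: int
    eps_t: float
    eps_s: float
    eval_kind: str = "train"
    K: int | None = None
    fold_G: np.ndarray | None = None
    G: float = field(init=False)

    def __post_init__(self) -> None:
        self.G = self.G1 - self.G2

    @property
    def favours_decoupling(self) -> bool:
        return self.G > 0

    @property
    def G_per_sample(self) -> float:
        return self.G / self.n_eval

    @property
    def G_per_sample_per_coordinate(self) -> float:
        return self.G / (self.n_eval * self.d_t)

    @property
    def G1_per_sample(self) -> float:
        return self.G1 / self.n_eval

    @property
    def G2_per_sample(self) -> float:
        return self.G2 / self.n_eval

    def fold_sem(self) -> float:
        if self.fold_G is None or len(self.fold_G) < 2:
            return 0.0
        return float(np.std(self.fold_G, ddof=1) / np.sqrt(len(self.fold_G)))


# ---------------------------------------------------------------------------
# description-length primitives


def out_of_sample_bits(train: np.ndarray, eval_data: np.ndarray, p: int, eps: float) -> float:
    """L of ``eval_data`` under the model trained on ``train``.

    The parameters are paid once, by the trainer; an evaluation set of
    ``N_eval`` vectors is charged its empirical entropy under the trained
    model plus the trainer's Occam length amortised at the trainer's
    per-sample rate, ``S(eval) + N_eval * O(train)/N_train``.  (Charging the
    full Occam length to an arbitrarily small evaluation set would make its
    per-sample description length diverge; only the entropy term genuinely
    varies with the evaluated set.)  For ``eval_data`` identical to ``train``
    this reduces exactly to the training-set description length.
    """
    report = log_evidence_bits(train, p, eps)
    if eval_data is train or (eval_data.shape == train.shape and np.array_equal(eval_data, train)):
        return report.total_bits
    model = fit_ppca(train, p)
    n_eval = eval_data.shape[0]
    return (log_likelihood_bits(model, eval_data, eps)
            + n_eval * report.occam_bits / report.n_vectors)


def _auto_p(train: np.ndarray, eps: float) -> int:
    p_star, _ = select_p(train, method="evidence", eps=eps)
    return p_star


def texture_gap(train_images, eval_images, train_uniformed, eval_uniformed,
                p: int | None = None, p_hat: int | None = None, eps_t: float = 1.0):
    """G1 = L_raw(eval raw) - L_uniformed(eval uniformed), in bits.

    ``p`` and ``p_hat`` default to evidence-selected values on the respective
    training sets.  Returns ``(G1, p, p_hat)``.
    """
    if eval_images.shape[0] != eval_uniformed.shape[0]:
        raise ValueError("mismatched evaluation set sizes")
    if p is None:
        p = _auto_p(train_images, eps_t)
    if p_hat is None:
        p_hat = _auto_p(train_uniformed, eps_t)
    l_raw = out_of_sample_bits(train_images, eval_images, p, eps_t)
    l_uni = out_of_sample_bits(train_uniformed, eval_uniformed, p_hat, eps_t)
    return float(l_raw - l_uni), p, p_hat


def shape_cost(train_landmarks, eval_landmarks, p_s: int | None = None,
               eps_s: float = 0.1):
    """G2 = description length of the landmark set, in bits; returns (G2, p_s)."""
    if p_s is None:
        p_s = _auto_p(train_landmarks, eps_s)
    g2 = out_of_sample_bits(train_landmarks, eval_landmarks, p_s, eps_s)
    return float(g2), p_s


def information_gap(G1: float, G2: float) -> float:
    """The information gap G = G1 - G2 (positive: decoupled coding wins)."""
    return G1 - G2


# ---------------------------------------------------------------------------
# dataset-level computation


def compute_gap(train: FaceDataset, eval_ds: FaceDataset | None = None,
                native_height: int | None = None, eval_kind: str = "train",
                p: int | None = None, p_hat: int | None = None,
                p_s: int | None = None, uniformation: bool = True) -> GapReport:
    """Full gap computation for a training set and an optional evaluation set.

    The mean shape and all models come from ``train`` only; ``eval_ds`` (if
    given) is uniformised with the training mean shape and charged
    out-of-sample description lengths.  ``uniformation=False`` short-circuits
    the warp (the uniformed set *is* the raw set): a null-pipeline control
    that forces G1 = 0.
    """
    if eval_ds is None:
        eval_ds = train
    native_height = native_height or train.height
    eps_t = 1.0
    eps_s = shape_precision(train.height, native_height)
    if uniformation:
        ms = mean_shape_of(train.landmarks, train.width, train.height)
        uni_train = uniformize_dataset(train, ms).images
        uni_eval = uni_train if eval_ds is train else uniformize_dataset(eval_ds, ms).images
    else:
        uni_train = train.images
        uni_eval = eval_ds.images
    g1, p, p_hat = texture_gap(train.images, eval_ds.images, uni_train, uni_eval,
                               p=p, p_hat=p_hat, eps_t=eps_t)
    g2, p_s = shape_cost(train.landmarks, eval_ds.landmarks, p_s=p_s, eps_s=eps_s)
    return GapReport(
        G1=g1, G2=g2, n_eval=eval_ds.n, d_t=train.d_t, d_s=train.d_s,
        p_raw=p, p_uniformed=p_hat, p_shape=p_s, eps_t=eps_t, eps_s=eps_s,
        eval_kind=eval_kind,
    )


def resolution_sweep(ds: FaceDataset, widths, **kwargs) -> list[GapReport]:
    """Training-set gap at each width (descending from the native resolution).

    All p values are re-selected per resolution; the shape precision scales
    with the resolution so that G2 stays put.
    """
    reports = []
    for w in widths:
        sub = downscale_dataset(ds, w)
        reports.append(compute_gap(sub, native_height=ds.height,
                                   eval_kind=f"train@w={w}", **kwargs))
    return reports


def expression_design_compare(ds: FaceDataset, n_train: int | None = None,
                              seed: int = 0):
    """Matched-size neutral vs mixed training designs; returns their GapReports.

    The *neutral* design takes ``n_train`` distinct subjects' neutral images;
    the *mixed* design takes both expressions of ``n_train/2`` different
    subjects.  The two subject pools are disjoint; ``n_train`` must be even.
    """
    subjects = sorted(set(ds.subject_id))
    if n_train is None:
        n_train = 2 * (len(subjects) // 3)
    if n_train % 2:
        raise ValueError("n_train must be even (the mixed design halves it)")
    if 3 * n_train // 2 > len(subjects):
        raise ValueError("not enough subjects for disjoint neutral/mixed pools")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    neutral_subjects = {subjects[i] for i in order[:n_train]}
    mixed_subjects = {subjects[i] for i in order[n_train : n_train + n_train // 2]}
    idx_neutral = [i for i in range(ds.n)
                   if ds.subject_id[i] in neutral_subjects and ds.expression[i] == "neutral"]
    idx_mixed = [i for i in range(ds.n) if ds.subject_id[i] in mixed_subjects]
    rep_n = compute_gap(ds.subset(idx_neutral), eval_kind="train-neutral")
    rep_m = compute_gap(ds.subset(idx_mixed), eval_kind="train-mixed")
    return rep_n, rep_m


def _subject_folds(ds: FaceDataset, K: int, seed: int):
    subjects = sorted(set(ds.subject_id))
    if K > len(subjects):
        raise ValueError(f"K={K} exceeds the number of subjects {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    return [{subjects[i] for i in chunk} for chunk in np.array_split(order, K)]


def testset_gap_cv(ds: FaceDataset, K: int = 5, seed: int = 0) -> dict:
    """K-fold cross-validated gaps for the two test designs of the study.

    *expression-overlap*: each fold's test set holds the smiling images of its
    subjects, whose neutral images remain in the training set.
    *non-overlapping*: the test set holds both expressions of the fold's
    subjects, which are absent from the training set.

    For each design and fold the training fold's own (in-sample) gap is
    paired with the test gap; the returned dict carries per-fold arrays,
    per-sample means, and one-sided significance (paired t-test and sign
    test) that the test gap exceeds the training gap.
    """
    folds = _subject_folds(ds, K, seed)
    out = {"K": K, "train_full": compute_gap(ds, eval_kind="train")}
    for design in ("overlap", "nonoverlap"):
        rows = {"G1_train": [], "G2_train": [], "G_train": [],
                "G1_test": [], "G2_test": [], "G_test": []}
        for fold_subjects in folds:
            if design == "overlap":
                te = [i for i in range(ds.n)
                      if ds.subject_id[i] in fold_subjects and ds.expression[i] == "smiling"]
                tr = [i for i in range(ds.n) if i not in set(te)]
            else:
                te = [i for i in range(ds.n) if ds.subject_id[i] in fold_subjects]
                tr = [i for i in range(ds.n) if ds.subject_id[i] not in fold_subjects]
            train = ds.subset(tr)
            test = ds.subset(te)
            rep_tr = compute_gap(train, eval_kind=f"{design}-trainfold")
            rep_te = compute_gap(train, test, eval_kind=f"{design}-test",
                                 p=rep_tr.p_raw, p_hat=rep_tr.p_uniformed, p_s=rep_tr.p_shape)
            rows["G1_train"].append(rep_tr.G1_per_sample)
            rows["G2_train"].append(rep_tr.G2_per_sample)
            rows["G_train"].append(rep_tr.G_per_sample)
            rows["G1_test"].append(rep_te.G1_per_sample)
            rows["G2_test"].append(rep_te.G2_per_sample)
            rows["G_test"].append(rep_te.G_per_sample)
        rows = {k: np.asarray(v) for k, v in rows.items()}
        diff = rows["G_test"] - rows["G_train"]
        t_res = stats.ttest_rel(rows["G_test"], rows["G_train"], alternative="greater")
        n_pos = int(np.sum(diff > 0))
        sign_p = float(stats.binomtest(n_pos, len(diff), alternative="greater").pvalue)
        out[design] = {
            **rows,
            "p_greater_ttest": float(t_res.pvalue),
            "p_greater_signtest": sign_p,
        }
    return out


def landmark_sweep(truth_factory, n_landmark_grid, n_subjects: int = 50,
                   seed: int = 0) -> list[dict]:
    """Training-set gap as a function of the number of landmarks.

    ``truth_factory(n_landmarks)`` must return a ground truth whose landmark
    set refines the same contours.  Returns one record per grid point with
    ``n_landmarks``, ``d_s`` and the GapReport; the record after a sign change
    of G is flagged as the zero crossing.
    """
    records = []
    prev_sign = None
    for n_l in n_landmark_grid:
        truth = truth_factory(n_l)
        ds = generate_dataset(truth, n_subjects, 2, seed=seed)
        rep = compute_gap(ds, eval_kind=f"train@nl={n_l}")
        sign = np.sign(rep.G)
        records.append({
            "n_landmarks": n_l,
            "d_s": 2 * n_l,
            "report": rep,
            "zero_crossing": bool(prev_sign is not None and sign != prev_sign),
        })
        prev_sign = sign
    return records
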