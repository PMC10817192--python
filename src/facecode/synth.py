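"""Synthetic face datasets from a known decoupled generative model.

The generator emulates the structure of a landmark-annotated portrait
database (paired neutral/smiling images per subject, 8-bit grayscale, a
fixed set of landmarks on facial feature contours) while making the
decoupling assumption true *by construction*: per-subject texture lives on
the mean-shape (template) frame and varies along a few smooth, low-spatial-
frequency orthonormal fields; per-subject shape varies along a few smooth
orthonormal landmark modes; the smiling expression adds a single shape
direction confined to the mouth landmarks and leaves texture untouched.
Images are rendered by piecewise-affine warping of the subject texture from
the template landmarks to the subject landmarks, plus i.i.d. sensor noise
added after warping (noise arises at acquisition), re-quantised to 8 bits.

Landmark vectors are interleaved ``(x1, y1, ..., xk, yk)`` in pixel units.
Landmark order: jaw (head contour), left eye, right eye, mouth — each block
evenly spaced along its contour, so denser landmark sets refine the same
contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FaceDataset",
    "SyntheticGroundTruth",
    "make_template",
    "generate_dataset",
    "downscale_dataset",
    "default_truth",
    "low_correlation_truth",
]


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class FaceDataset:
    """Aligned images, landmarks and metadata at a fixed resolution.

    ``images`` is (N, w*h) with 8-bit gray values stored as floats;
    ``landmarks`` is (N, 2*n_landmarks), interleaved (x, y), real-valued.
    """

    images: np.ndarray
    landmarks: np.ndarray
    width: int
    height: int
    subject_id: list
    expression: list
    gender: list

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        n, d_t = self.images.shape
        if d_t != self.width * self.height:
            raise ValueError("image matrix width does not equal w*h")
        if self.landmarks.shape[0] != n or self.landmarks.shape[1] % 2:
            raise ValueError("landmark matrix shape mismatch")
        if not (len(self.subject_id) == len(self.expression) == len(self.gender) == n):
            raise ValueError("metadata length mismatch")
        xs = self.landmarks[:, 0::2]
        ys = self.landmarks[:, 1::2]
        if xs.min() < 0 or xs.max() >= self.width or ys.min() < 0 or ys.max() >= self.height:
            raise ValueError("landmark coordinates outside the image frame")
        pairs = list(zip(self.subject_id, self.expression))
        if len(set(pairs)) != n:
            raise ValueError("duplicate (subject, expression) pair")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def d_t(self) -> int:
        return self.images.shape[1]

    @property
    def d_s(self) -> int:
        return self.landmarks.shape[1]

    @property
    def n_landmarks(self) -> int:
        return self.d_s // 2

    def image(self, i: int) -> np.ndarray:
        return self.images[i].reshape(self.height, self.width)

    def subset(self, idx) -> "FaceDataset":
        idx = np.asarray(idx)
        return FaceDataset(
            images=self.images[idx].copy(),
            landmarks=self.landmarks[idx].copy(),
            width=self.width,
            height=self.height,
            subject_id=[self.subject_id[i] for i in idx],
            expression=[self.expression[i] for i in idx],
            gender=[self.gender[i] for i in idx],
        )

    def rows_where(self, subject=None, expression=None) -> np.ndarray:
        sel = np.ones(self.n, dtype=bool)
        if subject is not None:
            sel &= np.asarray([s == subject for s in self.subject_id])
        if expression is not None:
            sel &= np.asarray([e == expression for e in self.expression])
        return np.flatnonzero(sel)


# ---------------------------------------------------------------------------
# template


def _allocate_landmarks(n: int) -> tuple[int, int, int]:
    """Split n landmarks into (jaw, per-eye, mouth) blocks."""
    if n < 8:
        raise ValueError("need at least 8 landmarks")
    mouth = max(3, int(round(0.28 * n)))
    eye = max(2, int(round(0.15 * n)))
    jaw = n - mouth - 2 * eye
    while jaw < 1:  # shrink the larger blocks for tiny n
        if mouth > 3:
            mouth -= 1
        elif eye > 2:
            eye -= 1
        else:
            raise ValueError(f"cannot allocate {n} landmarks over the face features")
        jaw = n - mouth - 2 * eye
    return jaw, eye, mouth


def make_template(width: int, height: int, n_landmarks: int):
    """Deterministic smooth face-like template image with contour landmarks.

    The face is a bright head ellipse on a mid-gray background with two dark
    eye blobs and a dark mouth blob, all smooth Gaussian-profile features.
    Landmarks sit on the head contour, the two eye circles and the mouth
    ellipse.  Returns ``(image, landmarks)`` with the image float (w*h gray
    values in [0, 255]) and interleaved landmark coordinates.
    """
    if width < 16 or height < 16:
        raise ValueError("template smaller than 16 pixels per side")
    n_jaw, n_eye, n_mouth = _allocate_landmarks(n_landmarks)
    w, h = float(width), float(height)
    cx, cy = (w - 1) / 2, (h - 1) / 2
    rx, ry = 0.36 * w, 0.40 * h
    eye_dx, eye_dy = 0.155 * w, 0.13 * h
    eye_r = 0.065 * w
    mouth_dy, mouth_rx, mouth_ry = 0.22 * h, 0.12 * w, 0.045 * h
    # reject geometries whose features would leave the frame
    for (px, py, mx, my) in [
        (cx, cy, rx + 2, ry + 2),
        (cx - eye_dx, cy - eye_dy, eye_r + 2, eye_r + 2),
        (cx + eye_dx, cy - eye_dy, eye_r + 2, eye_r + 2),
        (cx, cy + mouth_dy, mouth_rx + 2, mouth_ry + 2),
    ]:
        if px - mx < 0 or px + mx > w - 1 or py - my < 0 or py + my > h - 1:
            raise ValueError("face features would overlap the image border")

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    r2 = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    img = 120.0 + 90.0 * np.exp(-(r2 ** 2))           # head on mid-gray background
    for ex in (cx - eye_dx, cx + eye_dx):
        er2 = ((xx - ex) ** 2 + (yy - (cy - eye_dy)) ** 2) / eye_r ** 2
        img -= 75.0 * np.exp(-er2)
    mr2 = ((xx - cx) / mouth_rx) ** 2 + ((yy - (cy + mouth_dy)) / mouth_ry) ** 2
    img -= 60.0 * np.exp(-mr2)
    img = np.clip(img, 0.0, 255.0)

    def ring(cx_, cy_, rx_, ry_, k, phase=0.0):
        t = phase + 2 * np.pi * np.arange(k) / k
        return np.stack([cx_ + rx_ * np.cos(t), cy_ + ry_ * np.sin(t)], 1)

    jaw = ring(cx, cy, rx, ry, n_jaw, phase=np.pi / 2)           # start at chin
    leye = ring(cx - eye_dx, cy - eye_dy, eye_r, eye_r, n_eye)
    reye = ring(cx + eye_dx, cy - eye_dy, eye_r, eye_r, n_eye)
    mouth = ring(cx, cy + mouth_dy, mouth_rx, mouth_ry, n_mouth)
    pts = np.vstack([jaw, leye, reye, mouth])
    return img.ravel(), pts.ravel()


def _mouth_slice(n_landmarks: int) -> slice:
    n_jaw, n_eye, n_mouth = _allocate_landmarks(n_landmarks)
    return slice(n_jaw + 2 * n_eye, n_landmarks)


def _eye_indices(n_landmarks: int) -> np.ndarray:
    n_jaw, n_eye, _ = _allocate_landmarks(n_landmarks)
    return np.arange(n_jaw, n_jaw + 2 * n_eye)


# ---------------------------------------------------------------------------
# ground truth


def _orthonormalize(rows: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(rows.T)
    # fix signs so the decomposition is deterministic
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return (q * signs).T


def _shape_basis(template_landmarks: np.ndarray, q_s: int) -> np.ndarray:
    """Smooth orthonormal landmark deformation modes (rows, interleaved x,y)."""
    pts = template_landmarks.reshape(-1, 2)
    k = pts.shape[0]
    c = pts.mean(axis=0)
    rel = pts - c
    r = np.linalg.norm(rel, axis=1)
    r_safe = np.where(r > 1e-9, r, 1.0)
    unit = rel / r_safe[:, None]
    modes = []
    modes.append(rel.copy())                                  # isotropic scale
    modes.append(np.stack([rel[:, 0], -rel[:, 1]], 1))        # aspect stretch
    modes.append(np.stack([rel[:, 1], rel[:, 0]], 1))         # shear
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    modes.append(unit * np.cos(2 * ang)[:, None] * r[:, None])  # ellipticity wobble
    modes.append(unit * np.sin(2 * ang)[:, None] * r[:, None])
    modes.append(np.stack([np.zeros(k), rel[:, 1] ** 2 / (np.abs(rel[:, 1]).max() + 1e-9)], 1))
    modes.append(unit * np.cos(3 * ang)[:, None] * r[:, None])
    modes.append(np.stack([rel[:, 0] ** 2 / (np.abs(rel[:, 0]).max() + 1e-9), np.zeros(k)], 1))
    if q_s > len(modes):
        raise ValueError(f"at most {len(modes)} shape modes available")
    flat = np.stack([m.ravel() for m in modes[:q_s]])
    return _orthonormalize(flat)


def _expression_direction(template_landmarks: np.ndarray, n_landmarks: int) -> np.ndarray:
    """Unit shape direction confined to the mouth block: corners up, lips apart."""
    sl = _mouth_slice(n_landmarks)
    pts = template_landmarks.reshape(-1, 2)
    mouth = pts[sl]
    c = mouth.mean(axis=0)
    rel = mouth - c
    rx = np.abs(rel[:, 0]).max() + 1e-9
    vec = np.zeros_like(pts)
    # widen the mouth, lift the corners, open the lips slightly
    vec[sl, 0] = rel[:, 0] / rx
    vec[sl, 1] = -0.8 * (rel[:, 0] / rx) ** 2 + 0.6 * np.sign(rel[:, 1]) * (1 - (rel[:, 0] / rx) ** 2)
    flat = vec.ravel()
    return flat / np.linalg.norm(flat)


def _texture_basis(width: int, height: int, q_t: int, extra_gender: bool):
    """Smooth orthonormal low-spatial-frequency texture fields (rows of w*h).

    Separable cosine fields ordered by increasing spatial frequency, so the
    leading components are the smoothest and inter-pixel correlations persist
    under downscaling.
    """
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    u = xx / (width - 1)
    v = yy / (height - 1)
    f_max = 8
    freqs = sorted(
        ((fx, fy) for fx in range(f_max + 1) for fy in range(f_max + 1) if fx or fy),
        key=lambda f: (f[0] ** 2 + f[1] ** 2, f),
    )
    if q_t + extra_gender > len(freqs):
        raise ValueError(f"at most {len(freqs)} texture modes available")
    fields = [np.cos(np.pi * fx * u) * np.cos(np.pi * fy * v) for fx, fy in freqs[: q_t + extra_gender]]
    flat = np.stack([f.ravel() for f in fields])
    basis = _orthonormalize(flat)
    if extra_gender:
        return basis[:q_t], basis[q_t]
    return basis, None


def _detail_pattern(width: int, height: int, amplitude: float = 12.0,
                    n_waves: int = 24) -> np.ndarray:
    """Deterministic fine-grain detail field (skin/hair-like texture).

    A fixed sum of oriented cosine waves with wavelengths of ~3-8 px at the
    reference width, masked to the head interior.  The pattern is identical
    in every rendered face, so it is free to encode in the shape-free frame,
    but its displacement by pose and shape makes raw images expensive to
    compress at high resolution — and it averages away under downscaling.
    """
    rng = np.random.default_rng(1234567)  # fixed: the pattern is a constant
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    u = xx / width
    v = yy / width  # same unit so wavelengths are isotropic
    field = np.zeros((height, width))
    for _ in range(n_waves):
        f = rng.uniform(12.0, 30.0)
        th = rng.uniform(0, np.pi)
        ph = rng.uniform(0, 2 * np.pi)
        field += np.cos(2 * np.pi * f * (u * np.cos(th) + v * np.sin(th)) + ph)
    field *= amplitude / field.std()
    # confine to the head interior (same ellipse as the template head)
    cx, cy = (width - 1) / 2, (height - 1) / 2
    r2 = ((xx - cx) / (0.36 * width)) ** 2 + ((yy - cy) / (0.40 * height)) ** 2
    return field * np.exp(-(r2 ** 3))


@dataclass
class SyntheticGroundTruth:
    """The generator's true decoupled model.

    Component standard deviations are in pixel units (shape) and gray units
    (texture).  ``expression_component`` is supported only on the mouth
    landmarks.  A dedicated texture+shape gender pair separates the two
    gender classes by a fixed offset.
    """

    template_image: np.ndarray          # (h, w) floats in [0, 255]
    template_landmarks: np.ndarray      # (2*n_landmarks,)
    shape_components: np.ndarray        # (q_s, 2*n_landmarks), orthonormal rows
    shape_sds: np.ndarray               # (q_s,)
    expression_component: np.ndarray    # (2*n_landmarks,), unit, mouth-only
    expression_sd: float
    texture_components: np.ndarray      # (q_t, w*h), orthonormal rows
    texture_sds: np.ndarray             # (q_t,)
    pixel_noise_sd: float
    width: int
    height: int
    # per-image texture latent jitter as a fraction of each component sd
    # (day-to-day variability; 0 makes the shape/texture decoupling exact)
    texture_within_fraction: float = 0.0
    # per-image head pose jitter (separate photo sessions): similarity
    # transform around the face centre; all zero reproduces perfectly
    # registered shots
    pose_translation_sd: float = 0.0    # pixels
    pose_log_scale_sd: float = 0.0      # log units
    pose_rotation_sd: float = 0.0       # radians
    # landmark annotation noise, i.i.d. per coordinate (makes the landmark
    # covariance full rank, as hand- or detector-annotated landmarks are)
    landmark_noise_sd: float = 0.0      # pixels
    # per-subject idiosyncratic texture: a random smooth field unique to each
    # subject, shared by that subject's images.  It lies outside the span of
    # the population components, so a model can only represent it after
    # seeing the subject — the source of the familiar/unfamiliar asymmetry.
    idiosyncratic_texture_sd: float = 0.0   # gray units per pixel
    idiosyncratic_smooth_px: float = 2.0    # Gaussian smoothing scale
    gender_texture_component: np.ndarray | None = None
    gender_texture_sd: float = 0.0
    gender_shape_component: np.ndarray | None = None
    gender_shape_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for comps in (self.shape_components, self.texture_components):
            g = comps @ comps.T
            if not np.allclose(g, np.eye(len(comps)), atol=1e-10):
                raise ValueError("component set is not orthonormal")
        sl = _mouth_slice(len(self.template_landmarks) // 2)
        mask = np.ones(len(self.template_landmarks) // 2, dtype=bool)
        mask[sl] = False
        outside = self.expression_component.reshape(-1, 2)[mask]
        if np.any(outside != 0):
            raise ValueError("expression component has support outside the mouth landmarks")
        if self.template_image.min() < 0 or self.template_image.max() > 255:
            raise ValueError("template image values outside [0, 255]")

    @property
    def n_landmarks(self) -> int:
        return len(self.template_landmarks) // 2

    @property
    def mouth_slice(self) -> slice:
        return _mouth_slice(self.n_landmarks)


def default_truth(width: int = 100, height: int = 120, n_landmarks: int = 46,
                  seed: int = 0, q_s: int = 6, q_t: int = 40) -> SyntheticGroundTruth:
    """The benchmark ground truth used across the experiments.

    Shape modes have standard deviations of a few pixels (comparable, after
    scaling, to landmark variability in portrait databases), and the smiling
    direction moves mouth landmarks by ~2.5 px.  Texture latent standard
    deviations are stated in gray units of per-pixel RMS amplitude (the
    components are unit-norm fields, so the latent scale is that figure times
    sqrt(d_t)); they follow a power-law tail over ``q_t`` smooth fields — the
    slowly decaying spectrum typical of natural texture variation — and add
    up to ~37 gray of per-pixel texture variability.  Pixel noise is 3 gray
    units.  Each subject also carries an idiosyncratic smooth texture field
    outside the population components (the familiar/unfamiliar asymmetry),
    and two within-subject nuisances emulate separate photo sessions: a
    texture latent jitter (half a component sd per image) and a head pose
    jitter (5 px translation, 3% scale, 2 degrees rotation at the reference
    height), both of which uniformation is designed to absorb.
    """
    img, lm = make_template(width, height, n_landmarks)
    img = np.clip(img + _detail_pattern(width, height).ravel(), 0.0, 255.0)
    shape = _shape_basis(lm, q_s)
    scale = height / 120.0
    shape_sds = np.array([4.0, 3.2, 2.6, 2.1, 1.7, 1.4, 1.2, 1.0])[:q_s] * scale
    tex, gender_tex = _texture_basis(width, height, q_t, extra_gender=True)
    rms = np.sqrt(width * height)  # unit-norm field -> per-pixel RMS 1/rms
    texture_sds = 22.0 * np.arange(1, q_t + 1) ** -0.7 * rms
    return SyntheticGroundTruth(
        template_image=img.reshape(height, width),
        template_landmarks=lm,
        shape_components=shape,
        shape_sds=shape_sds,
        expression_component=_expression_direction(lm, n_landmarks),
        expression_sd=8.0 * scale,
        texture_components=tex,
        texture_sds=texture_sds,
        pixel_noise_sd=6.0,
        width=width,
        height=height,
        gender_texture_component=gender_tex,
        gender_texture_sd=8.0 * rms,
        gender_shape_component=shape[1],  # aspect stretch doubles as the gender shape cue
        gender_shape_sd=1.2 * scale,
        seed=seed,
        texture_within_fraction=0.5,
        pose_translation_sd=5.0 * scale,
        pose_log_scale_sd=0.03,
        pose_rotation_sd=0.035,
        landmark_noise_sd=0.4 * scale,
        idiosyncratic_texture_sd=4.0,
        idiosyncratic_smooth_px=2.0 * scale,
    )


def low_correlation_truth(width: int = 100, height: int = 120, n_landmarks: int = 46,
                          seed: int = 0) -> SyntheticGroundTruth:
    """Variant with weak inter-pixel texture correlation and strong pixel noise.

    The texture fields carry little variance relative to the independent pixel
    noise, and the shots are nearly registered (negligible pose jitter), so
    uniformation has little structure to exploit and the shape cost dominates
    at low resolution.
    """
    t = default_truth(width, height, n_landmarks, seed)
    t.texture_sds = t.texture_sds * 0.25
    t.pixel_noise_sd = 9.0
    t.gender_texture_sd = t.gender_texture_sd * 0.5
    t.pose_translation_sd = 0.3
    t.pose_log_scale_sd = 0.003
    t.pose_rotation_sd = 0.004
    return t


# ---------------------------------------------------------------------------
# generation


def _pose_jitter(lm: np.ndarray, truth: "SyntheticGroundTruth", rng) -> np.ndarray:
    """Per-shot similarity-transform jitter of a landmark vector (may be a no-op)."""
    if not (truth.pose_translation_sd or truth.pose_log_scale_sd or truth.pose_rotation_sd):
        return lm
    pts = lm.reshape(-1, 2)
    c = truth.template_landmarks.reshape(-1, 2).mean(axis=0)
    s = np.exp(rng.standard_normal() * truth.pose_log_scale_sd)
    a = rng.standard_normal() * truth.pose_rotation_sd
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    t = rng.standard_normal(2) * truth.pose_translation_sd
    return (c + s * (pts - c) @ rot.T + t).ravel()


def generate_dataset(truth: SyntheticGroundTruth, n_subjects: int,
                     expressions_per_subject: int = 2, seed: int = 0,
                     max_resample: int = 50) -> FaceDataset:
    """Sample a dataset from the ground truth.

    Each subject draws one shape latent and one texture latent; the smiling
    variant adds the expression direction times a positive (half-normal)
    magnitude to the shape only.  Images are the subject texture (template +
    texture deviations + gender offset, clipped to [0, 255]) warped from the
    template landmarks to the subject landmarks, plus i.i.d. sensor noise,
    re-quantised to 8 bits.  Subjects whose landmarks leave the frame are re-drawn up to
    ``max_resample`` times.
    """
    from .warp import MeanShape, PiecewiseAffineWarper

    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if expressions_per_subject not in (1, 2):
        raise ValueError("expressions_per_subject must be 1 or 2")
    rng = np.random.default_rng(seed)
    w, h = truth.width, truth.height
    warper = PiecewiseAffineWarper(MeanShape(truth.template_landmarks, w, h))
    tmpl = truth.template_image.ravel()
    exprs = ["neutral", "smiling"][:expressions_per_subject]

    images, landmarks, subj, expr, gend = [], [], [], [], []
    for s in range(n_subjects):
        g = 1.0 if (s % 2 == 0) else -1.0
        for _attempt in range(max_resample):
            z_s = rng.standard_normal(len(truth.shape_sds))
            shape_dev = (z_s * truth.shape_sds) @ truth.shape_components
            if truth.gender_shape_component is not None and truth.gender_shape_sd:
                shape_dev = shape_dev + g * truth.gender_shape_sd * truth.gender_shape_component
            smile_mag = abs(rng.standard_normal()) * truth.expression_sd
            cand = {}
            ok = True
            for e in exprs:
                lm = truth.template_landmarks + shape_dev
                if e == "smiling":
                    lm = lm + smile_mag * truth.expression_component
                lm = _pose_jitter(lm, truth, rng)
                if truth.landmark_noise_sd:
                    lm = lm + rng.standard_normal(lm.shape) * truth.landmark_noise_sd
                xs, ys = lm[0::2], lm[1::2]
                if xs.min() < 0 or xs.max() > w - 1 or ys.min() < 0 or ys.max() > h - 1:
                    ok = False
                    break
                cand[e] = lm
            if ok:
                break
        else:
            raise RuntimeError(f"subject {s}: landmarks left the frame {max_resample} times")
        z_t = rng.standard_normal(len(truth.texture_sds))
        base = tmpl.copy()
        if truth.gender_texture_component is not None and truth.gender_texture_sd:
            base = base + g * truth.gender_texture_sd * truth.gender_texture_component
        if truth.idiosyncratic_texture_sd:
            from scipy.ndimage import gaussian_filter

            field = gaussian_filter(rng.standard_normal((h, w)),
                                    truth.idiosyncratic_smooth_px)
            base = base + (truth.idiosyncratic_texture_sd / field.std()) * field.ravel()
        for e in exprs:
            z_img = z_t
            if truth.texture_within_fraction:
                z_img = z_t + truth.texture_within_fraction * rng.standard_normal(len(z_t))
            texture_img = np.clip(base + (z_img * truth.texture_sds) @ truth.texture_components,
                                  0.0, 255.0)
            rendered = warper.warp_from_mean(texture_img, cand[e]).astype(float)
            if truth.pixel_noise_sd:
                # sensor noise arises at acquisition, after the geometry
                rendered = rendered + rng.standard_normal(rendered.shape) * truth.pixel_noise_sd
            rendered = np.rint(np.clip(rendered, 0.0, 255.0))
            images.append(rendered.ravel().astype(float))
            landmarks.append(cand[e])
            subj.append(f"s{s:04d}")
            expr.append(e)
            gend.append("f" if g > 0 else "m")
    return FaceDataset(
        images=np.stack(images), landmarks=np.stack(landmarks),
        width=w, height=h, subject_id=subj, expression=expr, gender=gend,
    )


def downscale_dataset(ds: FaceDataset, new_width: int) -> FaceDataset:
    """Downscale by integer area averaging; landmarks scale by the same ratio.

    Images are block-averaged and re-quantised to 8 bits; landmark coordinates
    are multiplied by ``new_height/height`` and kept real-valued.
    """
    if new_width == ds.width:
        return ds.subset(np.arange(ds.n))
    if new_width < 8:
        raise ValueError("new width below 8 pixels")
    if ds.width % new_width:
        raise ValueError(f"width {ds.width} is not an integer multiple of {new_width}")
    f = ds.width // new_width
    if ds.height % f:
        raise ValueError("aspect ratio cannot be preserved at this width")
    new_height = ds.height // f
    imgs = ds.images.reshape(ds.n, new_height, f, new_width, f).mean(axis=(2, 4))
    imgs = np.rint(np.clip(imgs, 0, 255))
    scale = new_height / ds.height
    return FaceDataset(
        images=imgs.reshape(ds.n, -1), landmarks=ds.landmarks * scale,
        width=new_width, height=new_height,
        subject_id=list(ds.subject_id), expression=list(ds.expression),
        gender=list(ds.gender),
    )
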