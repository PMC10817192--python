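"""The three face codes: eigenface, decoupled, and concatenated.

* Eigenface coding represents an image by its projections on the principal
  components of raw training images.
* Decoupled coding first splits a face into a shape-free *uniformed* texture
  (the image warped to the training mean shape) and a texture-free shape
  vector (the landmarks), and represents each by its own principal
  components.
* Concatenated coding runs a single PCA over the concatenation
  ``y = (uniformed texture, landmarks)``, which shares one p between the two
  blocks and makes the parameter count directly comparable with eigenface
  coding.  By default the shape block is scaled so its total variance matches
  the texture block's (the classic appearance-model weighting): without it the
  landmark block — a hundred pixel-unit coordinates against thousands of gray
  coordinates — is numerically invisible to the joint PCA and decoded
  landmarks collapse to the mean shape.  ``shape_weight`` accepts an explicit
  number (1.0 recovers raw concatenation).

Decoding a decoupled or concatenated encoding de-uniformises the decoded
texture at the decoded landmarks, producing an image in the native space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ppca import GaussianPCAModel, fit_ppca
from .synth import FaceDataset
from .warp import MeanShape, PiecewiseAffineWarper, mean_shape_of

__all__ = ["EigenfaceCode", "DecoupledCode", "ConcatenatedCode", "FaceEncoding",
           "sample_faces"]


def _clip_landmarks(lm: np.ndarray, width: int, height: int) -> np.ndarray:
    """Clip decoded landmarks into the frame (truncated codes can overshoot)."""
    lm = np.asarray(lm, dtype=float).copy()
    lm[0::2] = np.clip(lm[0::2], 0.0, width - 1)
    lm[1::2] = np.clip(lm[1::2], 0.0, height - 1)
    return lm


@dataclass
class FaceEncoding:
    """Per-block principal-component coefficients of one face."""

    code_kind: str
    texture: np.ndarray | None = None
    shape: np.ndarray | None = None
    joint: np.ndarray | None = None


class EigenfaceCode:
    """PCA code over raw images."""

    kind = "RE"

    def __init__(self, train: FaceDataset, p: int):
        self.p = int(p)
        self.model = fit_ppca(train.images, self.p)
        self.width, self.height = train.width, train.height

    def encode(self, image: np.ndarray, landmarks=None) -> FaceEncoding:
        x = np.asarray(image, dtype=float).ravel()
        return FaceEncoding(self.kind, texture=self.model.axes @ (x - self.model.mean))

    def decode(self, enc: FaceEncoding) -> np.ndarray:
        img = self.model.mean + enc.texture @ self.model.axes
        return img.reshape(self.height, self.width)

    def reconstruct(self, image: np.ndarray, landmarks=None) -> np.ndarray:
        return self.decode(self.encode(image))


class DecoupledCode:
    """Separate PCA codes over uniformed textures and landmark vectors."""

    kind = "RD"

    def __init__(self, train: FaceDataset, p_texture: int, p_shape: int,
                 mean_shape: MeanShape | None = None):
        from .warp import uniformize_dataset

        self.mean_shape = mean_shape or mean_shape_of(train.landmarks, train.width, train.height)
        self.warper = PiecewiseAffineWarper(self.mean_shape)
        uni = uniformize_dataset(train, self.mean_shape)
        self.texture_model = fit_ppca(uni.images, int(p_texture))
        self.shape_model = fit_ppca(train.landmarks, int(p_shape))
        self.p_texture = int(p_texture)
        self.p_shape = int(p_shape)
        self.width, self.height = train.width, train.height

    def encode(self, image: np.ndarray, landmarks: np.ndarray) -> FaceEncoding:
        uni = self.warper.warp_to_mean(image, landmarks).ravel().astype(float)
        tex = self.texture_model.axes @ (uni - self.texture_model.mean)
        shp = self.shape_model.axes @ (np.asarray(landmarks, float) - self.shape_model.mean)
        return FaceEncoding(self.kind, texture=tex, shape=shp)

    def decode(self, enc: FaceEncoding):
        uni = self.texture_model.mean + enc.texture @ self.texture_model.axes
        lm = self.shape_model.mean + enc.shape @ self.shape_model.axes
        lm = _clip_landmarks(lm, self.width, self.height)
        img = self.warper.warp_from_mean(uni, lm)
        return img.astype(float).reshape(self.height, self.width), lm

    def reconstruct(self, image: np.ndarray, landmarks: np.ndarray):
        return self.decode(self.encode(image, landmarks))


class ConcatenatedCode:
    """Single PCA over concatenated (uniformed texture, landmark) vectors."""

    kind = "Rc"

    def __init__(self, train: FaceDataset, p: int,
                 mean_shape: MeanShape | None = None,
                 shape_weight: float | str = "balanced"):
        from .warp import uniformize_dataset

        self.mean_shape = mean_shape or mean_shape_of(train.landmarks, train.width, train.height)
        self.warper = PiecewiseAffineWarper(self.mean_shape)
        uni = uniformize_dataset(train, self.mean_shape)
        if shape_weight == "balanced":
            # classic appearance-model weighting: scale the shape block so its
            # total variance matches the texture block's
            v_tex = float(uni.images.var(axis=0).sum())
            v_shp = float(train.landmarks.var(axis=0).sum())
            shape_weight = np.sqrt(v_tex / v_shp)
        self.shape_weight = float(shape_weight)
        y = np.hstack([uni.images, train.landmarks * self.shape_weight])
        self.model = fit_ppca(y, int(p))
        self.p = int(p)
        self.d_t = train.d_t
        self.width, self.height = train.width, train.height

    def _concat(self, image: np.ndarray, landmarks: np.ndarray) -> np.ndarray:
        uni = self.warper.warp_to_mean(image, landmarks).ravel().astype(float)
        return np.concatenate([uni, np.asarray(landmarks, float) * self.shape_weight])

    def encode(self, image: np.ndarray, landmarks: np.ndarray) -> FaceEncoding:
        return FaceEncoding(self.kind, joint=self.model.axes @ (self._concat(image, landmarks) - self.model.mean))

    def split(self, y: np.ndarray):
        """Split a concatenated vector into (uniformed texture, landmarks)."""
        return y[: self.d_t], y[self.d_t :] / self.shape_weight

    def decode(self, enc: FaceEncoding, deuniformize: bool = True):
        y = self.model.mean + enc.joint @ self.model.axes
        uni, lm = self.split(y)
        if not deuniformize:
            return uni.reshape(self.height, self.width), lm
        lm = _clip_landmarks(lm, self.width, self.height)
        img = self.warper.warp_from_mean(uni, lm)
        return img.astype(float).reshape(self.height, self.width), lm

    def reconstruct(self, image: np.ndarray, landmarks: np.ndarray, deuniformize: bool = True):
        return self.decode(self.encode(image, landmarks), deuniformize=deuniformize)


def sample_faces(code, p: int, pool: int, n: int, seed: int = 0,
                 return_coefficients: bool = False, max_retries: int = 20):
    """Draw synthetic faces from the Gaussian induced by a code.

    Coefficients over the first ``pool`` principal components are drawn from
    ``N(0, diag(eigenvalues))``; a random subset of ``pool - p`` of them is
    zeroed per sample (uniform without replacement), the result is
    back-projected and, for the concatenated code, the texture block is
    de-uniformised at the sampled landmarks.  Samples whose landmarks leave
    the frame are re-drawn (bounded retries).
    """
    model: GaussianPCAModel = code.model
    p, pool = int(p), int(pool)
    if not (0 < p <= pool <= model.p):
        raise ValueError("need 0 < p <= pool <= model rank")
    rng = np.random.default_rng(seed)
    lam = model.eigenvalues[:pool]
    sds = np.sqrt(np.clip(lam, 0.0, None))
    out_images, out_coeffs = [], []
    for _ in range(n):
        for _try in range(max_retries):
            y = rng.standard_normal(pool) * sds
            if pool > p:
                off = rng.choice(pool, size=pool - p, replace=False)
                y[off] = 0.0
            vec = model.mean + y @ model.axes[:pool]
            if isinstance(code, ConcatenatedCode):
                uni, lm = code.split(vec)
                xs, ys_ = lm[0::2], lm[1::2]
                if (xs.min() < 0 or xs.max() > code.width - 1
                        or ys_.min() < 0 or ys_.max() > code.height - 1):
                    continue
                img = code.warper.warp_from_mean(uni, lm).astype(float)
            else:
                img = vec.reshape(code.height, code.width)
            break
        else:
            raise RuntimeError("sampled landmarks kept leaving the frame")
        out_images.append(img)
        out_coeffs.append(y)
    images = np.stack(out_images)
    if return_coefficients:
        return images, np.stack(out_coeffs)
    return images
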