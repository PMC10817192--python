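"""Piecewise-affine image uniformation and de-uniformation.

*Uniformation* warps a face image so that its landmarks move to the mean
landmark configuration of a training set, producing a shape-free texture;
*de-uniformation* is the inverse warp back to target landmarks.  Both are
backward warps over a single Delaunay triangulation of the mean shape plus
border anchor points (the four image corners and evenly spaced border
points), so that every pixel of the frame is covered and the triangulation
topology is shared by all warps of a dataset.

Coordinate convention: landmark vectors are interleaved ``(x1, y1, ..., xk, yk)``
in pixel units, with x along the width and y along the height, origin at the
top-left pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import Delaunay

__all__ = ["MeanShape", "PiecewiseAffineWarper", "uniformize", "deuniformize",
           "uniformize_dataset", "mean_shape_of", "interior_psnr"]


@dataclass(frozen=True)
class MeanShape:
    """Mean landmark configuration of a training set, with its reference frame."""

    landmarks: np.ndarray   # (2*n_landmarks,), interleaved x,y
    width: int
    height: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.landmarks, dtype=float)
        if pts.ndim != 1 or pts.size % 2:
            raise ValueError("mean shape must be a flat interleaved (x, y) vector")
        xy = pts.reshape(-1, 2)
        if (xy[:, 0].min() < 0 or xy[:, 0].max() >= self.width
                or xy[:, 1].min() < 0 or xy[:, 1].max() >= self.height):
            raise ValueError("mean shape landmarks outside the image frame")
        object.__setattr__(self, "landmarks", pts)

    @property
    def points(self) -> np.ndarray:
        return self.landmarks.reshape(-1, 2)


def mean_shape_of(landmarks: np.ndarray, width: int, height: int) -> MeanShape:
    """Mean of an (N, 2*n_landmarks) landmark matrix as a :class:`MeanShape`."""
    lm = np.asarray(landmarks, dtype=float)
    return MeanShape(landmarks=lm.mean(axis=0), width=int(width), height=int(height))


def _border_anchors(width: int, height: int, per_side: int = 4) -> np.ndarray:
    """Corner and border anchor points pinning the frame boundary."""
    xs = np.linspace(0, width - 1, per_side + 2)
    ys = np.linspace(0, height - 1, per_side + 2)
    top = np.stack([xs, np.zeros_like(xs)], 1)
    bottom = np.stack([xs, np.full_like(xs, height - 1)], 1)
    left = np.stack([np.zeros_like(ys[1:-1]), ys[1:-1]], 1)
    right = np.stack([np.full_like(ys[1:-1], width - 1), ys[1:-1]], 1)
    return np.concatenate([top, bottom, left, right], axis=0)


class PiecewiseAffineWarper:
    """Shared-topology piecewise-affine warper anchored at a mean shape.

    The Delaunay triangulation is built once from the mean-shape landmarks
    plus border anchors; every warp re-uses the same triangle topology with
    displaced landmark positions (anchors never move).  Warps are backward:
    each output pixel is located in the target geometry, mapped barycentrically
    to the source geometry and sampled bilinearly; output is re-quantised to
    8 bits with round-half-even.
    """

    def __init__(self, mean_shape: MeanShape, border_points_per_side: int = 4):
        self.mean_shape = mean_shape
        self.width = mean_shape.width
        self.height = mean_shape.height
        self.anchors = _border_anchors(self.width, self.height, border_points_per_side)
        base = np.vstack([mean_shape.points, self.anchors])
        if len(np.unique(np.round(base, 9), axis=0)) != len(base):
            raise ValueError("duplicate control points (landmark coincides with an anchor)")
        self._tri = Delaunay(base)
        self.triangles = self._tri.simplices.copy()
        self._check_degenerate(base)
        self.n_landmarks = mean_shape.points.shape[0]
        # pixel grid, (P, 2) in (x, y)
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        self._grid = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
        # pixel -> (triangle, barycentric) in the mean-shape geometry, computed once
        self._mean_simplex, self._mean_bary = self._locate(base)

    def _check_degenerate(self, pts: np.ndarray) -> None:
        t = pts[self.triangles]
        u = t[:, 1] - t[:, 0]
        v = t[:, 2] - t[:, 0]
        area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
        if np.any(area2 < 1e-9):
            raise ValueError("degenerate (collinear) triangle in the triangulation")

    def _locate(self, vertices: np.ndarray):
        """Assign every pixel to a triangle of the shared topology placed at
        ``vertices`` and compute its barycentric coordinates.

        A pixel takes the triangle maximising its minimum barycentric
        coordinate, which is an interior triangle when one exists and the
        nearest triangle on numerical boundary cases.
        """
        tri_pts = vertices[self.triangles]                    # (T, 3, 2)
        a, b, c = tri_pts[:, 0], tri_pts[:, 1], tri_pts[:, 2]
        v0 = b - a
        v1 = c - a
        den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]       # (T,)
        g = self._grid                                        # (P, 2)
        # w1, w2 via Cramer's rule, vectorised (P, T)
        dx = g[:, None, 0] - a[None, :, 0]
        dy = g[:, None, 1] - a[None, :, 1]
        w1 = (dx * v1[None, :, 1] - dy * v1[None, :, 0]) / den[None, :]
        w2 = (dy * v0[None, :, 0] - dx * v0[None, :, 1]) / den[None, :]
        w0 = 1.0 - w1 - w2
        score = np.minimum(w0, np.minimum(w1, w2))            # (P, T)
        simplex = np.argmax(score, axis=1)
        rows = np.arange(len(g))
        bary = np.stack([w0[rows, simplex], w1[rows, simplex], w2[rows, simplex]], axis=1)
        return simplex, bary

    def _vertices_for(self, landmarks: np.ndarray) -> np.ndarray:
        lm = np.asarray(landmarks, dtype=float).reshape(-1, 2)
        if lm.shape[0] != self.n_landmarks:
            raise ValueError(f"expected {self.n_landmarks} landmarks, got {lm.shape[0]}")
        if (lm[:, 0].min() < 0 or lm[:, 0].max() >= self.width
                or lm[:, 1].min() < 0 or lm[:, 1].max() >= self.height):
            raise ValueError("landmarks outside the image frame")
        return np.vstack([lm, self.anchors])

    def _warp(self, image: np.ndarray, src_vertices: np.ndarray,
              simplex: np.ndarray, bary: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float).reshape(self.height, self.width)
        src = src_vertices[self.triangles[simplex]]           # (P, 3, 2)
        pos = np.einsum("pk,pkc->pc", bary, src)              # source (x, y) per pixel
        xs = np.clip(pos[:, 0], 0, self.width - 1)
        ys = np.clip(pos[:, 1], 0, self.height - 1)
        out = map_coordinates(img, [ys, xs], order=1, mode="nearest")
        return _quantize(out.reshape(self.height, self.width))

    def warp_to_mean(self, image: np.ndarray, landmarks: np.ndarray) -> np.ndarray:
        """Uniformise: move ``landmarks`` to the mean shape (backward warp)."""
        src_vertices = self._vertices_for(landmarks)
        if np.array_equal(src_vertices, np.vstack([self.mean_shape.points, self.anchors])):
            return _quantize(np.asarray(image, dtype=float).reshape(self.height, self.width))
        return self._warp(image, src_vertices, self._mean_simplex, self._mean_bary)

    def warp_from_mean(self, image: np.ndarray, landmarks: np.ndarray) -> np.ndarray:
        """De-uniformise: move the mean shape to ``landmarks`` (backward warp)."""
        tgt_vertices = self._vertices_for(landmarks)
        base = np.vstack([self.mean_shape.points, self.anchors])
        if np.array_equal(tgt_vertices, base):
            return _quantize(np.asarray(image, dtype=float).reshape(self.height, self.width))
        self._check_degenerate(tgt_vertices)
        simplex, bary = self._locate(tgt_vertices)
        return self._warp(image, base, simplex, bary)


def _quantize(img: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half-to-even to 8-bit integers."""
    return np.rint(np.clip(img, 0.0, 255.0)).astype(np.uint8)


def uniformize(image: np.ndarray, landmarks: np.ndarray, mean_shape: MeanShape,
               warper: PiecewiseAffineWarper | None = None) -> np.ndarray:
    """Warp ``image`` so its ``landmarks`` land on ``mean_shape``."""
    warper = warper or PiecewiseAffineWarper(mean_shape)
    return warper.warp_to_mean(image, landmarks)


def deuniformize(uniformed: np.ndarray, landmarks: np.ndarray, mean_shape: MeanShape,
                 warper: PiecewiseAffineWarper | None = None) -> np.ndarray:
    """Inverse warp: move the mean-shape texture onto target ``landmarks``."""
    warper = warper or PiecewiseAffineWarper(mean_shape)
    return warper.warp_from_mean(uniformed, landmarks)


def uniformize_dataset(ds, mean_shape: MeanShape):
    """Uniformise every image of a dataset; landmarks become the mean shape.

    The mean shape must come from the caller's *training* subset; this
    function only checks frame compatibility.
    """
    from .synth import FaceDataset  # local import to avoid a cycle

    if (mean_shape.width, mean_shape.height) != (ds.width, ds.height):
        raise ValueError("mean shape resolution does not match the dataset")
    warper = PiecewiseAffineWarper(mean_shape)
    images = np.stack([
        warper.warp_to_mean(ds.images[i], ds.landmarks[i]).ravel()
        for i in range(ds.n)
    ]).astype(float)
    landmarks = np.tile(mean_shape.landmarks, (ds.n, 1))
    return FaceDataset(
        images=images, landmarks=landmarks, width=ds.width, height=ds.height,
        subject_id=list(ds.subject_id), expression=list(ds.expression),
        gender=list(ds.gender),
    )


def interior_psnr(a: np.ndarray, b: np.ndarray, margin: int = 8) -> float:
    """PSNR (dB, peak 255) on the interior region, ``margin`` pixels from the border."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    ai = a[margin:-margin, margin:-margin]
    bi = b[margin:-margin, margin:-margin]
    mse = float(np.mean((ai - bi) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0 ** 2 / mse))
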