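"""Dataset and model I/O.

A dataset directory holds one 8-bit grayscale PNG (or PGM) per image, one
ASCII landmark file per image (first line: the landmark count; then one
``x y`` pair per line, floating point), and a ``manifest.csv`` with columns
``file, landmarks_file, subject_id, expression, gender``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .ppca import GaussianPCAModel
from .synth import FaceDataset
from .warp import MeanShape

__all__ = ["save_dataset", "load_dataset", "save_mean_shape", "load_mean_shape",
           "save_model", "load_model", "DatasetFormatError", "MissingFileError",
           "LandmarkCountError", "NotEightBitError"]


class DatasetFormatError(ValueError):
    """The on-disk dataset violates the expected layout."""


class MissingFileError(DatasetFormatError):
    """The manifest references a file that does not exist."""


class LandmarkCountError(DatasetFormatError):
    """A landmark file's count disagrees with the rest of the dataset."""


class NotEightBitError(DatasetFormatError):
    """An image is not 8-bit grayscale."""


def _write_landmarks(path: Path, landmarks: np.ndarray, decimals: int = 6) -> None:
    pts = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    lines = [str(len(pts))]
    lines += [f"{x:.{decimals}f} {y:.{decimals}f}" for x, y in pts]
    path.write_text("\n".join(lines) + "\n")


def _read_landmarks(path: Path) -> np.ndarray:
    if not path.exists():
        raise MissingFileError(f"landmark file not found: {path}")
    lines = path.read_text().strip().splitlines()
    k = int(lines[0])
    if len(lines) - 1 != k:
        raise LandmarkCountError(f"{path}: header says {k} landmarks, file has {len(lines) - 1}")
    pts = np.array([[float(t) for t in ln.split()] for ln in lines[1:]], dtype=float)
    return pts.ravel()


def save_dataset(ds: FaceDataset, directory) -> None:
    """Write images (PNG), landmark files and the manifest into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(ds.n):
        stem = f"{ds.subject_id[i]}_{ds.expression[i]}"
        img_file = f"{stem}.png"
        lm_file = f"{stem}.pts"
        iio.imwrite(directory / img_file, ds.image(i).astype(np.uint8))
        _write_landmarks(directory / lm_file, ds.landmarks[i])
        rows.append({"file": img_file, "landmarks_file": lm_file,
                     "subject_id": ds.subject_id[i], "expression": ds.expression[i],
                     "gender": ds.gender[i]})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def load_dataset(directory) -> FaceDataset:
    """Read a dataset directory back; validates layout and container invariants."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise MissingFileError(f"manifest not found: {manifest}")
    table = pd.read_csv(manifest)
    images, landmarks = [], []
    n_expected = None
    for rec in table.itertuples():
        img_path = directory / rec.file
        if not img_path.exists():
            raise MissingFileError(f"image not found: {img_path}")
        img = iio.imread(img_path)
        if img.dtype != np.uint8 or img.ndim != 2:
            raise NotEightBitError(f"{img_path}: expected 8-bit grayscale, got {img.dtype}/{img.ndim}D")
        lm = _read_landmarks(directory / rec.landmarks_file)
        if n_expected is None:
            n_expected = lm.size
        elif lm.size != n_expected:
            raise LandmarkCountError(
                f"{rec.landmarks_file}: {lm.size // 2} landmarks, expected {n_expected // 2}")
        images.append(img.astype(float).ravel())
        landmarks.append(lm)
    h, w = iio.imread(directory / table.iloc[0]["file"]).shape
    return FaceDataset(
        images=np.stack(images), landmarks=np.stack(landmarks), width=w, height=h,
        subject_id=list(table["subject_id"]), expression=list(table["expression"]),
        gender=list(table["gender"]),
    )


def save_mean_shape(ms: MeanShape, path) -> None:
    path = Path(path)
    _write_landmarks(path, ms.landmarks, decimals=9)
    path.with_suffix(path.suffix + ".meta").write_text(
        json.dumps({"width": ms.width, "height": ms.height}))


def load_mean_shape(path) -> MeanShape:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta").read_text())
    return MeanShape(_read_landmarks(path), meta["width"], meta["height"])


def save_model(model: GaussianPCAModel, path) -> None:
    """Serialise a fitted p-PCA model as an NPZ archive with a JSON header."""
    header = json.dumps({"n_train": model.n_train, "d": model.d, "p": model.p,
                         "residual_variance": model.residual_variance})
    np.savez_compressed(path, header=np.array(header), mean=model.mean,
                        axes=model.axes, eigenvalues=model.eigenvalues)


def load_model(path) -> GaussianPCAModel:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        return GaussianPCAModel(
            mean=z["mean"], axes=z["axes"], eigenvalues=z["eigenvalues"],
            residual_variance=float(header["residual_variance"]),
            n_train=int(header["n_train"]), d=int(header["d"]), p=int(header["p"]),
        )
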