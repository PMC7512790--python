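"""Readers and writers for images, label maps, membership matrices, tables.

Intensities from PNG/TIFF are converted to float without rescaling; NPY and
delimited text round-trip losslessly. Membership matrices are stored as
whitespace-delimited text with a one-line ``n c`` header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "read_memberships",
    "write_memberships",
    "write_table",
]

_TEXT_SUFFIXES = {".txt", ".dat", ".csv", ".tsv"}
_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def _delimiter(path: Path):
    return {"csv": ",", "tsv": "\t"}.get(path.suffix.lstrip(".").lower())


def read_image(path) -> np.ndarray:
    """Load a 2-D grayscale image as floats (no intensity rescaling)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        if path.suffix.lower() in _IMAGE_SUFFIXES:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path), dtype=float)
        elif path.suffix.lower() == ".npy":
            arr = np.asarray(np.load(path), dtype=float)
        elif path.suffix.lower() in _TEXT_SUFFIXES:
            arr = np.loadtxt(path, delimiter=_delimiter(path), ndmin=2)
        else:
            raise IOError(f"unsupported image format {path.suffix!r} for {path}")
    except IOError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read {path} as a numeric grid: {exc}") from exc
    if arr.ndim == 3:  # collapse trivial channel axes from image files
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise IOError(f"{path} is not a 2-D grayscale image (ndim={arr.ndim})")
    return arr


def write_image(image: np.ndarray, path) -> None:
    """Write a float image: NPY or delimited text keep exact values."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    if path.suffix.lower() == ".npy":
        np.save(path, image)
    elif path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, image, delimiter=_delimiter(path) or " ")
    elif path.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        lo, hi = image.min(), image.max()
        scaled = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
    else:
        raise IOError(f"unsupported image format {path.suffix!r} for {path}")


def write_labels(labels: np.ndarray, path) -> None:
    """Write an integer label map; PNG uses one gray level per class."""
    path = Path(path)
    labels = np.asarray(labels, dtype=int)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, labels, fmt="%d", delimiter=_delimiter(path) or " ")
    elif path.suffix.lower() == ".npy":
        np.save(path, labels)
    elif path.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        k = max(int(labels.max()), 1)
        iio.imwrite(path, (labels * (255 // k)).astype(np.uint8))
    else:
        raise IOError(f"unsupported label format {path.suffix!r} for {path}")


def read_labels(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".npy":
        return np.asarray(np.load(path), dtype=int)
    arr = np.loadtxt(path, delimiter=_delimiter(path), ndmin=2)
    return np.rint(arr).astype(int)


def write_memberships(u: np.ndarray, path) -> None:
    """Delimited membership matrix with an ``n c`` header line."""
    u = np.asarray(u, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{u.shape[0]} {u.shape[1]}\n")
        np.savetxt(fh, u)


def read_memberships(path) -> np.ndarray:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise IOError(f"{path}: expected 'n c' header line")
        n, c = int(header[0]), int(header[1])
        u = np.loadtxt(fh, ndmin=2)
    if u.shape != (n, c):
        raise IOError(f"{path}: header says {(n, c)}, body is {u.shape}")
    return u


def write_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = _delimiter(path) or ","
    table.to_csv(path, sep=sep, index=False)
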