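"""Reading and writing the package's file formats.

Gray images go through Pillow/imageio as PNG or TIFF; masks are 0/255 PNGs;
feature matrices and metric tables are CSV; model state and learned weights
are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import GrayImage
from .segmentation import BinaryMask

__all__ = [
    "read_gray_image",
    "write_gray_png",
    "read_mask_png",
    "write_mask_png",
    "write_features_csv",
    "read_features_csv",
    "write_json",
    "read_json",
]


def read_gray_image(path: str | Path) -> GrayImage:
    """Load a single-channel PNG/TIFF as a GrayImage (8- or 16-bit)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # tolerate gray saved as RGB
        arr = arr[..., 0]
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return GrayImage(arr.astype(np.int64), bit_depth)


def write_gray_png(path: str | Path, img: GrayImage) -> None:
    iio.imwrite(Path(path), img.to_uint())


def read_mask_png(path: str | Path) -> BinaryMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask((arr > 0).astype(np.uint8))


def write_mask_png(path: str | Path, mask: BinaryMask) -> None:
    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def write_features_csv(path: str | Path, f1: np.ndarray, f2: np.ndarray, f3: np.ndarray, labels) -> None:
    """Feature matrices as one CSV: rows = images, branch-prefixed columns."""
    cols = {}
    for name, mat in (("f1", f1), ("f2", f2), ("f3", f3)):
        mat = np.asarray(mat)
        for j in range(mat.shape[1]):
            cols[f"{name}_{j:03d}"] = mat[:, j]
    frame = pd.DataFrame(cols)
    frame.insert(0, "label", list(labels))
    frame.to_csv(Path(path), index=False)


def read_features_csv(path: str | Path):
    frame = pd.read_csv(Path(path))
    labels = frame["label"].to_numpy()
    out = []
    for name in ("f1", "f2", "f3"):
        sub = frame[[c for c in frame.columns if c.startswith(name + "_")]]
        out.append(sub.to_numpy(dtype=float))
    return out[0], out[1], out[2], labels


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
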