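"""Image and disparity file I/O.

RGB frames travel as ``float32`` arrays in [0, 1] (H, W, 3) and are stored as
8-bit PNG.  Disparity maps are stored as single-channel little-endian PFM
(portable float map), the format stereo benchmarks use for float fields.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np


def to_float(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit or float image to float32 in [0, 1]."""
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(np.float32) / 255.0
    return np.clip(img.astype(np.float32), 0.0, 1.0)


def to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def load_image(path: str | os.PathLike) -> np.ndarray:
    img = to_float(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3]


def save_image(path: str | os.PathLike, img: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, to_uint8(img))


def write_pfm(path: str | os.PathLike, field: np.ndarray) -> None:
    """Write a single-channel float field as little-endian PFM.

    PFM stores scanlines bottom-to-top; a negative scale marks little endian.
    """
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 2:
        raise ValueError("PFM writer expects a 2-D field")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    h, w = field.shape
    with open(path, "wb") as f:
        f.write(b"Pf\n")
        f.write(f"{w} {h}\n".encode())
        f.write(b"-1.0\n")
        f.write(field[::-1].astype("<f4").tobytes())


def read_pfm(path: str | os.PathLike) -> np.ndarray:
    with open(path, "rb") as f:
        header = f.readline().strip()
        if header != b"Pf":
            raise ValueError(f"not a single-channel PFM file: {header!r}")
        dims = f.readline().split()
        w, h = int(dims[0]), int(dims[1])
        scale = float(f.readline())
        data = np.frombuffer(f.read(w * h * 4), dtype="<f4" if scale < 0 else ">f4")
    return data.reshape(h, w)[::-1].astype(np.float32)


def write_json(path: str | os.PathLike, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)
        f.write("\n")


def read_json(path: str | os.PathLike):
    with open(path) as f:
        return json.load(f)
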