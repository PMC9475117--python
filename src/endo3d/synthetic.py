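"""Synthetic stereo endoscopy fixtures with known disparity.

Real binocular laparoscopy footage is large and externally hosted, so every
stage of the pipeline is exercised on procedurally generated stand-ins:
tissue-like multi-octave colour textures crossed by dark vessel strokes, a
known horizontal disparity field, and a right view rendered from the left by
backward bilinear warping.  All generators are pure functions of their seeds.

Sign convention (shared package-wide): the right camera is displaced so that
``right(x) = left(x + d)`` with ``d >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import imgio
from .autodiff import _resize_axis_idx

__all__ = [
    "TextureSpec",
    "DisparitySpec",
    "StereoSample",
    "generate_tissue_texture",
    "generate_disparity_field",
    "render_right_view",
    "make_dataset",
    "write_dataset",
    "bilinear_resize_np",
]


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one tissue-like frame; identical specs give identical pixels."""

    seed: int = 0
    shape: tuple[int, int] = (128, 256)
    octaves: int = 4
    vessel_count: int = 6
    color_base: tuple[float, float, float] = (0.62, 0.33, 0.30)

    def __post_init__(self):
        h, w = self.shape
        if h < 32 or w < 32:
            raise ValueError(f"texture shape must be at least 32x32, got {self.shape}")
        if self.octaves < 1:
            raise ValueError("octaves must be >= 1")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")


@dataclass(frozen=True)
class DisparitySpec:
    kind: str = "constant"  # constant | ramp | blob
    magnitude: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("constant", "ramp", "blob"):
            raise ValueError(f"unknown disparity kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")


@dataclass
class StereoSample:
    """One rectified pair with its ground truth and clean (smoke-free) frames."""

    left: np.ndarray
    right: np.ndarray
    gt_disparity: np.ndarray | None = None
    clean: np.ndarray | None = None
    clean_right: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left/right shapes differ")
        if self.gt_disparity is not None and self.gt_disparity.shape != self.left.shape[:2]:
            raise ValueError("gt_disparity shape does not match images")


def bilinear_resize_np(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize (align-corners-false) of an (H, W[, C]) array."""
    img = np.asarray(img, dtype=np.float32)
    h, w = img.shape[:2]
    if h != out_h:
        i0, f = _resize_axis_idx(h, out_h)
        i1 = np.minimum(i0 + 1, h - 1)
        f = f.reshape(-1, *([1] * (img.ndim - 1)))
        img = img[i0] * (1.0 - f) + img[i1] * f
    if w != out_w:
        i0, f = _resize_axis_idx(w, out_w)
        i1 = np.minimum(i0 + 1, w - 1)
        f = f.reshape(1, -1, *([1] * (img.ndim - 2)))
        img = img[:, i0] * (1.0 - f) + img[:, i1] * f
    return img


def _value_noise(rng: np.random.Generator, shape: tuple[int, int], octaves: int) -> np.ndarray:
    """Multi-octave value noise in [0, 1]: coarse random lattices, bilinearly
    upsampled, summed with halving amplitudes."""
    h, w = shape
    acc = np.zeros((h, w), dtype=np.float32)
    amp = 1.0
    for o in range(octaves):
        gh = max(2, min(h, 3 * 2 ** o))
        gw = max(2, min(w, 3 * 2 ** o))
        lattice = rng.random((gh, gw)).astype(np.float32)
        acc += amp * bilinear_resize_np(lattice, h, w)
        amp *= 0.5
    # fixed normalisation (sum of amplitudes < 2) so extra octaves add
    # detail variance instead of averaging it away
    return acc * 0.5


def _stamp_vessels(img: np.ndarray, rng: np.random.Generator, count: int) -> np.ndarray:
    """Darken the texture along random quadratic Bezier strokes."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    dark = np.zeros((h, w), dtype=np.float32)
    for _ in range(count):
        p = rng.random((3, 2)) * [h - 1, w - 1]
        width = rng.uniform(0.8, 2.0)
        t = np.linspace(0.0, 1.0, 64, dtype=np.float32)[:, None]
        pts = (1 - t) ** 2 * p[0] + 2 * (1 - t) * t * p[1] + t ** 2 * p[2]
        for cy, cx in pts:
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            dark = np.maximum(dark, np.exp(-d2 / (2.0 * width ** 2)))
    return img * (1.0 - 0.55 * dark[..., None])


def generate_tissue_texture(spec: TextureSpec) -> np.ndarray:
    """Render a smooth tissue-like RGB frame with dark curvilinear vessels."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    base = np.asarray(spec.color_base, dtype=np.float32)
    img = np.empty((h, w, 3), dtype=np.float32)
    master = _value_noise(rng, (h, w), spec.octaves)
    for c in range(3):
        detail = _value_noise(rng, (h, w), spec.octaves)
        img[..., c] = base[c] * (0.55 + 0.55 * master + 0.35 * detail)
    img = _stamp_vessels(img, rng, spec.vessel_count)
    # gentle vignette, as endoscope optics produce
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    img *= (1.0 - 0.25 * r2[..., None]).astype(np.float32)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_disparity_field(spec: DisparitySpec, shape: tuple[int, int]) -> np.ndarray:
    """Ground-truth horizontal disparity in pixels, values in [0, magnitude]."""
    h, w = shape
    if spec.magnitude >= w / 4:
        raise ValueError(
            f"magnitude {spec.magnitude} >= W/4 = {w / 4}: warp would be invalid"
        )
    if spec.kind == "constant":
        return np.full((h, w), spec.magnitude, dtype=np.float32)
    if spec.kind == "ramp":
        ramp = np.linspace(0.0, spec.magnitude, w, dtype=np.float32)
        return np.broadcast_to(ramp, (h, w)).copy()
    # blob: separable raised-cosine bump, exactly 0 on the borders
    wy = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(h) / (h - 1))
    wx = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(w) / (w - 1))
    return (spec.magnitude * np.outer(wy, wx)).astype(np.float32)


def render_right_view(left: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Backward-warp the left frame into the right viewpoint.

    ``right(x, y) = left(x + d(x, y), y)`` sampled bilinearly with edge
    clamping, so no holes appear (a deliberate simplification of true
    occlusion handling).
    """
    left = np.asarray(left, dtype=np.float32)
    d = np.asarray(d, dtype=np.float32)
    if d.shape != left.shape[:2]:
        raise ValueError(f"disparity shape {d.shape} != image shape {left.shape[:2]}")
    if np.any(d < 0):
        raise ValueError("disparity must be nonnegative")
    h, w = d.shape
    if np.any(d >= w / 4):
        raise ValueError("disparity must stay below W/4")
    xs = np.arange(w, dtype=np.float32)[None, :] + d
    xs = np.clip(xs, 0.0, w - 1.0)
    x0 = np.minimum(np.floor(xs).astype(np.int64), w - 2)
    f = (xs - x0).astype(np.float32)[..., None]
    rows = np.arange(h)[:, None]
    out = left[rows, x0] * (1.0 - f) + left[rows, x0 + 1] * f
    return np.clip(out, 0.0, 1.0)


def make_dataset(n: int,
                 texture: TextureSpec = TextureSpec(),
                 disparity: DisparitySpec = DisparitySpec(),
                 smoke_level: str = "none",
                 seed: int = 0) -> list[StereoSample]:
    """Generate ``n`` stereo samples with per-sample seeds derived from ``seed``.

    ``smoke_level`` in {none, light, dense} composites procedural smoke onto
    both eyes (the same plume, as both cameras share the optical cavity);
    the clean frames and ground-truth disparity are always retained.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if smoke_level not in ("none", "light", "dense"):
        raise ValueError(f"unknown smoke_level {smoke_level!r}")
    from . import smoke as smoke_mod

    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2 ** 31 - 1, size=(n, 3))
    samples = []
    for i in range(n):
        t_seed, d_seed, s_seed = (int(s) for s in sub_seeds[i])
        tspec = TextureSpec(seed=t_seed, shape=texture.shape, octaves=texture.octaves,
                            vessel_count=texture.vessel_count, color_base=texture.color_base)
        dspec = DisparitySpec(kind=disparity.kind, magnitude=disparity.magnitude, seed=d_seed)
        left = generate_tissue_texture(tspec)
        dfield = generate_disparity_field(dspec, texture.shape)
        right = render_right_view(left, dfield)
        sample = StereoSample(left=left, right=right, gt_disparity=dfield,
                              clean=left.copy(), clean_right=right.copy(),
                              meta={"texture_seed": t_seed, "disparity_seed": d_seed,
                                    "smoke_seed": s_seed, "smoke_level": smoke_level,
                                    "disparity_kind": disparity.kind,
                                    "disparity_magnitude": disparity.magnitude})
        if smoke_level != "none":
            (fog_l, _), = smoke_mod.fog_dataset([sample.left], smoke_level, s_seed)
            (fog_r, _), = smoke_mod.fog_dataset([sample.right], smoke_level, s_seed)
            sample.left, sample.right = fog_l, fog_r
        sample.validate()
        samples.append(sample)
    return samples


def write_dataset(samples: Sequence[StereoSample], out_dir: str | Path) -> Path:
    """Write PNG pairs, PFM ground truth and a JSON manifest."""
    out = Path(out_dir)
    manifest = []
    for i, s in enumerate(samples):
        entry = {"index": i, **s.meta}
        for name, img in (("left", s.left), ("right", s.right),
                          ("clean", s.clean), ("clean_right", s.clean_right)):
            if img is not None:
                rel = f"{i:04d}_{name}.png"
                imgio.save_image(out / rel, img)
                entry[name] = rel
        if s.gt_disparity is not None:
            rel = f"{i:04d}_disp.pfm"
            imgio.write_pfm(out / rel, s.gt_disparity)
            entry["gt_disparity"] = rel
        manifest.append(entry)
    imgio.write_json(out / "manifest.json", manifest)
    return out


def load_dataset(in_dir: str | Path) -> list[StereoSample]:
    root = Path(in_dir)
    samples = []
    for entry in imgio.read_json(root / "manifest.json"):
        kw = {}
        for name, attr in (("left", "left"), ("right", "right"),
                           ("clean", "clean"), ("clean_right", "clean_right")):
            if name in entry:
                kw[attr] = imgio.load_image(root / entry[name])
        if "gt_disparity" in entry:
            kw["gt_disparity"] = imgio.read_pfm(root / entry["gt_disparity"])
        meta = {k: v for k, v in entry.items()
                if k not in ("left", "right", "clean", "clean_right", "gt_disparity", "index")}
        samples.append(StereoSample(meta=meta, **kw))
    return samples
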