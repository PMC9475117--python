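"""Gaussian/Laplacian pyramids with bilinear up-sampling.

Each Laplacian level is the difference between a Gaussian level and the
bilinearly re-expanded next-coarser Gaussian level,

    L_i = G_i - up(down(G_i)),

which makes reconstruction exact by construction: adding ``up(G_{i+1})``
back to ``L_i`` recovers ``G_i`` to machine precision.  Down-sampling uses
the separable 5-tap binomial kernel [1, 4, 6, 4, 1]/16 (the classic
Burt-Adelson choice) with reflective borders, then decimation by 2;
up-sampling is plain bilinear interpolation (align-corners-false), chosen
over nearest-neighbour to avoid mosaic artefacts at strong gradients.

The per-scale band-pass images are what the desmoking encoder concatenates
onto its feature maps (:func:`fusion_stack`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import bilinear_resize_np

__all__ = [
    "LaplacianStack",
    "gaussian_down",
    "bilinear_up",
    "laplacian_level",
    "build_stack",
    "collapse",
    "fusion_stack",
]

_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0], dtype=np.float32) / 16.0


def _blur_axis(img: np.ndarray, axis: int) -> np.ndarray:
    pad = [(0, 0)] * img.ndim
    pad[axis] = (2, 2)
    padded = np.pad(img, pad, mode="reflect")
    out = np.zeros_like(img, dtype=np.float32)
    n = img.shape[axis]
    sl = [slice(None)] * img.ndim
    for k in range(5):
        sl[axis] = slice(k, k + n)
        out += _KERNEL[k] * padded[tuple(sl)]
    return out


def gaussian_down(image: np.ndarray) -> np.ndarray:
    """Binomial blur then decimation by 2 (floor sizes)."""
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    if h < 2 or w < 2:
        raise ValueError(f"cannot down-sample a {h}x{w} image")
    blurred = _blur_axis(_blur_axis(image, 0), 1)
    return blurred[::2, ::2]


def bilinear_up(image: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    th, tw = target_shape[:2]
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    if th < h or tw < w:
        raise ValueError(f"target {target_shape} smaller than source {(h, w)}")
    return bilinear_resize_np(image, th, tw)


@dataclass
class LaplacianStack:
    """Gaussian levels G_0..G_n and band-pass levels L_0..L_{n-1}."""

    gaussians: list
    laplacians: list

    @property
    def n_levels(self) -> int:
        return len(self.laplacians)


def build_stack(image: np.ndarray, n_levels: int) -> LaplacianStack:
    image = np.asarray(image, dtype=np.float32)
    gaussians = [image]
    for _ in range(n_levels):
        gaussians.append(gaussian_down(gaussians[-1]))
    laplacians = [
        g - bilinear_up(gn, g.shape[:2]) for g, gn in zip(gaussians, gaussians[1:])
    ]
    return LaplacianStack(gaussians=gaussians, laplacians=laplacians)


def laplacian_level(image: np.ndarray, i: int) -> np.ndarray:
    """Band-pass residual at level ``i``: G_i - up(down(G_i))."""
    stack = build_stack(image, i + 1)
    return stack.laplacians[i]


def collapse(stack: LaplacianStack) -> np.ndarray:
    """Invert the decomposition: up-sample the coarsest Gaussian and add the
    band-pass levels back in, finest last.  Exact to float precision."""
    out = stack.gaussians[-1]
    for lap in reversed(stack.laplacians):
        out = lap + bilinear_up(out, lap.shape[:2])
    return out


def fusion_stack(image: np.ndarray, encoder_scales: list[tuple[int, int]]) -> list[np.ndarray]:
    """One Laplacian image per encoder scale, resized to match it exactly.

    Scales must be strictly decreasing.  Pyramid levels live at
    floor-halved sizes, so a level may miss a requested scale by a pixel
    when the input is not a power of two; a final bilinear resize aligns it.
    """
    for a, b in zip(encoder_scales, encoder_scales[1:]):
        if b[0] > a[0] or b[1] > a[1]:
            raise ValueError(f"encoder scales must be non-increasing, got {a} -> {b}")
    h, w = np.asarray(image).shape[:2]
    n_possible = int(np.floor(np.log2(min(h, w))))  # deepest Gaussian stays >= 1 px
    stack = build_stack(image, max(1, min(len(encoder_scales) - 1, n_possible)))
    out = []
    for i, (th, tw) in enumerate(encoder_scales):
        lap = stack.laplacians[min(i, stack.n_levels - 1)]
        if lap.shape[:2] != (th, tw):
            lap = bilinear_resize_np(lap, th, tw)
        out.append(lap)
    return out
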