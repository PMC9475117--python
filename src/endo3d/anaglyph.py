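"""Colour-difference (anaglyph) 3D rendering.

The red channel is resampled through the (gain-scaled) disparity field
toward the virtual right viewpoint while the blue-green channels stay
untouched, so red/cyan glasses present each eye a horizontally offset view.
Zero disparity is an exact fixed point, and the G/B channels of the output
are always bit-identical to the input's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnaglyphConfig", "make_anaglyph", "hole_fill"]


@dataclass(frozen=True)
class AnaglyphConfig:
    disparity_gain: float = 1.0
    fill_strategy: str = "clamp"        # clamp | inpaint-nearest
    direction: str = "toward_right"     # toward_right | toward_left

    def __post_init__(self):
        if self.disparity_gain <= 0:
            raise ValueError("disparity gain must be > 0")
        if self.fill_strategy not in ("clamp", "inpaint-nearest"):
            raise ValueError(f"unknown fill strategy {self.fill_strategy!r}")
        if self.direction not in ("toward_right", "toward_left"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _sample_channel(ch: np.ndarray, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear row-wise resample; returns (values, validity mask)."""
    h, w = ch.shape
    valid = (xs >= 0.0) & (xs <= w - 1.0)
    xc = np.clip(xs, 0.0, w - 1.0)
    x0 = np.minimum(np.floor(xc).astype(np.int64), w - 2)
    f = (xc - x0).astype(np.float32)
    rows = np.arange(h)[:, None]
    out = ch[rows, x0] * (1.0 - f) + ch[rows, x0 + 1] * f
    return out, valid


def hole_fill(channel: np.ndarray, validity_mask: np.ndarray,
              strategy: str = "clamp") -> np.ndarray:
    """Resolve pixels resampled from out of frame.

    ``clamp`` keeps the edge-clamped values; ``inpaint-nearest`` copies the
    nearest valid pixel along each row.
    """
    if strategy == "clamp":
        return channel
    if strategy != "inpaint-nearest":
        raise ValueError(f"unknown fill strategy {strategy!r}")
    out = channel.copy()
    h, w = channel.shape
    cols = np.arange(w)
    for y in range(h):
        invalid = ~validity_mask[y]
        if not invalid.any():
            continue
        valid_cols = cols[~invalid]
        if valid_cols.size == 0:
            continue
        nearest = valid_cols[np.argmin(np.abs(cols[invalid, None] - valid_cols[None, :]),
                                       axis=1)]
        out[y, invalid] = channel[y, nearest]
    return out


def make_anaglyph(image: np.ndarray, d: np.ndarray,
                  cfg: AnaglyphConfig = AnaglyphConfig()) -> np.ndarray:
    """Fuse a disparity-shifted red component with the original blue-green."""
    image = np.asarray(image, dtype=np.float32)
    d = np.asarray(d, dtype=np.float32)
    if d.shape != image.shape[:2]:
        raise ValueError(f"disparity shape {d.shape} != image shape {image.shape[:2]}")
    h, w = d.shape
    sign = 1.0 if cfg.direction == "toward_right" else -1.0
    xs = np.arange(w, dtype=np.float32)[None, :] + sign * cfg.disparity_gain * d
    red, valid = _sample_channel(image[..., 0], xs)
    red = hole_fill(red, valid, cfg.fill_strategy)
    out = image.copy()
    out[..., 0] = np.clip(red, 0.0, 1.0)
    return out
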