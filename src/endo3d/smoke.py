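"""Procedural surgical-smoke synthesis and compositing.

Electrocautery smoke is semi-transparent, locally near-white, and — unlike
scene fog — independent of depth.  A plume is modelled as deterministic
multi-octave turbulence shaped by a Gaussian falloff around a centre
position and scaled by a density parameter; it is composited onto a clean
frame by plain clipped addition, and a luminance mask is derived from the
plume's channels with the fixed weights (0.3, 0.59, 0.11).

Two fogging levels exist: *light* is a single render-and-composite pass, and
*dense* applies a second independent pass on top of the light result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import _value_noise

__all__ = ["SmokeParams", "render_smoke", "smoke_mask", "composite_smoke", "fog_dataset"]

MASK_WEIGHTS = (0.3, 0.59, 0.11)


@dataclass(frozen=True)
class SmokeParams:
    """Turbulence / density / position triple controlling one plume."""

    t_rand: float = 0.5       # turbulence scale in (0, 1]: higher = wispier
    d_rand: float = 0.5       # peak density in (0, 1]
    p_rand: tuple[float, float] = (0.5, 0.5)  # (x, y) centre, normalized
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.d_rand <= 1.0:
            raise ValueError("d_rand must lie in (0, 1]")
        if not all(0.0 <= c <= 1.0 for c in self.p_rand):
            raise ValueError("p_rand must lie in [0, 1]^2")


def render_smoke(params: SmokeParams, shape: tuple[int, int]) -> np.ndarray:
    """Render a near-grayscale smoke field in [0, 1], deterministic per seed.

    Intensity peaks around ``p_rand`` and decays with a Gaussian falloff;
    the whole field scales linearly with ``d_rand``, so density -> 0 makes
    the plume vanish.
    """
    h, w = shape
    rng = np.random.default_rng(params.seed)
    octaves = 2 + int(round(3 * params.t_rand))
    turb = _value_noise(rng, (h, w), octaves)
    cx, cy = params.p_rand
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    sigma = 0.28 * max(h, w)
    falloff = np.exp(-(((xx - cx * (w - 1)) ** 2) + ((yy - cy * (h - 1)) ** 2))
                     / (2.0 * sigma ** 2))
    gray = params.d_rand * falloff * (0.35 + 0.65 * turb)
    gray = np.clip(gray, 0.0, 1.0).astype(np.float32)
    # faint warm tint, well inside the near-grayscale tolerance
    field = np.stack([gray, gray * 0.99, gray * 0.97], axis=-1)
    return field


def smoke_mask(smoke: np.ndarray) -> np.ndarray:
    """Luminance mask: 0.3 R + 0.59 G + 0.11 B of the smoke field."""
    smoke = np.asarray(smoke, dtype=np.float32)
    if smoke.ndim != 3 or smoke.shape[-1] != 3:
        raise ValueError(f"smoke field must be HxWx3, got shape {smoke.shape}")
    r, g, b = MASK_WEIGHTS
    return r * smoke[..., 0] + g * smoke[..., 1] + b * smoke[..., 2]


def composite_smoke(clean: np.ndarray, smoke: np.ndarray) -> np.ndarray:
    """Additive superposition of plume over tissue, clipped to [0, 1]."""
    clean = np.asarray(clean, dtype=np.float32)
    smoke = np.asarray(smoke, dtype=np.float32)
    if clean.shape != smoke.shape:
        raise ValueError(f"shape mismatch: clean {clean.shape} vs smoke {smoke.shape}")
    return np.clip(clean + smoke, 0.0, 1.0)


def random_params(rng: np.random.Generator) -> SmokeParams:
    return SmokeParams(
        t_rand=float(rng.uniform(0.2, 1.0)),
        d_rand=float(rng.uniform(0.25, 0.55)),
        p_rand=(float(rng.uniform(0.25, 0.75)), float(rng.uniform(0.25, 0.75))),
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


def fog_dataset(cleans, level: str, seed: int, return_params: bool = False):
    """Fog a sequence of clean frames at the requested level.

    Light fog is one plume per frame; dense fog sends the light result
    through a second, independent plume, so dense luminance is never below
    light luminance.  Clean frames pass through untouched as labels.
    """
    if level not in ("light", "dense"):
        raise ValueError(f"unknown fog level {level!r}")
    cleans = list(cleans)
    if not cleans:
        raise ValueError("fog_dataset needs at least one frame")
    rng = np.random.default_rng(seed)
    pairs, all_params = [], []
    for clean in cleans:
        params = [random_params(rng)]
        fogged = composite_smoke(clean, render_smoke(params[0], clean.shape[:2]))
        if level == "dense":
            params.append(random_params(rng))
            fogged = composite_smoke(fogged, render_smoke(params[1], clean.shape[:2]))
        pairs.append((fogged, np.asarray(clean, dtype=np.float32)))
        all_params.append(params)
    if return_params:
        return pairs, all_params
    return pairs
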