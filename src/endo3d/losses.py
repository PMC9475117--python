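"""Differentiable warping and the self-supervised stereo loss stack.

The disparity network is trained without ground truth: a predicted left
disparity map warps the right image into a virtual left view (and vice
versa), and the loss scores how well the virtual views match the real ones.
Three ingredients combine:

* **photometric reconstruction error** — a per-pixel mix of structural
  dissimilarity and L1, ``pe = (alpha/2)(1 - SSIM) + (1 - alpha) |It - It'|``
  with ``alpha = 0.85``, taken as a per-pixel *minimum* over source views
  rather than an average so occluded pixels are not penalised twice;
* **left-right consistency** — L1 disagreement between one eye's disparity
  and the other eye's disparity sampled at the disparity-projected
  coordinate;
* **edge-aware smoothness** — first-order disparity gradients attenuated by
  ``exp(-|image gradient|)`` so depth edges may follow intensity edges.

An automatic binary mask ``mu`` keeps only pixels whose warped
reconstruction beats the *unwarped* source frame (strict inequality, ties
masked out); ``mu`` weights the photometric term only.  The total per scale is

    L = mu (Lp_r + Lp_l) + lambda (Llr_l + Llr_r + Lds_l + Lds_r)

and the per-scale totals of the four decoder scales are averaged.

Sign convention (package-wide): ``right(x) = left(x + d)``, so a left pixel
``x`` projects to right-image coordinate ``x - d_l(x)``, and the virtual
left view is the right image sampled there.  All sampling is bilinear with
edge clamping (a spatial-transformer-style weighted sum of the two
horizontal neighbours), differentiable in both the image and the disparity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (Tensor, as_tensor, box_sum_valid, gather_w, no_grad,
                       reflect_pad2d)

__all__ = [
    "LossWeights",
    "LossTerms",
    "bilinear_sample",
    "ssim_map",
    "photometric_error",
    "min_reprojection",
    "auto_mask",
    "lr_consistency",
    "edge_smoothness",
    "stereo_loss",
    "total_loss",
    "combine_terms",
    "disparity_search_oracle",
]


@dataclass
class LossWeights:
    alpha: float = 0.85        # SSIM vs L1 mix in the photometric error
    lam: float = 0.1           # weight of the consistency + smoothness block
    automask_enabled: bool = True
    ssim_window: int = 3

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


# ---------------------------------------------------------------------------
# array plumbing: public functions accept HxWx3 / HxW numpy or NCHW tensors
# ---------------------------------------------------------------------------

def _to_nchw(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, False
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr.transpose(2, 0, 1)[None]
    return Tensor(arr), True


def _from_nchw(t: Tensor, was_numpy: bool) -> np.ndarray | Tensor:
    if not was_numpy:
        return t
    arr = t.data[0]
    return arr[0] if arr.shape[0] == 1 else arr.transpose(1, 2, 0)


def _disp_to_n1hw(d) -> Tensor:
    if isinstance(d, Tensor):
        return d if d.ndim == 4 else d.reshape(1, 1, *d.shape)
    arr = np.asarray(d, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return Tensor(arr)


# ---------------------------------------------------------------------------
# differentiable horizontal warp (STN-style bilinear sampling)
# ---------------------------------------------------------------------------

def _warp_w(src: Tensor, disp: Tensor, sign: int) -> Tensor:
    N, C, H, W = src.shape
    xgrid = Tensor(np.broadcast_to(np.arange(W, dtype=np.float32), (1, 1, H, W)))
    xq = (xgrid + float(sign) * disp).clamp(0.0, float(W - 1))
    x0 = np.minimum(np.floor(xq.data), W - 2).astype(np.int64)
    frac = xq - Tensor(x0.astype(np.float32))
    ix0 = np.broadcast_to(x0[:, 0], (max(N, x0.shape[0]), H, W))
    if ix0.shape[0] != N:  # disparity batch broadcast
        ix0 = np.broadcast_to(ix0, (N, H, W))
    out = gather_w(src, ix0) * (1.0 - frac) + gather_w(src, ix0 + 1) * frac
    return out


def bilinear_sample(source, d, direction: str = "right_to_left"):
    """Warp ``source`` horizontally through disparity ``d``.

    ``direction='right_to_left'`` synthesises the left view from the right
    image using left disparity (samples at ``x - d``);
    ``direction='left_to_right'`` synthesises the right view from the left
    image (samples at ``x + d``).  Exact at integer coordinates; edges clamp.
    """
    signs = {"right_to_left": -1, "left_to_right": +1}
    if direction not in signs:
        raise ValueError(f"direction must be one of {sorted(signs)}, got {direction!r}")
    src, was_np = _to_nchw(source)
    disp = _disp_to_n1hw(d)
    if src.shape[2:] != disp.shape[2:]:
        raise ValueError(f"shape mismatch: image {src.shape} vs disparity {disp.shape}")
    return _from_nchw(_warp_w(src, disp, signs[direction]), was_np)


# ---------------------------------------------------------------------------
# SSIM and photometric error
# ---------------------------------------------------------------------------

def _box_filter(x: Tensor, k: int) -> Tensor:
    """k x k mean filter with reflective borders (same size output)."""
    H, W = x.shape[-2:]
    if k > min(H, W):
        raise ValueError(f"window {k} larger than image {H}x{W}")
    p = k // 2
    xp = reflect_pad2d(x, (p, p, p, p))
    return box_sum_valid(xp, k) * (1.0 / (k * k))


def ssim_map(x, y, window: int = 3, data_range: float = 1.0):
    """Per-pixel structural similarity of two images.

    Local statistics come from a ``window`` x ``window`` mean filter.  With
    the conventional choice c3 = c2/2 the luminance-contrast-structure
    product collapses to

        SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
               / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)),

    with c1 = (0.01 L)^2, c2 = (0.03 L)^2 for dynamic range L.
    Identical inputs give exactly 1 everywhere.
    """
    if not isinstance(x, Tensor) and not isinstance(y, Tensor):
        return _ssim_np(np.asarray(x), np.asarray(y), window, data_range)
    xt, was_np = _to_nchw(x)
    yt, _ = _to_nchw(y)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x = _box_filter(xt, window)
    mu_y = _box_filter(yt, window)
    var_x = _box_filter(xt * xt, window) - mu_x * mu_x
    var_y = _box_filter(yt * yt, window) - mu_y * mu_y
    cov = _box_filter(xt * yt, window) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + c1) * (2.0 * cov + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
    return _from_nchw(num / den, was_np)


def _box_np(a: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    pads = [(p, p), (p, p)] + [(0, 0)] * (a.ndim - 2)
    ap = np.pad(a, pads, mode="reflect")
    h, w = a.shape[:2]
    out = np.zeros_like(a)
    for i in range(k):
        for j in range(k):
            out += ap[i:i + h, j:j + w]
    return out / (k * k)


def _ssim_np(x: np.ndarray, y: np.ndarray, window: int, data_range: float) -> np.ndarray:
    """Double-precision numpy path for scoring (same windowed formulation)."""
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if window > min(x.shape[:2]):
        raise ValueError(f"window {window} larger than image {x.shape[:2]}")
    x = x.astype(np.float64)
    y = y.astype(np.float64)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_x, mu_y = _box_np(x, window), _box_np(y, window)
    var_x = _box_np(x * x, window) - mu_x ** 2
    var_y = _box_np(y * y, window) - mu_y ** 2
    cov = _box_np(x * y, window) - mu_x * mu_y
    return ((2 * mu_x * mu_y + c1) * (2 * cov + c2)
            / ((mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)))


def photometric_error(target, reconstructed, w: LossWeights | None = None):
    """Per-pixel photometric error map (channel-averaged, one per pixel)."""
    w = w or LossWeights()
    xt, was_np = _to_nchw(target)
    yt, _ = _to_nchw(reconstructed)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    ssim = ssim_map(xt, yt, window=w.ssim_window).mean(axis=1, keepdims=True)
    l1 = (xt - yt).abs().mean(axis=1, keepdims=True)
    pe = (w.alpha / 2.0) * (1.0 - ssim) + (1.0 - w.alpha) * l1
    if was_np:
        return pe.data[0, 0]
    return pe


def min_reprojection(errors):
    """Elementwise minimum over a list of per-pixel error maps."""
    errors = list(errors)
    if not errors:
        raise ValueError("min_reprojection needs at least one error map")
    if isinstance(errors[0], Tensor):
        out = errors[0]
        for e in errors[1:]:
            out = out.minimum(as_tensor(e))
        return out
    return np.minimum.reduce([np.asarray(e, dtype=np.float32) for e in errors])


def auto_mask(target, sources, warped, w: LossWeights | None = None) -> np.ndarray:
    """Binary mask keeping pixels whose best warped reconstruction strictly
    beats the best unwarped source frame; ties are masked out."""
    w = w or LossWeights()
    if len(sources) != len(warped):
        raise ValueError("sources and warped lists must have equal length")
    with no_grad():
        pe_w = [np.asarray(_pe_data(target, v, w)) for v in warped]
        pe_s = [np.asarray(_pe_data(target, s, w)) for s in sources]
    mu = (np.minimum.reduce(pe_w) < np.minimum.reduce(pe_s)).astype(np.float32)
    return mu


def _pe_data(a, b, w):
    pe = photometric_error(a, b, w)
    return pe.data if isinstance(pe, Tensor) else pe


def lr_consistency(d_l, d_r, side: str = "left"):
    """Mean L1 gap between one disparity map and the other, sampled at the
    disparity-projected coordinate (left pixel x looks up the right map at
    ``x - d_l(x)``; right pixel x looks up the left map at ``x + d_r(x)``)."""
    dl = _disp_to_n1hw(d_l)
    dr = _disp_to_n1hw(d_r)
    if dl.shape != dr.shape:
        raise ValueError("disparity shapes differ")
    if side == "left":
        projected = _warp_w(dr, dl, -1)
        gap = (dl - projected).abs().mean()
    elif side == "right":
        projected = _warp_w(dl, dr, +1)
        gap = (dr - projected).abs().mean()
    else:
        raise ValueError("side must be 'left' or 'right'")
    return gap if isinstance(d_l, Tensor) else gap.item()


def edge_smoothness(d, I):
    """Edge-weighted mean of first-order disparity gradients.

    Image gradients reduce over channels by mean absolute value; the weight
    ``exp(-|grad I|)`` lets disparity change freely across intensity edges.
    A linear ramp of slope g on a constant image scores exactly g.
    """
    dt = _disp_to_n1hw(d)
    it, _ = _to_nchw(I)
    if dt.shape[2:] != it.shape[2:]:
        raise ValueError("disparity/image spatial shapes differ")
    dx_d = (dt[:, :, :, 1:] - dt[:, :, :, :-1]).abs()
    dy_d = (dt[:, :, 1:, :] - dt[:, :, :-1, :]).abs()
    wx = ((it[:, :, :, 1:] - it[:, :, :, :-1]).abs().mean(axis=1, keepdims=True) * -1.0).exp()
    wy = ((it[:, :, 1:, :] - it[:, :, :-1, :]).abs().mean(axis=1, keepdims=True) * -1.0).exp()
    loss = (dx_d * wx).mean() + (dy_d * wy).mean()
    return loss if isinstance(d, Tensor) else loss.item()


# ---------------------------------------------------------------------------
# assembled loss
# ---------------------------------------------------------------------------

@dataclass
class LossTerms:
    photometric_left: Tensor
    photometric_right: Tensor
    lr_consistency_left: Tensor
    lr_consistency_right: Tensor
    smoothness_left: Tensor
    smoothness_right: Tensor
    mask: np.ndarray
    mask_right: np.ndarray
    total: Tensor
    scale: int = 0

    def scalars(self) -> dict[str, float]:
        out = {}
        for k in ("photometric_left", "photometric_right", "lr_consistency_left",
                  "lr_consistency_right", "smoothness_left", "smoothness_right", "total"):
            v = getattr(self, k)
            out[k] = float(v.data) if isinstance(v, Tensor) else float(v)
        out["mask_fraction"] = float(np.mean(self.mask))
        return out


def combine_terms(photo_l, photo_r, lr_l, lr_r, ds_l, ds_r, w: LossWeights):
    """The total-loss combination on already-reduced (mask-weighted) terms:
    ``(Lp_r + Lp_l) + lambda (Llr_l + Llr_r + Lds_l + Lds_r)``."""
    return (photo_l + photo_r) + w.lam * (lr_l + lr_r + ds_l + ds_r)


def stereo_loss(left, right, d_l, d_r, w: LossWeights | None = None,
                scale: int = 0, pe_identity_left: np.ndarray | None = None,
                pe_identity_right: np.ndarray | None = None) -> LossTerms:
    """Full loss for one scale of one stereo batch.

    ``pe_identity_left/right`` optionally supply precomputed unwarped-source
    error maps for the auto-mask (they do not depend on the network, so a
    training loop can compute them once per sample).
    """
    w = w or LossWeights()
    lt, _ = _to_nchw(left)
    rt, _ = _to_nchw(right)
    dl = _disp_to_n1hw(d_l)
    dr = _disp_to_n1hw(d_r)
    recon_l = _warp_w(rt, dl, -1)
    recon_r = _warp_w(lt, dr, +1)
    pe_l = photometric_error(lt, recon_l, w)
    pe_r = photometric_error(rt, recon_r, w)
    if w.automask_enabled:
        with no_grad():
            pe_id_l = pe_identity_left if pe_identity_left is not None \
                else photometric_error(lt.detach(), rt.detach(), w).data
            pe_id_r = pe_identity_right if pe_identity_right is not None \
                else photometric_error(rt.detach(), lt.detach(), w).data
        mu_l = (pe_l.data < pe_id_l).astype(np.float32)
        mu_r = (pe_r.data < pe_id_r).astype(np.float32)
    else:
        mu_l = np.ones(pe_l.shape, dtype=np.float32)
        mu_r = np.ones(pe_r.shape, dtype=np.float32)
    photo_l = (pe_l * Tensor(mu_l)).mean()
    photo_r = (pe_r * Tensor(mu_r)).mean()
    lr_l = lr_consistency(dl, dr, "left")
    lr_r = lr_consistency(dl, dr, "right")
    ds_l = edge_smoothness(dl, lt)
    ds_r = edge_smoothness(dr, rt)
    total = combine_terms(photo_l, photo_r, lr_l, lr_r, ds_l, ds_r, w)
    return LossTerms(photometric_left=photo_l, photometric_right=photo_r,
                     lr_consistency_left=lr_l, lr_consistency_right=lr_r,
                     smoothness_left=ds_l, smoothness_right=ds_r,
                     mask=mu_l, mask_right=mu_r, total=total, scale=scale)


def total_loss(per_scale_terms: list[LossTerms], w: LossWeights | None = None) -> Tensor:
    """Average the per-scale totals over the emitted disparity scales."""
    if not per_scale_terms:
        raise ValueError("no per-scale terms given")
    acc = per_scale_terms[0].total
    for t in per_scale_terms[1:]:
        acc = acc + t.total
    return acc * (1.0 / len(per_scale_terms))


# ---------------------------------------------------------------------------
# non-learning verifier: exhaustive photometric search
# ---------------------------------------------------------------------------

def disparity_search_oracle(left: np.ndarray, right: np.ndarray,
                            d_candidates, agg_window: int = 9,
                            w: LossWeights | None = None) -> np.ndarray:
    """Per-pixel argmin of the photometric error over constant candidate
    shifts, box-aggregated for stability.  A brute-force, training-free
    cross-check of the photometric objective."""
    w = w or LossWeights()
    cands = np.asarray(list(d_candidates), dtype=np.float32)
    if cands.size == 0:
        raise ValueError("candidate set is empty")
    h, w_img = left.shape[:2]
    costs = np.empty((cands.size, h, w_img), dtype=np.float32)
    with no_grad():
        for i, c in enumerate(cands):
            recon = bilinear_sample(right, np.full((h, w_img), c, np.float32),
                                    "right_to_left")
            pe = photometric_error(left, recon, w)
            pe_t, _ = _to_nchw(pe)
            costs[i] = _box_filter(pe_t, agg_window).data[0, 0]
    return cands[np.argmin(costs, axis=0)]
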