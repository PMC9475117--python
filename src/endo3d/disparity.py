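"""Self-supervised disparity network with hierarchical split blocks.

The encoder is a compact HS-ResNet: a 7x7 stride-2 batch-normalised
pre-convolution, then four stride-2 stages whose feature extractor is a
*hierarchical split block* (HSB).  An HSB first mixes channels with a 1x1
convolution, splits the result into ``s`` groups, and lets group i's 3x3
convolution see its own split concatenated with half of the previous
group's output:

    y_i = x_i                     for i = 1
    y_i = f_i([x_i ; carry_{i-1}]) for 1 < i <= s,

where each y_i (except the last) is split into an emitted half (floor) and
a carried half (ceil).  The emitted halves concatenate into the block
output; choosing width-preserving convolutions makes the output width equal
the input width for every s, while using strictly fewer parameters than one
standard k x k convolution over the same width.  Each block sits inside a
residual connection.

The decoder mirrors the encoder with 3x3 stride-2 transposed convolutions
and skip connections; the last four decoder scales emit left and right
disparity maps through sigmoid heads scaled to ``max_disparity_fraction``
of that scale's width, so predicted disparity is bounded and warps stay
valid.  The network sees only the left image; supervision comes from the
stereo loss stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, bilinear_resize, concat, no_grad
from .losses import LossWeights, stereo_loss, total_loss
from .nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Module, set_training
from .synthetic import bilinear_resize_np

__all__ = ["HSBConfig", "DispNetSpec", "DispTrainConfig", "HSBlock", "DispNet",
           "build_disp_net", "hsb_param_count", "predict_disparity",
           "train_disparity"]


@dataclass(frozen=True)
class HSBConfig:
    s: int = 5      # number of split groups
    k: int = 3      # group convolution kernel

    def __post_init__(self):
        if self.s < 2:
            raise ValueError("HSB needs at least 2 groups")


@dataclass(frozen=True)
class DispNetSpec:
    encoder_channels: tuple = (16, 32, 64, 128, 256)
    decoder_channels: tuple = (256, 128, 64, 32, 16)
    disparity_scales: int = 4
    max_disparity_fraction: float = 0.3
    hsb: HSBConfig = HSBConfig()
    width_multiplier: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.max_disparity_fraction < 1.0:
            raise ValueError("max_disparity_fraction must lie in (0, 1)")

    def scaled(self, channels: tuple) -> tuple:
        return tuple(max(2, int(round(c * self.width_multiplier))) for c in channels)


def _partition(total: int, parts: int) -> list[int]:
    """Split ``total`` channels into ``parts`` near-equal nonzero groups."""
    parts = max(1, min(parts, total))
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


class HSBlock(Module):
    """One hierarchical split block; output width equals ``width``."""

    def __init__(self, width: int, cfg: HSBConfig = HSBConfig(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.width = width
        self.splits = _partition(width, cfg.s)
        self.s_eff = len(self.splits)
        self.mix = Conv2d(width, width, 1, rng=rng)
        self.convs: list = []
        carry = 0
        k = cfg.k
        for i in range(1, self.s_eff):
            c_in = self.splits[i] + carry
            c_out = c_in  # width-preserving: conserves total channels exactly
            self.convs.append(Conv2d(c_in, c_out, k, padding=k // 2, rng=rng))
            carry = -(-c_out // 2) if i < self.s_eff - 1 else 0  # ceil half carried

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.width:
            raise ValueError(f"expected {self.width} channels, got {x.shape[1]}")
        x = self.mix(x)
        groups = []
        start = 0
        for c in self.splits:
            groups.append(x[:, start:start + c])
            start += c
        emitted = [groups[0]]
        carry = None
        for i in range(1, self.s_eff):
            inp = groups[i] if carry is None else concat([groups[i], carry], axis=1)
            y = self.convs[i - 1](inp).relu()
            if i < self.s_eff - 1:
                c_total = y.shape[1]
                emit_n = c_total // 2
                emitted.append(y[:, :emit_n])
                carry = y[:, emit_n:]
            else:
                emitted.append(y)
        return concat(emitted, axis=1)

    def conv_weight_count(self) -> int:
        """Number of convolution weight elements (biases excluded)."""
        n = 0
        for conv in [self.mix] + self.convs:
            n += conv.weight.size
        return n


def hsb_param_count(k: int, w: int, s: int) -> tuple[int, int]:
    """Counted HSB weights vs the standard-convolution count k^2 s^2 w^2.

    ``w`` is the per-group width, so the block operates on s*w channels; the
    reference is one k x k convolution mapping s*w channels to s*w channels.
    """
    block = HSBlock(s * w, HSBConfig(s=s, k=k))
    p_standard = k * k * s * s * w * w
    return block.conv_weight_count(), p_standard


class _ResHSB(Module):
    """Residual wrapper: stride-2 entry conv, HSB, identity/projection add."""

    def __init__(self, c_in: int, c_out: int, cfg: HSBConfig,
                 rng: np.random.Generator):
        self.down = Conv2d(c_in, c_out, 3, stride=2, padding=1, rng=rng)
        self.block = HSBlock(c_out, cfg, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.down(x).relu()
        return (self.block(x) + x).relu()


class DispNet(Module):
    def __init__(self, spec: DispNetSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        enc = spec.scaled(spec.encoder_channels)
        dec = spec.scaled(spec.decoder_channels)
        self.pre = Conv2d(3, enc[0], 7, stride=2, padding=3, rng=rng)
        self.pre_bn = BatchNorm2d(enc[0])
        self.stages = [
            _ResHSB(enc[i], enc[i + 1], spec.hsb, rng) for i in range(4)
        ]
        self.up: list = []
        self.fuse: list = []
        skip_ch = [enc[3], enc[2], enc[1], enc[0], 0]
        d_in = enc[4]
        for j, c_out in enumerate(dec):
            self.up.append(ConvTranspose2d(d_in, c_out, 3, rng=rng))
            self.fuse.append(Conv2d(c_out + skip_ch[j], c_out, 3, padding=1, rng=rng))
            d_in = c_out
        self.heads = [Conv2d(dec[j], 2, 3, padding=1, rng=rng)
                      for j in range(5 - spec.disparity_scales, 5)]
        for head in self.heads:
            # start from a small-disparity (far-geometry) prior: sigmoid(-2)
            # lands the initial prediction inside the photometric basin
            head.bias.data[:] = -2.0

    def forward(self, left: Tensor) -> dict[int, tuple[Tensor, Tensor]]:
        """Return {scale_divisor: (d_left, d_right)} for the last 4 decoder
        scales; disparities are in pixels at their own scale."""
        n, _, h, w = left.shape
        if h % 32 or w % 32:
            ph, pw = -(-h // 32) * 32, -(-w // 32) * 32
            left = bilinear_resize(left, ph, pw)
            h, w = ph, pw
        x = self.pre_bn(self.pre(left)).relu()
        skips = [x]
        for stage in self.stages:
            x = stage(x)
            skips.append(x)
        sizes = [s.shape[2:] for s in skips]  # /2, /4, /8, /16, /32
        targets = sizes[-2::-1] + [(h, w)]    # /16, /8, /4, /2, /1
        outputs: dict[int, tuple[Tensor, Tensor]] = {}
        head_start = 5 - self.spec.disparity_scales
        for j in range(5):
            x = self.up[j](x)
            if x.shape[2:] != targets[j]:
                x = bilinear_resize(x, *targets[j])
            if j < 4:
                x = concat([x, skips[3 - j]], axis=1)
            x = self.fuse[j](x).relu()
            if j >= head_start:
                w_scale = x.shape[3]
                raw = self.heads[j - head_start](x).sigmoid()
                bound = self.spec.max_disparity_fraction * w_scale
                d = raw * bound
                divisor = w // w_scale
                outputs[divisor] = (d[:, 0:1], d[:, 1:2])
        return outputs


def build_disp_net(spec: DispNetSpec, seed: int = 0) -> DispNet:
    return DispNet(spec, seed=seed)


def predict_disparity(net: DispNet, left: np.ndarray) -> np.ndarray:
    """Full-resolution left disparity (pixels) for one HxWx3 frame."""
    h, w = left.shape[:2]
    h32, w32 = max(32, -(-h // 32) * 32), max(32, -(-w // 32) * 32)
    img = left if (h, w) == (h32, w32) else bilinear_resize_np(left, h32, w32)
    set_training(net, False)
    with no_grad():
        out = net(Tensor(img.transpose(2, 0, 1)[None]))
    d = out[1][0].data[0, 0]
    if (h, w) != (h32, w32):
        d = bilinear_resize_np(d, h, w) * (w / w32)
    return np.maximum(d, 0.0)


@dataclass(frozen=True)
class DispTrainConfig:
    input_size: tuple[int, int] = (128, 256)   # (H, W)
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 10
    seed: int = 0
    head_lr_multiplier: float = 1.0  # larger steps for the bounded sigmoid heads


def train_disparity(pairs, spec: DispNetSpec, cfg: DispTrainConfig,
                    weights: LossWeights | None = None,
                    progress=None) -> tuple[DispNet, list[float]]:
    """Self-supervised Adam training on (left, right) pairs.

    Per batch: forward the left image, then for each emitted scale resize
    both images to that scale, evaluate the stereo loss, and average the
    per-scale totals.  Returns the net and per-epoch mean loss history.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty training set")
    weights = weights or LossWeights()
    net = build_disp_net(spec, seed=cfg.seed)
    if cfg.epochs == 0:
        return net, []
    h, w = cfg.input_size
    lefts = np.stack([_prep(p[0], h, w) for p in pairs])
    rights = np.stack([_prep(p[1], h, w) for p in pairs])
    # unwarped-source error maps for the auto-mask are network-independent:
    # compute once per sample per scale
    scale_imgs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    pe_id: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    with no_grad():
        for divisor in (1, 2, 4, 8):
            if divisor == 1:
                ls, rs = lefts, rights
            else:
                ls = _resize_batch(lefts, h // divisor, w // divisor)
                rs = _resize_batch(rights, h // divisor, w // divisor)
            scale_imgs[divisor] = (ls, rs)
            if weights.automask_enabled:
                pe_id[divisor] = (
                    _photometric_np(ls, rs, weights),
                    _photometric_np(rs, ls, weights),
                )
    head_params = [p for h in net.heads for p in (h.weight, h.bias)]
    head_ids = {id(p) for p in head_params}
    trunk_params = [p for p in net.parameters() if id(p) not in head_ids]
    opts = [Adam(trunk_params, lr=cfg.learning_rate),
            Adam(head_params, lr=cfg.learning_rate * cfg.head_lr_multiplier)]
    rng = np.random.default_rng(cfg.seed + 1)
    history = []
    set_training(net, True)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            outputs = net(Tensor(lefts[idx]))
            terms = []
            for divisor, (d_l, d_r) in sorted(outputs.items()):
                ls_all, rs_all = scale_imgs[divisor]
                ls, rs = Tensor(ls_all[idx]), Tensor(rs_all[idx])
                id_l, id_r = pe_id.get(divisor, (None, None))
                terms.append(stereo_loss(
                    ls, rs, d_l, d_r, weights, scale=divisor,
                    pe_identity_left=None if id_l is None else id_l[idx],
                    pe_identity_right=None if id_r is None else id_r[idx]))
            loss = total_loss(terms)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"loss became non-finite at epoch {epoch}")
            for opt in opts:
                opt.zero_grad()
            loss.backward()
            for opt in opts:
                opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if progress is not None:
            progress(epoch, history[-1])
    return net, history


def _prep(img: np.ndarray, h: int, w: int) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    if img.shape[:2] != (h, w):
        img = bilinear_resize_np(img, h, w)
    return img.transpose(2, 0, 1)


def _photometric_np(targets: np.ndarray, sources: np.ndarray,
                    weights: LossWeights) -> np.ndarray:
    from .losses import photometric_error
    return photometric_error(Tensor(targets), Tensor(sources), weights).data


def _resize_batch(batch: np.ndarray, h: int, w: int) -> np.ndarray:
    return np.stack([
        bilinear_resize_np(im.transpose(1, 2, 0), h, w).transpose(2, 0, 1)
        for im in batch
    ])
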