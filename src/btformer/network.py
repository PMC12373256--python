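"""BTFormer: encoder–decoder segmentation network with axial-free attention.

The encoder is a two-block convolutional stem (the first block halves the
resolution with a 2×2 max pool, the second keeps it) followed by a stack of
axial-free attention blocks, each of which halves the resolution.  The
decoder mirrors the encoder with ×2 upsampling, channel-concatenation skip
fusion and Conv-BN-ReLU layers; a 1×1 convolution produces the 5-class
logits at the input resolution.  Optional deep-supervision heads emit
auxiliary logits at every intermediate decoder scale.

Stage widths, stage count and stem layout are configurable; the defaults
here are implementation choices documented in the methods note, not values
fixed by the architecture itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import AFABlock
from .nn import (Conv2d, ConvBNReLU, Module, Sequential, MaxPool2x2,
                 UpsampleBilinear2x, TransposedConvUp2x)

__all__ = ["NetworkConfig", "LogitsBundle", "BTFormer", "count_params_flops"]


@dataclass
class NetworkConfig:
    in_channels: int = 1
    class_count: int = 5
    input_size: int = 256
    stem_channels: int = 32
    stage_channels: tuple = (64, 128, 256)
    D: int = 4
    heads: int = 2
    agg: str = "soft"
    pe: str = "lsrpe"
    deep_supervision: bool = True
    upsample: str = "bilinear"  # or "tconv"
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        if self.class_count <= 1:
            raise ValueError("class_count must be at least 2")
        if not self.stage_channels:
            raise ValueError("at least one attention stage is required")
        if any(c <= 0 for c in self.stage_channels) or self.stem_channels <= 0:
            raise ValueError("channel widths must be positive")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type

    @property
    def divisor(self) -> int:
        """Input spatial sizes must be divisible by this (stem pool + one pool
        per attention stage)."""
        return 2 ** (len(self.stage_channels) + 1)

    @classmethod
    def tiny(cls, **overrides) -> "NetworkConfig":
        """Desk-scale model for 64×64 phantoms (~0.2M parameters)."""
        base = dict(input_size=64, stem_channels=16, stage_channels=(32, 64),
                    D=4, heads=2)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class LogitsBundle:
    """Main logits (class_count, input H, input W) plus coarse-to-fine
    auxiliary logits when deep supervision is enabled."""

    main: Tensor
    aux: list = field(default_factory=list)


class BTFormer(Module):
    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dt = cfg.np_dtype
        c0 = cfg.stem_channels
        self.stem1 = Sequential(ConvBNReLU(cfg.in_channels, c0, rng=rng, dtype=dt),
                                ConvBNReLU(c0, c0, rng=rng, dtype=dt),
                                MaxPool2x2())
        self.stem2 = Sequential(ConvBNReLU(c0, c0, rng=rng, dtype=dt),
                                ConvBNReLU(c0, c0, rng=rng, dtype=dt))
        stages = []
        in_ch = c0
        res = cfg.input_size // 2
        for c in cfg.stage_channels:
            stages.append(AFABlock(in_ch, c, D=cfg.D, heads=cfg.heads, max_len=res,
                                   agg=cfg.agg, pe=cfg.pe, rng=rng, dtype=dt))
            in_ch = c
            res //= 2
        self.stages = stages
        # decoder: one stage per attention block, finest last
        dec = []
        ups = []
        skip_chs = [c0] + list(cfg.stage_channels[:-1])
        prev = cfg.stage_channels[-1]
        for skip_ch in reversed(skip_chs):
            ups.append(self._make_up(prev, rng, dt))
            dec.append(ConvBNReLU(prev + skip_ch, skip_ch, rng=rng, dtype=dt))
            prev = skip_ch
        self.ups = ups
        self.dec = dec
        self.final_up = self._make_up(c0, rng, dt)
        self.final_conv = ConvBNReLU(c0, c0, rng=rng, dtype=dt)
        self.head = Conv2d(c0, cfg.class_count, kernel=1, rng=rng, dtype=dt)
        if cfg.deep_supervision:
            self.aux_heads = [Conv2d(c, cfg.class_count, kernel=1, rng=rng, dtype=dt)
                              for c in reversed(skip_chs)]
        else:
            self.aux_heads = []

    def _make_up(self, channels: int, rng, dt) -> Module:
        if self.cfg.upsample == "tconv":
            return TransposedConvUp2x(channels, rng=rng, dtype=dt)
        return UpsampleBilinear2x()

    def forward(self, x: Tensor) -> LogitsBundle:
        H, W = x.shape[-2:]
        d = self.cfg.divisor
        if H % d or W % d:
            raise ValueError(f"input spatial size {H}x{W} must be divisible by {d}")
        f = self.stem2(self.stem1(x))
        skips = [f]
        for stage in self.stages:
            f = stage(f)
            skips.append(f)
        skips = skips[:-1]  # last stage output is the bottleneck itself
        aux = []
        for up, conv, skip, head in zip(
                self.ups, self.dec, reversed(skips),
                self.aux_heads or [None] * len(self.dec)):
            f = conv(ad.concatenate([up(f), skip], axis=1))
            if head is not None:
                aux.append(head(f))
        main = self.head(self.final_conv(self.final_up(f)))
        return LogitsBundle(main=main, aux=aux)

    def predict_probs(self, x: Tensor) -> np.ndarray:
        """Class probabilities (B, K, H, W) in eval mode."""
        was_training = self.training
        self.eval()
        out = ad.softmax(self.forward(x).main, axis=1).data
        if was_training:
            self.train()
        return out


# ----------------------------------------------------------------------
# analytic parameter / FLOP counting
# ----------------------------------------------------------------------

def _conv_params(ci, co, k, bn=True):
    return co * ci * k * k + co + (2 * co if bn else 0)


def _conv_macs(ci, co, k, h, w):
    return ci * co * k * k * h * w


def count_params_flops(cfg: NetworkConfig) -> tuple[int, int]:
    """Analytic parameter and multiply-accumulate counts for one forward pass
    at the configured input size.

    Attention FLOPs use bank-length accounting: at resolution H×W with bank
    length L and output width Co, the logit and value stages cost
    O(H·W·L·Co) each, never O(H²W²).
    """
    S = cfg.input_size
    c0 = cfg.stem_channels
    cin = cfg.in_channels
    K = cfg.class_count
    params = 0
    macs = 0
    # stem block 1 (pooled) and block 2
    params += _conv_params(cin, c0, 3) + _conv_params(c0, c0, 3) * 3
    macs += _conv_macs(cin, c0, 3, S, S) + _conv_macs(c0, c0, 3, S, S)
    h = S // 2
    macs += 2 * _conv_macs(c0, c0, 3, h, h)
    # attention stages
    in_ch = c0
    for c in cfg.stage_channels:
        L = h  # square feature maps: bank length equals the stage resolution
        params += _conv_params(in_ch, c, 1)          # conv_in + bn
        macs += _conv_macs(in_ch, c, 1, h, h)
        per_dir_params = 3 * c * c                   # W_Q, W_K, W_V (no bias)
        if cfg.pe in ("lsrpe", "lrpe"):
            per_dir_params += 3 * (2 * L - 1) * c    # one table per role, all heads
        params += cfg.D * per_dir_params
        # per direction: qkv projections + logits (content + 2 positional) +
        # weighted values; off-axis directions add two bilinear resamplings
        per_dir_macs = 3 * c * c * h * h + 4 * h * h * L * c
        axis_dirs = 1 + (1 if cfg.D >= 2 and cfg.D % 2 == 0 else 0)
        per_dir_macs_offaxis = per_dir_macs + 2 * 4 * c * h * h
        macs += axis_dirs * per_dir_macs + (cfg.D - axis_dirs) * per_dir_macs_offaxis
        if cfg.agg == "soft":
            params += cfg.D * (c * c + c) + (cfg.D * c) * c + c
            macs += cfg.D * c * c + _conv_macs(cfg.D * c, c, 1, h, h)
        elif cfg.agg == "agg":
            params += cfg.D * (c * c + c)
            macs += cfg.D * c * c
        elif cfg.agg == "cat":
            params += (cfg.D * c) * c + c
            macs += _conv_macs(cfg.D * c, c, 1, h, h)
        elif cfg.agg == "wadd":
            params += cfg.D
        params += _conv_params(c, c, 1)              # conv_out + bn
        macs += _conv_macs(c, c, 1, h, h)
        if in_ch != c:
            params += c * in_ch + c                  # skip projection
            macs += _conv_macs(in_ch, c, 1, h, h)
        in_ch = c
        h //= 2
    # decoder
    skip_chs = [c0] + list(cfg.stage_channels[:-1])
    prev = cfg.stage_channels[-1]
    for skip_ch in reversed(skip_chs):
        h *= 2
        if cfg.upsample == "tconv":
            params += prev * prev * 9 + prev
            macs += _conv_macs(prev, prev, 3, h, h)
        params += _conv_params(prev + skip_ch, skip_ch, 3)
        macs += _conv_macs(prev + skip_ch, skip_ch, 3, h, h)
        if cfg.deep_supervision:
            params += K * skip_ch + K
            macs += _conv_macs(skip_ch, K, 1, h, h)
        prev = skip_ch
    h *= 2
    if cfg.upsample == "tconv":
        params += c0 * c0 * 9 + c0
        macs += _conv_macs(c0, c0, 3, h, h)
    params += _conv_params(c0, c0, 3)
    macs += _conv_macs(c0, c0, 3, h, h)
    params += K * c0 + K
    macs += _conv_macs(c0, K, 1, h, h)
    return params, macs
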