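"""Axial-free attention blocks: D parallel directions fused by soft aggregation.

A block runs D axial-free attention layers at the uniformly spaced angles
{d·π/D} in parallel, fuses the aligned per-direction outputs, wraps the
transform in a residual, and halves the resolution with a 2×2 max pool.

Soft aggregation fuses the D outputs with two branches:

* an aggregation branch — each direction's map is summed over space to a
  per-channel descriptor, scored by a per-direction channel mixer, and a
  softmax across directions (per channel) weights the maps;
* a concatenation branch — channel concatenation of all D maps followed by
  a 1×1 convolution back to the block width;

the block output is the sum of the two branches.  The simpler aggregation
variants used in ablations (plain add, learnable-scalar add, concatenation
only, aggregation branch only) share the same interface.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .attention import AxialFreeAttention
from .autodiff import Tensor
from .geometry import make_angle_set
from .nn import BatchNorm2d, Conv2d, Module, Parameter

__all__ = ["SoftAggregate", "AddAggregate", "WeightedAddAggregate", "CatAggregate",
           "AggOnlyAggregate", "AFABlock", "make_aggregator", "AGGREGATOR_KINDS"]


class SoftAggregate(Module):
    """Softmax-weighted direction fusion plus a concatenation branch."""

    def __init__(self, D: int, channels: int, rng: np.random.Generator | None = None,
                 dtype=np.float64, with_cat: bool = True, with_agg: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.D = D
        self.with_cat = with_cat
        self.with_agg = with_agg
        scale = 1.0 / np.sqrt(channels)
        if with_agg:
            # per-direction 1-layer channel mixer scoring the global descriptor
            self.scorer_w = Parameter((rng.standard_normal((D, channels, channels)) * scale).astype(dtype))
            self.scorer_b = Parameter(np.zeros((D, channels), dtype=dtype))
        if with_cat:
            self.conv_cat = Conv2d(D * channels, channels, kernel=1, rng=rng, dtype=dtype)

    def direction_weights(self, ys: list[Tensor]) -> Tensor:
        """Per-(sample, direction, channel) softmax weights; sum to 1 over D."""
        descriptors = [y.sum(axis=(2, 3)) for y in ys]             # D × (B, C)
        logits = ad.stack(
            [ad.einsum("oc,bc->bo", self.scorer_w[d], s) + self.scorer_b[d]
             for d, s in enumerate(descriptors)], axis=1)          # (B, D, C)
        return ad.softmax(logits, axis=1)

    def forward(self, ys: list[Tensor]) -> Tensor:
        if len(ys) != self.D:
            raise ValueError(f"expected {self.D} direction outputs, got {len(ys)}")
        shape = ys[0].shape
        for y in ys[1:]:
            if y.shape != shape:
                raise ValueError("direction outputs must share one shape")
        out = None
        if self.with_agg:
            w = self.direction_weights(ys)                         # (B, D, C)
            stacked = ad.stack(ys, axis=1)                         # (B, D, C, H, W)
            out = ad.einsum("bdc,bdchw->bchw", w, stacked)
        if self.with_cat:
            cat = self.conv_cat(ad.concatenate(ys, axis=1))
            out = cat if out is None else out + cat
        return out


class AddAggregate(Module):
    """Unweighted sum of direction outputs."""

    def __init__(self, D: int, channels: int, rng=None, dtype=np.float64):
        super().__init__()
        self.D = D

    def forward(self, ys: list[Tensor]) -> Tensor:
        out = ys[0]
        for y in ys[1:]:
            out = out + y
        return out


class WeightedAddAggregate(Module):
    """Sum with one learnable scalar per direction (initialized to 1)."""

    def __init__(self, D: int, channels: int, rng=None, dtype=np.float64):
        super().__init__()
        self.D = D
        self.alphas = Parameter(np.ones(D, dtype=dtype))

    def forward(self, ys: list[Tensor]) -> Tensor:
        out = None
        for d, y in enumerate(ys):
            term = y * self.alphas[d]
            out = term if out is None else out + term
        return out


def CatAggregate(D, channels, rng=None, dtype=np.float64):
    return SoftAggregate(D, channels, rng=rng, dtype=dtype, with_agg=False)


def AggOnlyAggregate(D, channels, rng=None, dtype=np.float64):
    return SoftAggregate(D, channels, rng=rng, dtype=dtype, with_cat=False)


AGGREGATOR_KINDS = {
    "add": AddAggregate,
    "wadd": WeightedAddAggregate,
    "cat": CatAggregate,
    "agg": AggOnlyAggregate,
    "soft": SoftAggregate,
}


def make_aggregator(kind: str, D: int, channels: int, rng=None, dtype=np.float64) -> Module:
    if kind not in AGGREGATOR_KINDS:
        raise ValueError(f"unknown aggregation {kind!r}; choose from {sorted(AGGREGATOR_KINDS)}")
    return AGGREGATOR_KINDS[kind](D, channels, rng=rng, dtype=dtype)


class AFABlock(Module):
    """Residual axial-free attention block with 2×2 max pooling.

    Transform path: 1×1 conv (+BN+ReLU) → D parallel attention layers at the
    angles of ``make_angle_set(D)`` → aggregation → 1×1 conv (+BN); the skip
    is the identity (a 1×1 projection only when the channel count changes);
    the two paths are summed, passed through ReLU and pooled.  Every
    direction has independent projection weights and positional tables.
    """

    def __init__(self, in_ch: int, out_ch: int, D: int = 4, heads: int = 2,
                 max_len: int = 64, agg: str = "soft", pe: str = "lsrpe",
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.D = D
        self.angle_set = make_angle_set(D)
        self.conv_in = Conv2d(in_ch, out_ch, kernel=1, rng=rng, dtype=dtype)
        self.bn_in = BatchNorm2d(out_ch, dtype=dtype)
        self.attn = [AxialFreeAttention(out_ch, out_ch, heads=heads, max_len=max_len,
                                        pe=pe, rng=rng, dtype=dtype) for _ in range(D)]
        self.agg = make_aggregator(agg, D, out_ch, rng=rng, dtype=dtype)
        self.conv_out = Conv2d(out_ch, out_ch, kernel=1, rng=rng, dtype=dtype)
        self.bn_out = BatchNorm2d(out_ch, dtype=dtype)
        self.skip = Conv2d(in_ch, out_ch, kernel=1, rng=rng, dtype=dtype) \
            if in_ch != out_ch else None

    def forward(self, x: Tensor, pool: bool = True) -> Tensor:
        h = ad.relu(self.bn_in(self.conv_in(x)))
        ys = [layer(h, theta) for layer, theta in zip(self.attn, self.angle_set.angles)]
        fused = self.agg(ys)
        main = self.bn_out(self.conv_out(fused))
        skip = self.skip(x) if self.skip is not None else x
        out = ad.relu(skip + main)
        return ad.maxpool2x2(out) if pool else out
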