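"""Angle-parameterized 1D attention with relative positional encodings.

One axial-free attention layer attends, for every anchor pixel, over a 1D
bank of pixels lying on the line through the anchor at angle θ.  For
θ ∈ [0, π/2) the feature map is resampled on a grid rotated by θ and the
banks are its rows (length W); for θ ∈ [π/2, π) the map is rotated by
θ − π/2 and the banks are its columns (length H), so the layer's cost is
O(H·W·W) or O(H·W·H) rather than the O(H²W²) of dense 2D attention.

Attention logits combine a content term q·k with two positional terms
q·rᵠ and k·rᴷ, and the values receive an additive positional term rⱽ;
the positional vectors are indexed by the signed along-bank offset b−a.
The default encoding (LSRPE) is the elementwise sine of learnable
parameters constrained to [0, π/2], so encoded values lie in [0, 1].
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import geometry
from .autodiff import Tensor
from .nn import Module, Parameter

__all__ = ["NoPE", "LRPE", "LSRPE", "AxialFreeAttention", "make_positional_encoding"]

_ROLES = ("Q", "K", "V")


class NoPE(Module):
    """Positional-encoding stub: attention is purely content-based."""

    def __init__(self, max_offset: int, heads: int, head_dim: int, rng=None, dtype=np.float64):
        super().__init__()
        self.max_offset = max_offset

    def tables(self, length: int):
        return None, None, None


class LRPE(Module):
    """Plain learnable relative positional encoding: one directly-learnable
    additive vector per (role, signed offset, head); no sinusoid, no constraint."""

    def __init__(self, max_offset: int, heads: int, head_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.max_offset = max_offset
        T = 2 * max_offset + 1
        scale = 1.0 / np.sqrt(head_dim)
        self.table_q = Parameter((rng.standard_normal((heads, T, head_dim)) * scale).astype(dtype))
        self.table_k = Parameter((rng.standard_normal((heads, T, head_dim)) * scale).astype(dtype))
        self.table_v = Parameter((rng.standard_normal((heads, T, head_dim)) * scale).astype(dtype))

    def _encode_all(self):
        return self.table_q, self.table_k, self.table_v

    def tables(self, length: int):
        if length - 1 > self.max_offset:
            raise ValueError(f"bank length {length} exceeds supported offset {self.max_offset}")
        idx = _offset_index(length, self.max_offset)
        return tuple(ad.take(t, idx, axis=1) for t in self._encode_all())


def _offset_index(length: int, max_offset: int) -> np.ndarray:
    """(L, L) matrix of table indices for signed offsets j − i."""
    i = np.arange(length)
    return (i[None, :] - i[:, None]) + max_offset


class LSRPE(LRPE):
    """Learnable sinusoidal relative positional encoding.

    Each (role, offset, head, channel) has one learnable angle in [0, π/2],
    stored unconstrained and mapped through (π/2)·sigmoid(raw) so gradients
    never die at the boundary; the emitted encoding is sin(angle) ∈ [0, 1].
    Parameters for the Q, K and V roles are independent and randomly
    initialized.
    """

    def __init__(self, max_offset: int, heads: int, head_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        Module.__init__(self)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.max_offset = max_offset
        T = 2 * max_offset + 1
        # uniform raw in [-2, 2] => initial angles spread over most of [0, pi/2]
        self.table_q = Parameter(rng.uniform(-2, 2, (heads, T, head_dim)).astype(dtype))
        self.table_k = Parameter(rng.uniform(-2, 2, (heads, T, head_dim)).astype(dtype))
        self.table_v = Parameter(rng.uniform(-2, 2, (heads, T, head_dim)).astype(dtype))

    @classmethod
    def from_angles(cls, angles: dict[str, np.ndarray], dtype=np.float64) -> "LSRPE":
        """Build an encoding whose constrained angles equal ``angles`` (each
        (heads, 2·max_offset+1, head_dim), values in [0, π/2]; endpoints are
        approached to within sigmoid saturation)."""
        heads, T, head_dim = np.asarray(angles["Q"]).shape
        pe = cls((T - 1) // 2, heads, head_dim, dtype=dtype)
        for role, attr in zip(_ROLES, ("table_q", "table_k", "table_v")):
            a = np.clip(np.asarray(angles[role], dtype=float) / (np.pi / 2), 1e-18, 1 - 1e-16)
            getattr(pe, attr).data = np.log(a / (1.0 - a)).astype(dtype)
        return pe

    def angles(self, role: str) -> Tensor:
        raw = {"Q": self.table_q, "K": self.table_k, "V": self.table_v}[role]
        return ad.sigmoid(raw) * (np.pi / 2)

    def encode(self, role: str, offset: int) -> Tensor:
        """Encoding vectors (heads, head_dim) for one signed along-bank offset."""
        if abs(offset) > self.max_offset:
            raise ValueError(f"offset {offset} beyond max_offset {self.max_offset}")
        return self.angles(role).sin()[:, offset + self.max_offset, :]

    def _encode_all(self):
        return tuple(self.angles(r).sin() for r in _ROLES)


def make_positional_encoding(kind: str, max_offset: int, heads: int, head_dim: int,
                             rng=None, dtype=np.float64) -> Module:
    kinds = {"none": NoPE, "lrpe": LRPE, "lsrpe": LSRPE}
    if kind not in kinds:
        raise ValueError(f"unknown positional encoding {kind!r}; choose from {sorted(kinds)}")
    return kinds[kind](max_offset, heads, head_dim, rng=rng, dtype=dtype)


class AxialFreeAttention(Module):
    """Multi-head 1D attention along a line at angle θ ∈ [0, π).

    Composition: rotation grid → bilinear direction sampler → 1D attention
    over row/column banks → inverse rotation back to the input frame, so the
    output is spatially aligned with the input for any θ.  At θ = 0 and
    θ = π/2 the grids are identities and the layer reduces exactly to
    width-axis and height-axis attention.
    """

    def __init__(self, in_ch: int, out_ch: int, heads: int = 2, max_len: int = 64,
                 pe: str = "lsrpe", rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        if out_ch % heads:
            raise ValueError(f"out_ch={out_ch} not divisible by heads={heads}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.heads = heads
        self.head_dim = out_ch // heads
        self.out_ch = out_ch
        scale = 1.0 / np.sqrt(in_ch)
        self.wq = Parameter((rng.standard_normal((out_ch, in_ch)) * scale).astype(dtype))
        self.wk = Parameter((rng.standard_normal((out_ch, in_ch)) * scale).astype(dtype))
        self.wv = Parameter((rng.standard_normal((out_ch, in_ch)) * scale).astype(dtype))
        self.pe = make_positional_encoding(pe, max_len - 1, heads, self.head_dim,
                                           rng=rng, dtype=dtype)

    # ------------------------------------------------------------------
    def _project(self, z: Tensor, w: Parameter) -> Tensor:
        B, _, H, W = z.shape
        p = ad.einsum("oc,bchw->bohw", w, z)
        return p.reshape(B, self.heads, self.head_dim, H, W)

    def attend_1d(self, z: Tensor, theta: float) -> Tensor:
        """1D attention on banks of ``z`` selected by θ: rows (1×W banks) for
        θ < π/2, columns (H×1 banks) otherwise."""
        B, _, H, W = z.shape
        q = self._project(z, self.wq)
        k = self._project(z, self.wk)
        v = self._project(z, self.wv)
        row_banks = theta < np.pi / 2
        if row_banks:
            # (B, heads, hd, H, W) -> (B, n=H, heads, L=W, hd)
            perm, L = (0, 3, 1, 4, 2), W
        else:
            perm, L = (0, 4, 1, 3, 2), H
        q, k, v = (t.transpose(perm) for t in (q, k, v))
        logits = ad.einsum("bnhic,bnhjc->bnhij", q, k)
        rq, rk, rv = self.pe.tables(L)
        if rq is not None:
            logits = logits + ad.einsum("bnhic,hijc->bnhij", q, rq) \
                            + ad.einsum("bnhjc,hijc->bnhij", k, rk)
        attn = ad.softmax(logits, axis=-1)
        out = ad.einsum("bnhij,bnhjc->bnhic", attn, v)
        if rv is not None:
            out = out + ad.einsum("bnhij,hijc->bnhic", attn, rv)
        inv = tuple(np.argsort(perm))
        return out.transpose(inv).reshape(B, self.out_ch, H, W)

    def attention_weights(self, z: Tensor, theta: float) -> np.ndarray:
        """Softmax weights (B, n_banks, heads, L, L); diagnostic, no grad."""
        B, _, H, W = z.shape
        q = self._project(z, self.wq)
        k = self._project(z, self.wk)
        perm = (0, 3, 1, 4, 2) if theta < np.pi / 2 else (0, 4, 1, 3, 2)
        L = W if theta < np.pi / 2 else H
        q, k = (t.transpose(perm) for t in (q, k))
        logits = ad.einsum("bnhic,bnhjc->bnhij", q, k)
        rq, rk, _ = self.pe.tables(L)
        if rq is not None:
            logits = logits + ad.einsum("bnhic,hijc->bnhij", q, rq) \
                            + ad.einsum("bnhjc,hijc->bnhij", k, rk)
        return ad.softmax(logits, axis=-1).data

    def forward(self, x: Tensor, theta: float) -> Tensor:
        if not (0.0 <= theta < np.pi):
            raise ValueError(f"theta must lie in [0, pi), got {theta}")
        H, W = x.shape[-2:]
        rot = theta if theta < np.pi / 2 else theta - np.pi / 2
        if rot > 0.0:
            z = geometry.sample(x, geometry.make_rotation_grid(H, W, rot))
        else:
            z = x
        y = self.attend_1d(z, theta)
        if rot > 0.0:
            y = geometry.sample(y, geometry.make_rotation_grid(H, W, rot, inverse=True))
        return y
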