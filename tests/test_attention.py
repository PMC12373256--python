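"""1D attention, bank selection and positional encodings."""

import numpy as np
import pytest

import btformer.autodiff as ad
from btformer.attention import LSRPE, AxialFreeAttention, make_positional_encoding
from btformer.autodiff import Tensor
from btformer.geometry import make_rotation_grid, sample


def dense_axis_attention(z, wq, wk, wv, rq, rk, rv, axis):
    """Per-anchor softmax attention along rows (axis='row') or columns,
    evaluated with explicit python loops.  z: (C, H, W); r*: (L, L, Co) or None."""
    C, H, W = z.shape
    Co = wq.shape[0]
    out = np.zeros((Co, H, W))
    if axis == "col":
        res = dense_axis_attention(z.transpose(0, 2, 1), wq, wk, wv,
                                   rq, rk, rv, "row")
        return res.transpose(0, 2, 1)
    for h in range(H):
        bank = z[:, h, :]                     # (C, W)
        q, k, v = wq @ bank, wk @ bank, wv @ bank
        for a in range(W):
            logits = np.empty(W)
            for b in range(W):
                logit = q[:, a] @ k[:, b]
                if rq is not None:
                    logit += q[:, a] @ rq[a, b] + k[:, b] @ rk[a, b]
                logits[b] = logit
            p = np.exp(logits - logits.max())
            p /= p.sum()
            acc = np.zeros(Co)
            for b in range(W):
                vb = v[:, b] + (rv[a, b] if rv is not None else 0.0)
                acc += p[b] * vb
            out[:, h, a] = acc
    return out


def _single_head_layer(ci, co, L, pe="lsrpe", seed=0):
    return AxialFreeAttention(ci, co, heads=1, max_len=L, pe=pe,
                              rng=np.random.default_rng(seed))


class TestLSRPE:
    def test_angle_zero_encodes_to_zero(self):
        shape = (2, 9, 3)
        pe = LSRPE.from_angles({r: np.zeros(shape) for r in "QKV"})
        for role in "QKV":
            enc = pe.encode(role, 2).data
            np.testing.assert_allclose(enc, 0.0, atol=1e-8)

    def test_angle_half_pi_encodes_to_one(self):
        shape = (1, 5, 4)
        pe = LSRPE.from_angles({r: np.full(shape, np.pi / 2) for r in "QKV"})
        np.testing.assert_allclose(pe.encode("Q", -2).data, 1.0, atol=1e-8)

    def test_random_parameters_match_scalar_sine_oracle(self, rng):
        shape = (2, 7, 3)
        angles = {r: rng.uniform(0, np.pi / 2, shape) for r in "QKV"}
        pe = LSRPE.from_angles(angles)
        for role in "QKV":
            for off in (-3, 0, 3):
                got = pe.encode(role, off).data
                expect = np.empty(got.shape)
                for h in range(shape[0]):
                    for c in range(shape[2]):
                        expect[h, c] = np.sin(angles[role][h, off + 3, c])
                np.testing.assert_allclose(got, expect, atol=1e-7)

    def test_encodings_lie_in_unit_interval(self, rng):
        pe = LSRPE(5, 2, 4, rng=rng)
        for role in "QKV":
            for off in range(-5, 6):
                e = pe.encode(role, off).data
                assert (e >= 0).all() and (e <= 1).all()

    def test_offset_out_of_range_raises(self):
        pe = LSRPE(3, 1, 2)
        with pytest.raises(ValueError):
            pe.encode("Q", 4)

    def test_roles_are_independent(self, rng):
        pe = LSRPE(4, 1, 3, rng=rng)
        assert not np.allclose(pe.table_q.data, pe.table_k.data)
        assert not np.allclose(pe.table_k.data, pe.table_v.data)


class TestAttend1D:
    def test_zero_weights_give_zero_output(self):
        layer = _single_head_layer(1, 2, 6, pe="none")
        for w in (layer.wq, layer.wk, layer.wv):
            w.data[:] = 0.0
        z = Tensor(np.random.default_rng(0).standard_normal((1, 1, 5, 6)))
        out = layer.attend_1d(z, 0.0)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    @pytest.mark.parametrize("theta,axis", [(0.0, "row"), (np.pi / 2, "col")])
    def test_matches_dense_axis_oracle(self, theta, axis, rng):
        layer = _single_head_layer(1, 3, 6, pe="lsrpe", seed=3)
        z0 = rng.standard_normal((1, 5, 6))
        L = 6 if axis == "row" else 5
        rq, rk, rv = (t.data[0] for t in layer.pe.tables(L))  # head 0: (L, L, Co)
        expect = dense_axis_attention(z0, layer.wq.data, layer.wk.data,
                                      layer.wv.data, rq, rk, rv, axis)
        got = layer.attend_1d(Tensor(z0[None]), theta).data[0]
        np.testing.assert_allclose(got, expect, atol=1e-5)

    def test_forward_at_zero_equals_attend_1d(self, rng):
        layer = _single_head_layer(2, 2, 8, seed=1)
        x = Tensor(rng.standard_normal((1, 2, 8, 8)))
        np.testing.assert_allclose(layer(x, 0.0).data,
                                   layer.attend_1d(x, 0.0).data, atol=1e-12)

    def test_diagonal_direction_equals_rowwise_attention_in_rotated_frame(self, rng):
        """Composing grid → sampler → row attention → inverse grid by hand
        must reproduce the layer's forward at θ = π/4."""
        layer = _single_head_layer(1, 2, 12, pe="none", seed=2)
        x = rng.standard_normal((1, 1, 12, 12))
        theta = np.pi / 4
        g = make_rotation_grid(12, 12, theta)
        z = sample(x, g)
        y_rot = layer.attend_1d(Tensor(z), theta).data
        expect = sample(y_rot, make_rotation_grid(12, 12, theta, inverse=True))
        got = layer(Tensor(x), theta).data
        np.testing.assert_allclose(got, expect, atol=1e-10)

    def test_constant_bank_attention_is_uniform_average(self, rng):
        """On a bank with identical pixels the softmax is uniform and the
        output is that pixel's value map (content term only)."""
        layer = _single_head_layer(1, 2, 6, pe="none", seed=5)
        c = 0.7
        z = Tensor(np.full((1, 1, 4, 6), c))
        out = layer.attend_1d(z, 0.0)
        expect = (layer.wv.data @ np.array([[c]]))[:, 0]
        np.testing.assert_allclose(out.data[0, :, 0, 0], expect, atol=1e-10)
        w = layer.attention_weights(z, 0.0)
        np.testing.assert_allclose(w, 1.0 / 6, atol=1e-12)

    def test_bank_size_and_logit_complexity(self, rng):
        H, W = 6, 9
        layer = AxialFreeAttention(2, 4, heads=2, max_len=9, pe="lsrpe", rng=rng)
        z = Tensor(rng.standard_normal((1, 2, H, W)))
        for theta, L in ((0.3, W), (np.pi / 2 + 0.3, H)):
            w = layer.attention_weights(z, theta)
            n_banks = H if L == W else W
            assert w.shape == (1, n_banks, 2, L, L)
            # peak logit tensor: H·W·max(H,W) entries per head, never H²W²
            assert w[0, :, 0].size == n_banks * L * L <= H * W * max(H, W)

    def test_softmax_normalization_over_banks(self, rng):
        layer = AxialFreeAttention(2, 4, heads=2, max_len=8, rng=rng)
        z = Tensor(rng.standard_normal((2, 2, 8, 8)))
        for theta in (0.0, 0.4, np.pi / 2, 2.0):
            w = layer.attention_weights(z, theta)
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_permutation_blind_without_pe_broken_with_pe(self, rng):
        z0 = rng.standard_normal((1, 2, 1, 6))
        perm = np.array([3, 0, 5, 1, 4, 2])
        for kind, should_commute in (("none", True), ("lsrpe", False)):
            layer = AxialFreeAttention(2, 2, heads=1, max_len=6, pe=kind,
                                       rng=np.random.default_rng(11))
            out = layer.attend_1d(Tensor(z0), 0.0).data
            out_perm = layer.attend_1d(Tensor(z0[..., perm]), 0.0).data
            commutes = np.allclose(out[..., perm], out_perm, atol=1e-8)
            assert commutes == should_commute, f"pe={kind}"

    def test_outputs_and_gradients_finite(self, rng):
        layer = AxialFreeAttention(3, 4, heads=2, max_len=8, rng=rng)
        x = Tensor(rng.uniform(-1, 1, (1, 3, 8, 8)), requires_grad=True)
        out = layer(x, np.pi / 4)
        assert np.isfinite(out.data).all()
        (out * out).sum().backward()
        assert np.isfinite(x.grad).all()
        for p in layer.parameters():
            assert p.grad is None or np.isfinite(p.grad).all()

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            AxialFreeAttention(4, 6, heads=4, max_len=8)

    def test_unknown_pe_kind_raises(self):
        with pytest.raises(ValueError):
            make_positional_encoding("rope", 4, 1, 2)
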