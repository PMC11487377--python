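"""Selective group attention vs an independent nested-loop oracle.

The oracle re-implements the group module and selective attention with
plain Python loops (per element, no vectorization, no shared code with the
library), so agreement at 1e-6 validates the vectorized implementation.
"""

import numpy as np
import pytest

from sgknee.autodiff import Tensor
from sgknee.sg_attention import GroupModule, SelectiveAttention, group_reshape, ungroup


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def oracle_group_module(x, n, w1, b1, w3, b3):
    """Element-by-element evaluation of the cross-layer group attention."""
    B, L, C, H, W = x.shape
    pad = (-L) % n
    xp = np.concatenate([x] + [x[:, L - 1 : L]] * pad, axis=1) if pad else x
    G = (L + pad) // n
    Cn = C * n
    out = np.zeros((B, G, Cn, H, W))
    for b in range(B):
        for g in range(G):
            crop = xp[b, g * n : (g + 1) * n].reshape(Cn, H, W)
            ch = np.array([[crop[c, h, :].mean() for h in range(H)] for c in range(Cn)])
            cw = np.array([[crop[c, :, w].mean() for w in range(W)] for c in range(Cn)])
            cat = np.concatenate([ch, cw], axis=1)  # (Cn, H+W)
            a = np.zeros((Cn, H + W))
            for o in range(Cn):
                for pos in range(H + W):
                    a[o, pos] = sum(w1[o, i, 0, 0] * cat[i, pos] for i in range(Cn)) + b1[o]
            ah = _sig(a[:, :H])
            aw = _sig(a[:, H:])
            aprime = ah[:, :, None] * aw[:, None, :]
            gvec = np.zeros(Cn)
            for o in range(Cn):
                acc_map = np.zeros((H, W))
                for hh in range(H):
                    for ww in range(W):
                        acc = b3[o]
                        for i in range(Cn):
                            for dh in (-1, 0, 1):
                                for dw in (-1, 0, 1):
                                    h2, w2 = hh + dh, ww + dw
                                    if 0 <= h2 < H and 0 <= w2 < W:
                                        acc += w3[o, i, dh + 1, dw + 1] * crop[i, h2, w2]
                        acc_map[hh, ww] = acc
                gvec[o] = acc_map.mean()
            mask = _sig(aprime * gvec[:, None, None])
            out[b, g] = crop * mask
    return out.reshape(B, G * n, C, H, W)[:, :L]


def oracle_selective(x, module):
    """Loop evaluation of branch fusion, bottleneck gating and selection."""
    B, L, C, H, W = x.shape
    Fs = [
        oracle_group_module(
            x, br.n, br.conv1x1.w.data, br.conv1x1.b.data, br.conv3x3.w.data, br.conv3x3.b.data
        )
        for br in module.branches
    ]
    if len(Fs) == 1:
        return Fs[0]
    Fsum = sum(Fs)
    out = np.zeros_like(x)
    K = len(Fs)
    for b in range(B):
        desc = np.array([Fsum[b, :, c].mean() for c in range(C)])
        hidden = np.maximum(desc @ module.fc_reduce.w.data + module.fc_reduce.b.data, 0.0)
        logits = np.stack([hidden @ fc.w.data + fc.b.data for fc in module.fc_branches])
        e = np.exp(logits - logits.max(axis=0, keepdims=True))
        z = e / e.sum(axis=0, keepdims=True)  # (K, C)
        for k in range(K):
            out[b] += z[k][None, :, None, None] * Fs[k][b]
    return out


class TestGroupReshape:
    def test_bijection_when_divisible(self, rng):
        x = Tensor(rng.standard_normal((2, 4, 2, 3, 3)))
        cg = group_reshape(x, 2)
        assert cg.shape == (2, 2, 4, 3, 3)
        np.testing.assert_array_equal(ungroup(cg, 2, 4, 2).data, x.data)

    def test_n1_identity(self, rng):
        x = Tensor(rng.standard_normal((1, 3, 2, 2, 2)))
        np.testing.assert_array_equal(group_reshape(x, 1).data, x.data)

    def test_padding_replicates_last_layer(self, rng):
        x = Tensor(rng.standard_normal((1, 5, 2, 3, 3)))
        cg = group_reshape(x, 2)
        assert cg.shape == (1, 3, 4, 3, 3)
        full = cg.data.reshape(1, 6, 2, 3, 3)
        np.testing.assert_array_equal(full[0, 5], x.data[0, 4])
        np.testing.assert_array_equal(ungroup(cg, 2, 5, 2).data, x.data)


class TestGroupModule:
    def test_zero_weights_halve_input(self, rng):
        gm = GroupModule(channels=3, n=2, zero_init=True)
        x = rng.standard_normal((2, 4, 3, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(gm(x).data, x / 2, atol=1e-7)

    def test_directional_map_is_rank_one(self, rng):
        gm = GroupModule(channels=2, n=2, rng=rng)
        crop = Tensor(rng.standard_normal((3, 4, 5, 6)).astype(np.float32))
        att = gm.directional_attention(crop)
        A = att.A_prime.data
        assert np.all((A > 0) & (A < 1))
        for bg in range(3):
            for c in range(4):
                assert np.linalg.matrix_rank(A[bg, c], tol=1e-6) == 1

    def test_zero_conv_attention_is_quarter(self):
        gm = GroupModule(channels=2, n=1, zero_init=True)
        crop = Tensor(np.random.default_rng(0).standard_normal((1, 2, 3, 3)))
        att = gm.directional_attention(crop)
        np.testing.assert_allclose(att.A_H.data, 0.5)
        np.testing.assert_allclose(att.A_W.data, 0.5)
        np.testing.assert_allclose(att.A_prime.data, 0.25)

    @pytest.mark.parametrize("shape,n", [((1, 2, 2, 2, 2), 2), ((2, 3, 2, 2, 2), 2), ((1, 4, 3, 2, 3), 1)])
    def test_matches_nested_loop_oracle(self, rng, shape, n):
        gm = GroupModule(channels=shape[2], n=n, rng=rng)
        x = rng.standard_normal(shape).astype(np.float64)
        expected = oracle_group_module(
            x, n, gm.conv1x1.w.data, gm.conv1x1.b.data, gm.conv3x3.w.data, gm.conv3x3.b.data
        )
        np.testing.assert_allclose(gm(x).data, expected, atol=1e-6)

    def test_shape_preserved(self, rng):
        gm = GroupModule(channels=3, n=2, rng=rng)
        x = rng.standard_normal((2, 4, 3, 8, 8)).astype(np.float32)
        assert gm(x).shape == x.shape


class TestSelectiveAttention:
    def test_single_branch_passthrough(self, rng):
        sa = SelectiveAttention(4, (2,), rng=rng)
        x = rng.standard_normal((2, 4, 4, 3, 3)).astype(np.float32)
        np.testing.assert_array_equal(sa(x).data, sa.branches[0](x).data)

    def test_branch_weights_sum_to_one(self, rng):
        sa = SelectiveAttention(8, (1, 2, 4), rng=rng)
        x = rng.standard_normal((3, 4, 8, 4, 4)).astype(np.float32)
        outs = [b(Tensor(x)) for b in sa.branches]
        z = sa.branch_weights(outs).data
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(z >= 0)

    def test_tied_identical_branches_split_evenly(self, rng):
        sa = SelectiveAttention(4, (2, 2), rng=rng)
        # tie the two branches' parameters
        for src, dst in zip(sa.branches[0].parameters(), sa.branches[1].parameters()):
            dst.data = src.data.copy()
        sa.fc_branches[1].w.data = sa.fc_branches[0].w.data.copy()
        sa.fc_branches[1].b.data = sa.fc_branches[0].b.data.copy()
        x = rng.standard_normal((2, 4, 4, 3, 3)).astype(np.float32)
        outs = [b(Tensor(x)) for b in sa.branches]
        z = sa.branch_weights(outs).data
        np.testing.assert_allclose(z[:, 0, :], 0.5, atol=1e-6)
        np.testing.assert_allclose(z[:, 1, :], 0.5, atol=1e-6)

    def test_matches_nested_loop_oracle(self, rng):
        sa = SelectiveAttention(2, (1, 2), reduction=1, rng=rng)
        x = rng.standard_normal((1, 2, 2, 2, 2)).astype(np.float64)
        np.testing.assert_allclose(sa(x).data, oracle_selective(x, sa), atol=1e-6)

    @pytest.mark.parametrize("shape", [(1, 3, 8, 4, 4), (2, 7, 8, 3, 5)])
    def test_shape_preserved_variable_L(self, rng, shape):
        sa = SelectiveAttention(8, (1, 2, 4), rng=rng)
        x = rng.standard_normal(shape).astype(np.float32)
        assert sa(x).shape == shape

    def test_all_parameters_receive_gradient(self, rng):
        sa = SelectiveAttention(4, (1, 2), rng=rng)
        x = rng.standard_normal((2, 4, 4, 3, 3)).astype(np.float32)
        out = sa(x)
        (out * out).sum().backward()
        for p in sa.parameters():
            assert p.grad is not None
            assert np.any(p.grad != 0)

    def test_empty_group_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            SelectiveAttention(4, (), rng=rng)
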