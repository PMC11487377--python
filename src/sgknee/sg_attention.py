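"""Selective group cross-layer attention.

The backbone emits a 5-D feature map X of shape B x L x C x H x W (batch,
layers, channels, height, width).  The *group module* folds consecutive
blocks of n layers into the channel axis (L//n group-layers of C*n
channels), forcing the attention to model cross-layer structure, then
computes coordinate-style directional attention: the group is average-
pooled along W and along H, the two 1-D profiles are concatenated and
passed through a shared 1x1 convolution, split back, sigmoid-activated,
and combined by outer product into a rank-1 (per channel) spatial map A'.
A parallel global branch (3x3 convolution followed by global 2-D average
pooling) yields one scalar g per group-layer/channel; the final mask is
M = sigmoid(A' * g) and the group is modulated multiplicatively before
being unfolded back to the input shape.

The *selective attention* module runs K group modules with different
group sizes n_k, sums their outputs, squeezes the sum to a length-C
descriptor (average over layers and space), and derives per-channel
branch weights z through a bottleneck FC and a softmax across branches —
the selective-kernel recipe.  The output is sum_k z_k * F_k, a soft
selection of the best cross-layer grouping per channel.

Layer counts not divisible by n are padded by repeating the final layer;
padded slots are dropped when unfolding, so the shape contract holds for
variable-L exams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sgknee.autodiff import Tensor, concat, softmax
from sgknee.nn import Conv2d, Linear, Module

__all__ = [
    "DirectionalAttention",
    "group_reshape",
    "ungroup",
    "GroupModule",
    "SelectiveAttention",
]


@dataclass
class DirectionalAttention:
    """Sigmoid-activated directional profiles and their outer product.

    A_H has shape (BG, Cn, H, 1), A_W (BG, Cn, 1, W); A_prime = A_H * A_W
    broadcast to (BG, Cn, H, W) and is rank-1 per (group-layer, channel).
    """

    A_H: Tensor
    A_W: Tensor
    A_prime: Tensor


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def group_reshape(x: Tensor | np.ndarray, n: int) -> Tensor:
    """Fold layers into channels: (B, L, C, H, W) -> (B, ceil(L/n), C*n, H, W).

    Consecutive blocks of n layers share a group-layer; if L is not
    divisible by n the stack is padded by edge-replicating the last layer.
    """
    x = _lift(x)
    if n < 1:
        raise ValueError("group size n must be >= 1")
    B, L, C, H, W = x.shape
    pad = (-L) % n
    if pad:
        last = x[:, L - 1 : L]
        x = concat([x] + [last] * pad, axis=1)
    G = (L + pad) // n
    return x.reshape(B, G, n * C, H, W)


def ungroup(cg: Tensor, n: int, L: int, C: int) -> Tensor:
    """Inverse of :func:`group_reshape`, dropping any padded layers."""
    B, G, Cn, H, W = cg.shape
    if Cn != n * C:
        raise ValueError(f"channel count {Cn} inconsistent with n={n}, C={C}")
    full = cg.reshape(B, G * n, C, H, W)
    if G * n == L:
        return full
    return full[:, :L]


class GroupModule(Module):
    """Cross-layer group attention for one group size n.

    Parameters: a 1x1 conv over the C*n grouped channels (shared across
    group-layers and across the H/W profile positions) for the directional
    branch, and a 3x3 conv for the global branch.
    """

    def __init__(self, channels: int, n: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        self.n = n
        self.channels = channels
        cn = channels * n
        self.conv1x1 = Conv2d(cn, cn, 1, rng=rng, zero_init=zero_init)
        self.conv3x3 = Conv2d(cn, cn, 3, padding=1, rng=rng, zero_init=zero_init)

    def directional_attention(self, crop: Tensor) -> DirectionalAttention:
        """Coordinate attention profiles for a flattened crop group.

        `crop` has shape (BG, Cn, H, W).  Average-pool along W and along H,
        concatenate the two profiles on the length axis, mix channels with
        the shared 1x1 conv, split back, sigmoid, outer product.
        """
        BG, Cn, H, W = crop.shape
        c_h = crop.mean(axis=3, keepdims=True)  # (BG, Cn, H, 1)
        c_w = crop.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (BG, Cn, W, 1)
        a = self.conv1x1(concat([c_h, c_w], axis=2))  # (BG, Cn, H+W, 1)
        a_h = a[:, :, :H, :].sigmoid()  # (BG, Cn, H, 1)
        a_w = a[:, :, H:, :].transpose(0, 1, 3, 2).sigmoid()  # (BG, Cn, 1, W)
        return DirectionalAttention(A_H=a_h, A_W=a_w, A_prime=a_h * a_w)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = _lift(x)
        B, L, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {C}")
        cg = group_reshape(x, self.n)
        _, G, Cn, _, _ = cg.shape
        flat = cg.reshape(B * G, Cn, H, W)
        att = self.directional_attention(flat)
        g = self.conv3x3(flat).mean(axis=(2, 3), keepdims=True)  # (BG, Cn, 1, 1)
        mask = (att.A_prime * g).sigmoid()
        out = (flat * mask).reshape(B, G, Cn, H, W)
        return ungroup(out, self.n, L, C)


class SelectiveAttention(Module):
    """Softmax-gated combination of group modules with different n_k.

    The branch descriptor pools the summed branch outputs over layers and
    space (one value per channel), so branches with different effective
    L//n remain comparable.  The bottleneck FC has width
    max(channels // reduction, min_width).
    """

    def __init__(
        self,
        channels: int,
        group_sizes: tuple[int, ...] = (1, 2, 4),
        reduction: int = 4,
        min_width: int = 8,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        if len(group_sizes) < 1:
            raise ValueError("group_sizes must be non-empty")
        self.group_sizes = tuple(group_sizes)
        self.channels = channels
        self.branches = [
            GroupModule(channels, n, rng=rng, zero_init=zero_init) for n in self.group_sizes
        ]
        hidden = max(channels // reduction, min_width)
        self.fc_reduce = Linear(channels, hidden, rng=rng, zero_init=zero_init)
        self.fc_branches = [
            Linear(hidden, channels, rng=rng, zero_init=zero_init) for _ in self.group_sizes
        ]

    def branch_weights(self, branch_outputs: list[Tensor]) -> Tensor:
        """z of shape (B, K, C): softmax across branches per channel."""
        fused = branch_outputs[0]
        for f in branch_outputs[1:]:
            fused = fused + f
        desc = fused.mean(axis=(1, 3, 4))  # (B, C)
        hidden = self.fc_reduce(desc).relu()
        B = desc.shape[0]
        logits = concat(
            [fc(hidden).reshape(B, 1, self.channels) for fc in self.fc_branches], axis=1
        )  # (B, K, C)
        return softmax(logits, axis=1)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = _lift(x)
        B, L, C, H, W = x.shape
        outs = [branch(x) for branch in self.branches]
        if len(outs) == 1:
            return outs[0]
        z = self.branch_weights(outs)  # (B, K, C)
        result = None
        for k, f in enumerate(outs):
            zk = z[:, k, :].reshape(B, 1, C, 1, 1)
            term = f * zk
            result = term if result is None else result + term
        return result
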