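"""Per-view classifier: slice backbone, aggregation head and training loss.

Every slice of a stacked-slice volume passes through a shared 2-D conv
backbone; the per-slice features are stacked into the 5-D map consumed by
the attention module, spatially average-pooled per slice, aggregated by an
element-wise max over slices (a variable-depth-friendly reduction: the
most tear-suspicious slice drives the prediction), and mapped by one fully
connected layer to two-class softmax confidences.

The loss is the sum of a class-balanced weighted cross-entropy and a focal
term:

    L = L_wl + L_fl,   L_wl = -a_t log(p_t),   L_fl = -a_t (1-p_t)^g log(p_t)

with p_t the probability assigned to the true class and a_t = a for tears,
1 - a for intact exams.  By default a = 1 - prevalence(train), so the rarer
class is up-weighted, and g = 2, the canonical focusing exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sgknee.autodiff import Tensor, softmax
from sgknee.nn import Conv2d, Linear, Module
from sgknee.sg_attention import SelectiveAttention

__all__ = [
    "BackboneConfig",
    "LossParams",
    "SmallCNN",
    "MRNetAlexNetLike",
    "ClassifierHead",
    "SGNetModel",
    "build_model",
    "weighted_loss",
    "focal_loss",
    "total_loss",
]

LOG_EPS = 1e-12


@dataclass
class BackboneConfig:
    arch: str = "small_cnn"
    out_channels: int = 32
    pretrained: bool = False

    def __post_init__(self) -> None:
        if self.arch not in ("small_cnn", "mrnet_alexnet_like"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.out_channels < 8:
            raise ValueError("out_channels must be >= 8")
        if self.pretrained:
            raise ValueError("pretrained weights are not available in this artifact")


@dataclass
class LossParams:
    """alpha: class-balance weight in (0,1); gamma: focusing exponent >= 0."""

    alpha: float = 0.5
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


class SmallCNN(Module):
    """Four stride-2 conv/relu blocks: (N,1,S,S) -> (N,C,S/16,S/16).

    The desk-scale default backbone: on 56-64 px inputs it leaves a 4x4
    spatial map, deep enough for the attention module to matter and small
    enough to train on one CPU.
    """

    min_input = 16

    def __init__(self, out_channels: int = 32, rng: np.random.Generator | None = None):
        widths = [max(out_channels // 4, 8), max(out_channels // 2, 8), out_channels, out_channels]
        self.convs = []
        in_ch = 1
        for w in widths:
            self.convs.append(Conv2d(in_ch, w, 3, stride=2, padding=1, rng=rng))
            in_ch = w
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).relu()
        return x


def _pool2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pool (trailing odd row/col dropped)."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        x = x[:, :, : H - H % 2, : W - W % 2]
        N, C, H, W = x.shape
    return x.reshape(N, C, H // 2, 2, W // 2, 2).max(axis=5).max(axis=3)


class MRNetAlexNetLike(Module):
    """AlexNet-features topology at random init (no pretraining).

    Recreates the slice encoder of the MRNet family: 11x11/4 stem, 5x5 and
    three 3x3 stages with 2x2 max pooling between stages, final channel
    width `out_channels`.  Intended for 224-256 px inputs.
    """

    min_input = 63

    def __init__(self, out_channels: int = 256, rng: np.random.Generator | None = None):
        self.c1 = Conv2d(1, 64, 11, stride=4, padding=2, rng=rng)
        self.c2 = Conv2d(64, 192, 5, padding=2, rng=rng)
        self.c3 = Conv2d(192, 384, 3, padding=1, rng=rng)
        self.c4 = Conv2d(384, 256, 3, padding=1, rng=rng)
        self.c5 = Conv2d(256, out_channels, 3, padding=1, rng=rng)
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        x = _pool2x2(self.c1(x).relu())
        x = _pool2x2(self.c2(x).relu())
        x = self.c3(x).relu()
        x = self.c4(x).relu()
        x = _pool2x2(self.c5(x).relu())
        return x


class ClassifierHead(Module):
    """Spatial average pool -> max over layers -> FC -> 2-class softmax."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        self.fc = Linear(channels, 2, rng=rng, zero_init=zero_init)

    def forward(self, f: Tensor) -> Tensor:
        pooled = f.mean(axis=(3, 4))  # (B, L, C)
        agg = pooled.max(axis=1)  # (B, C)
        return softmax(self.fc(agg), axis=1)


class SGNetModel(Module):
    """Backbone + optional selective group attention + head, one view."""

    def __init__(
        self,
        backbone: Module,
        head: ClassifierHead,
        attention: SelectiveAttention | None = None,
    ):
        self.backbone = backbone
        self.attention = attention
        self.head = head

    def features(self, volumes: np.ndarray) -> Tensor:
        """(B, L, H, W) slice stacks -> (B, L, C, H', W') feature maps."""
        vol = np.asarray(volumes, dtype=np.float32)
        if vol.ndim != 4:
            raise ValueError("expected a (B, L, H, W) batch of volumes")
        B, L, H, W = vol.shape
        if min(H, W) < self.backbone.min_input:
            raise ValueError(
                f"spatial size {min(H, W)} below backbone minimum {self.backbone.min_input}"
            )
        x = Tensor(vol.reshape(B * L, 1, H, W))
        f = self.backbone(x)
        _, C, Hp, Wp = f.shape
        return f.reshape(B, L, C, Hp, Wp)

    def forward(self, volumes: np.ndarray) -> Tensor:
        """Per-exam two-class confidence scores, rows summing to 1."""
        f = self.features(volumes)
        if self.attention is not None:
            f = self.attention(f)
        return self.head(f)


def build_model(
    cfg: BackboneConfig,
    use_sg: bool = True,
    group_sizes: tuple[int, ...] = (1, 2, 4),
    reduction: int = 4,
    rng: np.random.Generator | None = None,
) -> SGNetModel:
    if cfg.arch == "small_cnn":
        backbone = SmallCNN(cfg.out_channels, rng=rng)
    else:
        backbone = MRNetAlexNetLike(cfg.out_channels, rng=rng)
    attention = (
        SelectiveAttention(backbone.out_channels, group_sizes, reduction, rng=rng)
        if use_sg
        else None
    )
    head = ClassifierHead(backbone.out_channels, rng=rng)
    return SGNetModel(backbone, head, attention)


def _pt_at(scores, y) -> Tensor:
    """p_t: probability assigned to the true class, clamped away from 0."""
    s = scores if isinstance(scores, Tensor) else Tensor(np.asarray(scores, dtype=float))
    if s.ndim == 1:
        s = s.reshape(1, s.shape[0])
    yv = np.atleast_1d(np.asarray(y, dtype=float))
    p_pos = s[:, 1]
    p_t = p_pos * yv + (1.0 - p_pos) * (1.0 - yv)
    return p_t.clip_min(LOG_EPS)


def _alpha_t(y, alpha: float) -> np.ndarray:
    yv = np.atleast_1d(np.asarray(y, dtype=float))
    return alpha * yv + (1.0 - alpha) * (1.0 - yv)


def weighted_loss(scores, y, lp: LossParams) -> Tensor:
    """Class-balanced cross-entropy  -a_t log(p_t), averaged over the batch."""
    p_t = _pt_at(scores, y)
    a_t = _alpha_t(y, lp.alpha)
    return -(Tensor(a_t) * p_t.log()).mean()

def focal_loss(scores, y, lp: LossParams) -> Tensor:
    """Focal term  -a_t (1-p_t)^gamma log(p_t), averaged over the batch."""
    p_t = _pt_at(scores, y)
    a_t = _alpha_t(y, lp.alpha)
    if lp.gamma == 0:
        mod = Tensor(np.ones_like(a_t))
    else:
        mod = (1.0 - p_t) ** lp.gamma
    return -(Tensor(a_t) * mod * p_t.log()).mean()


def total_loss(scores, y, lp: LossParams) -> Tensor:
    """Training objective: weighted + focal."""
    return weighted_loss(scores, y, lp) + focal_loss(scores, y, lp)
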