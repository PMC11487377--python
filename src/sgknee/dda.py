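"""Dual-scale data augmentation.

Pipeline per view: random crop -> normalization -> erasing or mixup, where
the erase/mixup step can act on the *spatial* scale (a square block inside
each slice) or on the *layer* scale (whole slices).  Block side length is
``input side x ratio`` by default (so the zeroed area fraction is ratio^2);
an ``area`` convention (area fraction = ratio) is available via
``AugmentConfig.block_mode``.  Spatial mixup borrows its donor block from
another layer of the same view; layer mixup borrows whole slices from a
randomly chosen *other* view, resized by nearest neighbour if needed.
Mixing weights are drawn from Beta(alpha, alpha).  Labels are never
touched: both erasing and mixup are class-preserving by construction.

Every stage draws from its own named substream of the run seed, so
enabling or disabling one stage never shifts another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sgknee.rng import substream
from sgknee.volume_io import ExamVolume

__all__ = [
    "AugmentConfig",
    "NormStats",
    "compute_norm_stats",
    "random_crop",
    "center_crop",
    "normalize",
    "spatial_erase",
    "spatial_mixup",
    "layer_scale_apply",
    "augment_pipeline",
    "basic_augment",
]


@dataclass
class AugmentConfig:
    """Knobs of the augmentation pipeline.

    ``erase_ratio`` 0.5 and ``mixup_ratio`` 0.25 are the settings that won
    the augmentation ablation; ``beta_alpha`` 0.4 is the conventional mixup
    concentration.  ``mode_probabilities`` gives the per-exam probability
    of applying erasing vs mixup (remaining mass = no op); the spatial and
    layer scales are mutually exclusive per draw, chosen uniformly.
    """

    crop_size: int = 224
    erase_ratio: float = 0.5
    mixup_ratio: float = 0.25
    layer_ratio: float = 0.25
    beta_alpha: float = 0.4
    mode_probabilities: dict = field(default_factory=lambda: {"erase": 0.5, "mixup": 0.5})
    block_mode: str = "side"  # "side": block side = H*ratio; "area": block area = H*W*ratio
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("erase_ratio", "mixup_ratio", "layer_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta_alpha <= 0:
            raise ValueError("beta_alpha must be positive")
        if self.block_mode not in ("side", "area"):
            raise ValueError("block_mode must be 'side' or 'area'")
        total = sum(self.mode_probabilities.values())
        if total > 1.0 + 1e-9 or any(p < 0 for p in self.mode_probabilities.values()):
            raise ValueError("mode_probabilities must be nonnegative and sum to <= 1")


@dataclass
class NormStats:
    """Global intensity mean / sd of the training split (one pair per dataset)."""

    m: float
    std: float

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValueError("std must be positive")


def compute_norm_stats(volumes) -> NormStats:
    """Pooled mean/sd over all voxels of the given training volumes."""
    n = 0
    s = 0.0
    ss = 0.0
    for vol in volumes:
        arr = vol.data if isinstance(vol, ExamVolume) else np.asarray(vol)
        n += arr.size
        s += float(arr.sum(dtype=np.float64))
        ss += float(np.square(arr, dtype=np.float64).sum())
    if n == 0:
        raise ValueError("no volumes supplied")
    m = s / n
    var = max(ss / n - m * m, 0.0)
    if var == 0.0:
        raise ValueError("zero-variance data: normalization undefined")
    return NormStats(m=m, std=float(np.sqrt(var)))


def _new(vol: ExamVolume, data: np.ndarray) -> ExamVolume:
    return ExamVolume(data, view=vol.view, exam_id=vol.exam_id)


def random_crop(vol: ExamVolume, size: int, rng: np.random.Generator) -> ExamVolume:
    """Crop every layer with one shared spatial window of side `size`."""
    L, H, W = vol.shape
    if size > min(H, W):
        raise ValueError(f"crop size {size} exceeds input side {min(H, W)}")
    top = int(rng.integers(0, H - size + 1))
    left = int(rng.integers(0, W - size + 1))
    return _new(vol, vol.data[:, top : top + size, left : left + size].copy())


def center_crop(vol: ExamVolume, size: int) -> ExamVolume:
    """Deterministic central window, used at evaluation time."""
    L, H, W = vol.shape
    if size > min(H, W):
        raise ValueError(f"crop size {size} exceeds input side {min(H, W)}")
    top = (H - size) // 2
    left = (W - size) // 2
    return _new(vol, vol.data[:, top : top + size, left : left + size].copy())


def normalize(vol: ExamVolume, stats: NormStats) -> ExamVolume:
    """Map every voxel p to (p - m) / std."""
    return _new(vol, (vol.data - stats.m) / stats.std)


def _block_side(side: int, ratio: float, mode: str) -> int:
    if mode == "area":
        ratio = float(np.sqrt(ratio))
    return int(round(side * ratio))


def _block_window(H: int, W: int, s: int, rng: np.random.Generator) -> tuple[slice, slice]:
    """A fully-inside s x s window with uniformly drawn position."""
    top = int(rng.integers(0, H - s + 1))
    left = int(rng.integers(0, W - s + 1))
    return slice(top, top + s), slice(left, left + s)


def spatial_erase(
    vol: ExamVolume, ratio: float, rng: np.random.Generator, block_mode: str = "side"
) -> ExamVolume:
    """Zero one square block per layer, side = layer side x ratio."""
    L, H, W = vol.shape
    s = _block_side(min(H, W), ratio, block_mode)
    out = vol.data.copy()
    if s == 0:
        return _new(vol, out)
    for layer in range(L):
        rs, cs = _block_window(H, W, s, rng)
        out[layer, rs, cs] = 0.0
    return _new(vol, out)


def spatial_mixup(
    vol: ExamVolume,
    ratio: float,
    rng: np.random.Generator,
    beta_alpha: float = 0.4,
    block_mode: str = "side",
    lam: float | None = None,
) -> ExamVolume:
    """Blend one block per layer with a donor block from another layer.

    Donor layer and donor window are drawn independently; the block becomes
    lam*self + (1-lam)*donor with lam ~ Beta(alpha, alpha) per layer
    (overridable via `lam` for testing degenerate mixes).
    """
    L, H, W = vol.shape
    if L < 2:
        raise ValueError("spatial mixup needs at least 2 layers for a donor")
    s = _block_side(min(H, W), ratio, block_mode)
    out = vol.data.copy()
    if s == 0:
        return _new(vol, out)
    for layer in range(L):
        rs, cs = _block_window(H, W, s, rng)
        donor_layer = int(rng.integers(0, L - 1))
        if donor_layer >= layer:
            donor_layer += 1
        drs, dcs = _block_window(H, W, s, rng)
        lam_i = float(rng.beta(beta_alpha, beta_alpha)) if lam is None else lam
        donor = vol.data[donor_layer, drs, dcs]
        out[layer, rs, cs] = lam_i * vol.data[layer, rs, cs] + (1.0 - lam_i) * donor
    return _new(vol, out)


def _resize_nearest(img: np.ndarray, H: int, W: int) -> np.ndarray:
    h, w = img.shape
    ri = (np.arange(H) * h / H).astype(int)
    ci = (np.arange(W) * w / W).astype(int)
    return img[np.ix_(ri, ci)]


def layer_scale_apply(
    vol: ExamVolume,
    op: str,
    layer_ratio: float,
    rng: np.random.Generator,
    donor_views: dict[str, ExamVolume] | None = None,
    beta_alpha: float = 0.4,
    lam: float | None = None,
) -> ExamVolume:
    """Erase or mix whole slices: k = round(L x ratio) distinct layers.

    Erase zeroes the chosen layers outright.  Mixup blends each chosen
    layer with a uniformly drawn layer of a uniformly drawn *other* view
    (nearest-neighbour resized to match), weight lam ~ Beta(alpha, alpha).
    """
    if op not in ("erase", "mixup"):
        raise ValueError(f"op must be 'erase' or 'mixup', got {op!r}")
    L, H, W = vol.shape
    k = int(round(L * layer_ratio))
    out = vol.data.copy()
    if k == 0:
        return _new(vol, out)
    chosen = rng.choice(L, size=k, replace=False)
    if op == "erase":
        out[chosen] = 0.0
        return _new(vol, out)
    donors = {v: d for v, d in (donor_views or {}).items() if v != vol.view}
    if not donors:
        raise ValueError("layer mixup requires at least one donor view")
    donor_names = sorted(donors)
    for layer in chosen:
        dview = donors[donor_names[int(rng.integers(0, len(donor_names)))]]
        dlayer = dview.data[int(rng.integers(0, dview.layers))]
        if dlayer.shape != (H, W):
            dlayer = _resize_nearest(dlayer, H, W)
        lam_i = float(rng.beta(beta_alpha, beta_alpha)) if lam is None else lam
        out[layer] = lam_i * vol.data[layer] + (1.0 - lam_i) * dlayer
    return _new(vol, out)


def augment_pipeline(
    views: dict[str, ExamVolume],
    cfg: AugmentConfig,
    stats: NormStats,
    seed: int | None = None,
    tag: str = "",
) -> dict[str, ExamVolume]:
    """Full per-exam augmentation: crop -> normalize -> erase/mixup.

    Per view, one op (erase / mixup / none, per ``mode_probabilities``) at
    one scale (spatial or layer, equiprobable) is applied.  Layer-mixup
    donors are the *other* views after their own crop + normalization.
    `tag` individualizes the substreams per exam/epoch.
    """
    if seed is None:
        seed = cfg.seed
    prepared: dict[str, ExamVolume] = {}
    for view, vol in views.items():
        rng_crop = substream(seed, f"aug/{tag}/{view}/crop")
        prepared[view] = normalize(random_crop(vol, cfg.crop_size, rng_crop), stats)

    out: dict[str, ExamVolume] = {}
    p_erase = cfg.mode_probabilities.get("erase", 0.0)
    p_mixup = cfg.mode_probabilities.get("mixup", 0.0)
    for view, vol in prepared.items():
        rng_mode = substream(seed, f"aug/{tag}/{view}/mode")
        u = rng_mode.random()
        if u < p_erase:
            op = "erase"
        elif u < p_erase + p_mixup:
            op = "mixup"
        else:
            out[view] = vol
            continue
        scale = "spatial" if rng_mode.random() < 0.5 else "layer"
        rng_op = substream(seed, f"aug/{tag}/{view}/{op}/{scale}")
        if scale == "spatial":
            ratio = cfg.erase_ratio if op == "erase" else cfg.mixup_ratio
            if op == "erase":
                out[view] = spatial_erase(vol, ratio, rng_op, cfg.block_mode)
            else:
                out[view] = spatial_mixup(vol, ratio, rng_op, cfg.beta_alpha, cfg.block_mode)
        else:
            donors = {v: p for v, p in prepared.items() if v != view}
            if op == "mixup" and not donors:
                out[view] = vol  # single-view mode: no donor, skip quietly
                continue
            out[view] = layer_scale_apply(
                vol, op, cfg.layer_ratio, rng_op, donor_views=donors, beta_alpha=cfg.beta_alpha
            )
    return out


def basic_augment(
    views: dict[str, ExamVolume],
    cfg: AugmentConfig,
    stats: NormStats,
    seed: int | None = None,
    tag: str = "",
) -> dict[str, ExamVolume]:
    """Minimal conventional baseline: random crop + flip/shift + normalize.

    Comparison pipeline for the basic rotation/shift/flip augmentation
    family; intentionally small, not a general 2-D augmentation library.
    """
    if seed is None:
        seed = cfg.seed
    out = {}
    for view, vol in views.items():
        rng = substream(seed, f"basic/{tag}/{view}")
        v = random_crop(vol, cfg.crop_size, rng)
        data = v.data
        if rng.random() < 0.5:
            data = data[:, :, ::-1].copy()
        shift = int(rng.integers(-3, 4))
        if shift:
            data = np.roll(data, shift, axis=2)
        out[view] = normalize(_new(vol, data), stats)
    return out
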