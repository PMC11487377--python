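"""Synthetic three-view knee phantom.

Each exam is rendered from one latent 3-D scene: an ellipsoidal soft-tissue
background plus a bright diagonal band (the "ligament") crossing the
mid-slices.  A positive (torn) exam interrupts the band with a gap at the
band's background level — the signal simply vanishes over ``gap_length``
voxels — and adds a hyperintense blob beside the gap, a geometric stand-in
for the fiber discontinuity and local signal abnormality a radiologist
looks for.  The three views (axial/coronal/sagittal) are slice stacks of
the same scene along its three axes, each with its own slice count L and
independent additive Gaussian noise, so multi-view fusion sees genuinely
correlated-but-distinct inputs.

No anatomical realism or MR physics is claimed; the phantom exists so the
augmentation, attention, training and fusion stages are exercisable and
their class signal is analytically traceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sgknee.rng import substream
from sgknee.volume_io import (
    VIEWS,
    DatasetManifest,
    ExamRecord,
    ExamVolume,
    write_manifest,
    write_volume,
)

__all__ = ["PhantomParams", "PhantomScene", "sample_scene", "generate_exam", "generate_dataset"]

BACKGROUND_LEVEL = 0.3
BAND_LEVEL = 1.0
BLOB_LEVEL = 1.5


@dataclass
class PhantomParams:
    """Geometry and sampling parameters of the phantom population.

    Defaults define the study conditions used throughout the test suite:
    64-voxel scenes, 16-24 slices per view, a 5-voxel-wide band, a 10-voxel
    tear gap, noise sd 0.05 (band-to-background contrast 0.7, so single
    voxels are ~14 sd from ambiguity) and 30% tear prevalence, inside the
    18-45% range spanned by the real training/validation cohorts.
    """

    spatial_size: int = 64
    layer_range: tuple[int, int] = (16, 24)
    band_width: float = 5.0
    gap_length: float = 10.0
    noise_sd: float = 0.05
    pos_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spatial_size < 16:
            raise ValueError("spatial_size must be >= 16")
        lo, hi = self.layer_range
        if lo < 4 or hi < lo:
            raise ValueError("layer_range must satisfy 4 <= min <= max")
        if not 0.0 <= self.pos_fraction <= 1.0:
            raise ValueError("pos_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.band_width <= 0 or self.gap_length <= 0:
            raise ValueError("band_width and gap_length must be positive")


@dataclass
class PhantomScene:
    """The latent geometry of one exam, before view rendering.

    The band runs between ``p0`` and ``p1`` (voxel coordinates, axis order
    z, y, x).  For a torn scene ``gap_t`` is the interval of the band's
    arc-length parameter t in [0, 1] carved back to background, and
    ``blob_center`` the centre of the hyperintense blob placed beside it.
    """

    params: PhantomParams
    label: int
    p0: np.ndarray
    p1: np.ndarray
    gap_t: tuple[float, float] | None = None
    blob_center: np.ndarray | None = None

    def band_center_path(self, n: int = 200) -> np.ndarray:
        """(n, 3) voxel coordinates tracing the band's central line."""
        t = np.linspace(0.0, 1.0, n)[:, None]
        return self.p0[None, :] * (1 - t) + self.p1[None, :] * t

    def _geometry(self, shape: int):
        s = shape
        zz, yy, xx = np.meshgrid(np.arange(s), np.arange(s), np.arange(s), indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1).astype(np.float32)
        d = self.p1 - self.p0
        seg_len = float(np.linalg.norm(d))
        u = d / seg_len
        rel = pts - self.p0
        t = rel @ u / seg_len  # arc-length parameter of the projection
        t_clip = np.clip(t, 0.0, 1.0)
        closest = self.p0 + (t_clip[..., None] * seg_len) * u
        dist = np.linalg.norm(pts - closest, axis=-1)
        return pts, t, dist

    def band_mask(self) -> np.ndarray:
        """Boolean S^3 mask of the intact band (gap not carved out)."""
        s = self.params.spatial_size
        _, _, dist = self._geometry(s)
        return dist <= self.params.band_width / 2.0

    def render(self) -> np.ndarray:
        """Noise-free S^3 scene (float32, axis order z, y, x)."""
        p = self.params
        s = p.spatial_size
        pts, t, dist = self._geometry(s)
        c = (s - 1) / 2.0
        radii = np.array([0.48 * s, 0.42 * s, 0.42 * s], dtype=np.float32)
        inside = np.sum(((pts - c) / radii) ** 2, axis=-1) <= 1.0
        scene = np.where(inside, BACKGROUND_LEVEL, 0.0).astype(np.float32)

        band = dist <= p.band_width / 2.0
        if self.gap_t is not None:
            t0, t1 = self.gap_t
            band = band & ~((t >= t0) & (t <= t1))
        scene[band] = BAND_LEVEL

        if self.blob_center is not None:
            blob = np.linalg.norm(pts - self.blob_center, axis=-1) <= p.band_width
            scene[blob] = BLOB_LEVEL
        return scene


def sample_scene(params: PhantomParams, label: int, rng: np.random.Generator) -> PhantomScene:
    """Draw one exam's latent geometry (endpoint jitter, gap placement)."""
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    s = params.spatial_size
    # nominal diagonal crossing the mid-depth slab, jittered per exam
    p0 = np.array([0.38 * s, 0.75 * s, 0.22 * s], dtype=np.float32)
    p1 = np.array([0.62 * s, 0.25 * s, 0.78 * s], dtype=np.float32)
    p0 = p0 + rng.uniform(-0.04 * s, 0.04 * s, size=3).astype(np.float32)
    p1 = p1 + rng.uniform(-0.04 * s, 0.04 * s, size=3).astype(np.float32)

    gap_t = None
    blob_center = None
    if label == 1:
        seg_len = float(np.linalg.norm(p1 - p0))
        half = params.gap_length / (2.0 * seg_len)
        t_mid = float(rng.uniform(0.35, 0.65))
        gap_t = (t_mid - half, t_mid + half)
        # blob sits beside the gap, offset perpendicular to the band so the
        # band's centre line inside the gap stays at background level
        u = (p1 - p0) / seg_len
        perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
        perp = perp / np.linalg.norm(perp)
        if rng.random() < 0.5:
            perp = -perp
        blob_center = (p0 + t_mid * seg_len * u + perp * 2.2 * params.band_width).astype(
            np.float32
        )
    return PhantomScene(params=params, label=label, p0=p0, p1=p1, gap_t=gap_t, blob_center=blob_center)


def _view_slices(scene: np.ndarray, axis: int, n_layers: int) -> np.ndarray:
    """Extract n evenly spaced slices along `axis`, central 70% slab."""
    s = scene.shape[axis]
    idx = np.linspace(0.15 * s, 0.85 * s, n_layers).round().astype(int)
    stack = np.moveaxis(scene, axis, 0)[idx]
    return np.ascontiguousarray(stack)


def generate_exam(
    params: PhantomParams,
    label: int,
    rng: np.random.Generator,
    exam_id: str = "",
    return_scene: bool = False,
):
    """Render one exam's three views from a freshly sampled latent scene.

    Returns a dict view -> :class:`ExamVolume`; with ``return_scene=True``
    also returns the :class:`PhantomScene` so tests can trace the analytic
    band path.
    """
    scene_geom = sample_scene(params, label, rng)
    scene = scene_geom.render()
    lo, hi = params.layer_range
    views: dict[str, ExamVolume] = {}
    for axis, view in enumerate(VIEWS):
        n_layers = int(rng.integers(lo, hi + 1))
        stack = _view_slices(scene, axis, n_layers)
        if params.noise_sd > 0:
            stack = stack + rng.normal(0.0, params.noise_sd, size=stack.shape)
        views[view] = ExamVolume(stack.astype(np.float32), view=view, exam_id=exam_id)
    if return_scene:
        return views, scene_geom
    return views


def generate_dataset(
    n: int,
    params: PhantomParams,
    out_dir: str | Path,
) -> DatasetManifest:
    """Write `n` phantom exams plus a CSV manifest under `out_dir`.

    The positive count is round(n * pos_fraction); label order is shuffled
    by a seed-derived stream, and each exam draws its geometry and noise
    from its own named substream, so regeneration with the same seed is
    byte-identical and independent of n-order bookkeeping.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_pos = int(round(n * params.pos_fraction))
    labels = np.array([1] * n_pos + [0] * (n - n_pos), dtype=int)
    substream(params.seed, "phantom/labels").shuffle(labels)

    records = []
    for i, label in enumerate(labels):
        exam_id = f"exam{i:04d}"
        rng = substream(params.seed, f"phantom/exam/{i}")
        views = generate_exam(params, int(label), rng, exam_id=exam_id)
        paths = {}
        for view, vol in views.items():
            path = out_dir / f"{exam_id}_{view}.npy"
            write_volume(vol, path)
            paths[view] = str(path)
        records.append(ExamRecord(exam_id=exam_id, label=int(label), paths=paths))

    manifest = DatasetManifest(records, split_tag="train")
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
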