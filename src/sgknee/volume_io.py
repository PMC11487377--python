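"""Stacked-slice volume files and CSV label manifests.

The on-disk dialect follows the MRNet convention: one ``.npy`` array per
exam-view holding the full ``L x H x W`` slice stack (L varies per exam),
plus a CSV manifest with header ``exam_id,label,axial,coronal,sagittal``
mapping each exam to its binary ACL-tear label (1 = tear = positive) and
its per-view file paths.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VIEWS = ("axial", "coronal", "sagittal")

__all__ = [
    "VIEWS",
    "ExamVolume",
    "ExamRecord",
    "DatasetManifest",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
    "class_prevalence",
]


@dataclass
class ExamVolume:
    """One view's slice stack: an ``L x H x W`` real array plus metadata.

    L is the slice (layer) count and may vary between exams; H and W are
    the in-plane dimensions (256 for MRNet-dialect data, smaller for the
    synthetic phantom).
    """

    data: np.ndarray
    view: str = "axial"
    exam_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(
                f"ExamVolume requires a 3-D (L, H, W) array, got ndim={arr.ndim}"
            )
        if arr.shape[0] < 1:
            raise ValueError("ExamVolume requires at least one layer")
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("ExamVolume values must be finite")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}; expected one of {VIEWS}")
        self.data = arr

    @property
    def layers(self) -> int:
        return int(self.data.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass
class ExamRecord:
    """One exam: id, binary label (1 = ACL tear), and per-view file paths."""

    exam_id: str
    label: int
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class DatasetManifest:
    """Ordered collection of exam records with split bookkeeping."""

    records: list[ExamRecord]
    split_tag: str = "train"

    def __post_init__(self) -> None:
        ids = [r.exam_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate exam_ids in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def exam_ids(self) -> list[str]:
        return [r.exam_id for r in self.records]

    def subset(self, exam_ids: Iterable[str], split_tag: str | None = None) -> "DatasetManifest":
        keep = set(exam_ids)
        recs = [r for r in self.records if r.exam_id in keep]
        return DatasetManifest(recs, split_tag or self.split_tag)


def read_volume(path: str | os.PathLike, view: str = "axial") -> ExamVolume:
    """Load a stacked-slice volume file into an :class:`ExamVolume`.

    Any numeric dtype is accepted and promoted to float; a non-3-D array
    raises ``ValueError``.
    """
    path = Path(path)
    try:
        arr = np.load(path, allow_pickle=False)
    except (OSError, ValueError) as exc:
        if isinstance(exc, ValueError) and "pickle" not in str(exc):
            raise
        raise OSError(f"cannot read volume file {path}: {exc}") from exc
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D (L, H, W) array, got ndim={arr.ndim}")
    return ExamVolume(data=arr, view=view, exam_id=path.stem.split("_")[0] or path.stem)


def write_volume(vol: ExamVolume | np.ndarray, path: str | os.PathLike) -> None:
    """Write a volume to disk as an ``.npy`` stack (dtype preserved)."""
    arr = vol.data if isinstance(vol, ExamVolume) else np.asarray(vol)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D array, got ndim={arr.ndim}")
    np.save(Path(path), arr)


def read_manifest(path: str | os.PathLike, split_tag: str = "train") -> DatasetManifest:
    """Parse a CSV label manifest, preserving file order.

    Required columns: ``exam_id``, ``label``, plus one path column per view
    (all three of axial/coronal/sagittal, or a subset in single-view mode).
    """
    df = pd.read_csv(path, dtype={"exam_id": str})
    missing = {"exam_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    view_cols = [v for v in VIEWS if v in df.columns]
    if not view_cols:
        raise ValueError(f"manifest {path} has no view path column (expected one of {VIEWS})")
    labels = df["label"].to_numpy()
    bad = [x for x in labels if x not in (0, 1)]
    if bad:
        raise ValueError(f"manifest labels must be 0/1, found {sorted(set(bad))}")
    records = [
        ExamRecord(
            exam_id=str(row["exam_id"]),
            label=int(row["label"]),
            paths={v: str(row[v]) for v in view_cols},
        )
        for _, row in df.iterrows()
    ]
    return DatasetManifest(records, split_tag)


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    """Write a manifest back out as CSV (header exam_id,label,<views>)."""
    view_cols = [v for v in VIEWS if any(v in r.paths for r in manifest.records)] or list(VIEWS)
    rows = [
        {"exam_id": r.exam_id, "label": r.label, **{v: r.paths.get(v, "") for v in view_cols}}
        for r in manifest.records
    ]
    pd.DataFrame(rows, columns=["exam_id", "label", *view_cols]).to_csv(path, index=False)


def class_prevalence(manifest: DatasetManifest | Sequence[int]) -> float:
    """Fraction of positive (ACL-tear) exams; input to the loss weight alpha."""
    labels = manifest.labels if isinstance(manifest, DatasetManifest) else np.asarray(manifest)
    if len(labels) == 0:
        raise ValueError("cannot compute prevalence of an empty manifest")
    return float(np.mean(labels == 1))


def load_exam(record: ExamRecord, views: Sequence[str] = VIEWS) -> dict[str, ExamVolume]:
    """Load all requested views of one exam from its manifest record."""
    out = {}
    for v in views:
        if v not in record.paths:
            raise KeyError(f"exam {record.exam_id}: no path for view {v!r}")
        vol = read_volume(record.paths[v], view=v)
        vol.exam_id = record.exam_id
        out[v] = vol
    return out
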