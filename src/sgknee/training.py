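"""Training, evaluation and ablation orchestration.

Each view (axial/coronal/sagittal) gets its own model, trained with the
weighted + focal objective; at evaluation the three per-view confidence
scores are combined by fuzzy-distance fusion.  Exams with different slice
counts are collated by padding/cropping to the batch median L (padding
edge-replicates the final slice, cropping keeps the central slab).

Intensity normalization statistics are computed once from the raw training
split and reused for tuning/validation, so no information leaks from the
held-out exams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from sgknee.dda import (
    AugmentConfig,
    NormStats,
    augment_pipeline,
    basic_augment,
    center_crop,
    compute_norm_stats,
    normalize,
)
from sgknee.evaluation import MetricsReport, confusion_metrics
from sgknee.fusion import FusionInput, fuse, fused_positive_score
from sgknee.network import (
    BackboneConfig,
    LossParams,
    SGNetModel,
    build_model,
    total_loss,
)
from sgknee.nn import Adam, ReduceLROnPlateau
from sgknee.rng import substream
from sgknee.volume_io import VIEWS, DatasetManifest, ExamVolume, class_prevalence, load_exam

__all__ = [
    "TrainConfig",
    "InMemoryDataset",
    "collate",
    "train_view",
    "evaluate_view",
    "fuse_scores",
    "run_experiment",
    "run_ablation",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Optimizer defaults (Adam, weight decay 0.01, plateau factor 0.8 with
    patience 5) follow the reference protocol; the default learning rate
    1e-3 suits the randomly initialized desk-scale `small_cnn` backbone —
    the 1e-5 used to fine-tune large pretrained backbones is far below the
    useful range for training this size of network from scratch.
    """

    epochs: int = 15
    batch_size: int = 16
    lr: float = 1e-3
    weight_decay: float = 0.01
    plateau_factor: float = 0.8
    plateau_patience: int = 5
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    use_dda: bool = True
    use_sg: bool = True
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(crop_size=56))
    augment_style: str = "dda"  # "dda" or "basic" (conventional flip/shift baseline)
    group_sizes: tuple[int, ...] = (1, 2, 4)
    reduction: int = 4
    alpha: float | None = None  # None -> 1 - train prevalence
    gamma: float = 2.0
    views: tuple[str, ...] = VIEWS
    seed: int = 0


@dataclass
class LoadedExam:
    exam_id: str
    label: int
    views: dict[str, ExamVolume]


class InMemoryDataset:
    """All exams of a manifest loaded into memory, order-preserving."""

    def __init__(self, exams: list[LoadedExam]):
        self.exams = exams

    @classmethod
    def from_manifest(cls, manifest: DatasetManifest, views=VIEWS) -> "InMemoryDataset":
        exams = [
            LoadedExam(r.exam_id, r.label, load_exam(r, views)) for r in manifest.records
        ]
        return cls(exams)

    def __len__(self) -> int:
        return len(self.exams)

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.exams], dtype=int)

    def subset(self, indices) -> "InMemoryDataset":
        return InMemoryDataset([self.exams[i] for i in indices])


def collate(volumes: list[np.ndarray]) -> np.ndarray:
    """Stack (L_i, H, W) arrays to (B, L_med, H, W).

    Deeper stacks keep their central L_med slices; shallower ones are
    padded by repeating the final slice.
    """
    Ls = [v.shape[0] for v in volumes]
    target = int(np.median(Ls))
    out = []
    for v in volumes:
        L = v.shape[0]
        if L > target:
            start = (L - target) // 2
            v = v[start : start + target]
        elif L < target:
            v = np.concatenate([v, np.repeat(v[-1:], target - L, axis=0)], axis=0)
        out.append(v)
    return np.stack(out).astype(np.float32)


def _prepare_eval(exam: LoadedExam, view: str, crop: int, stats: NormStats) -> np.ndarray:
    return normalize(center_crop(exam.views[view], crop), stats).data


def _prepare_train(
    exam: LoadedExam, view: str, cfg: TrainConfig, stats: NormStats, epoch: int
) -> np.ndarray:
    if not cfg.use_dda:
        return _prepare_eval(exam, view, cfg.augment.crop_size, stats)
    pipeline = basic_augment if cfg.augment_style == "basic" else augment_pipeline
    aug = pipeline(exam.views, cfg.augment, stats, seed=cfg.seed, tag=f"{epoch}/{exam.exam_id}")
    return aug[view].data


def train_view(
    train_ds: InMemoryDataset,
    tune_ds: InMemoryDataset,
    view: str,
    cfg: TrainConfig,
    stats: NormStats,
) -> tuple[SGNetModel, dict]:
    """Train one view's model; returns (model, history).

    history holds per-epoch mean training loss and tune loss; the plateau
    scheduler monitors the tune loss.
    """
    rng_init = substream(cfg.seed, f"init/{view}")
    model = build_model(
        cfg.backbone, use_sg=cfg.use_sg, group_sizes=cfg.group_sizes,
        reduction=cfg.reduction, rng=rng_init,
    )
    alpha = cfg.alpha if cfg.alpha is not None else 1.0 - class_prevalence(train_ds.labels)
    alpha = min(max(alpha, 1e-3), 1 - 1e-3)
    lp = LossParams(alpha=alpha, gamma=cfg.gamma)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.plateau_patience)

    n = len(train_ds)
    history = {"train_loss": [], "tune_loss": [], "lr": []}
    for epoch in range(cfg.epochs):
        order = substream(cfg.seed, f"order/{view}/{epoch}").permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = [train_ds.exams[i] for i in order[start : start + cfg.batch_size]]
            vols = collate([_prepare_train(e, view, cfg, stats, epoch) for e in batch])
            ys = np.array([e.label for e in batch])
            scores = model(vols)
            loss = total_loss(scores, ys, lp)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        tune_scores = evaluate_view(model, tune_ds, view, cfg, stats)
        tune_loss = float(total_loss(tune_scores, tune_ds.labels, lp).data)
        sched.step(tune_loss)
        history["train_loss"].append(float(np.mean(losses)))
        history["tune_loss"].append(tune_loss)
        history["lr"].append(opt.lr)
    return model, history


def evaluate_view(
    model: SGNetModel,
    ds: InMemoryDataset,
    view: str,
    cfg: TrainConfig,
    stats: NormStats,
    batch_size: int = 32,
) -> np.ndarray:
    """(n, 2) softmax confidence scores on center-cropped, normalized exams."""
    out = []
    crop = cfg.augment.crop_size
    for start in range(0, len(ds), batch_size):
        batch = ds.exams[start : start + batch_size]
        vols = collate([_prepare_eval(e, view, crop, stats) for e in batch])
        out.append(model(vols).data)
    return np.concatenate(out, axis=0)


def fuse_scores(per_view_scores: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy-distance fusion of per-view (n, 2) score matrices.

    Returns (predicted labels, continuous tear scores) of length n.
    """
    views = sorted(per_view_scores)
    n = per_view_scores[views[0]].shape[0]
    preds = np.empty(n, dtype=int)
    scores = np.empty(n)
    for i in range(n):
        inp = FusionInput(np.stack([per_view_scores[v][i] for v in views]))
        preds[i], _ = fuse(inp)
        scores[i] = fused_positive_score(inp)
    return preds, scores


def _stratified_split(ds: InMemoryDataset, valid_frac: float, tune_frac: float, seed: int):
    idx = np.arange(len(ds))
    labels = ds.labels
    rest, valid = train_test_split(
        idx, test_size=valid_frac, stratify=labels, random_state=seed
    )
    train, tune = train_test_split(
        rest, test_size=tune_frac, stratify=labels[rest], random_state=seed
    )
    return ds.subset(np.sort(train)), ds.subset(np.sort(tune)), ds.subset(np.sort(valid))


def run_experiment(
    ds: InMemoryDataset,
    cfg: TrainConfig,
    valid_frac: float = 0.25,
    tune_frac: float = 0.2,
) -> dict:
    """Train per-view models on a stratified split and evaluate held-out.

    Returns per-view MetricsReports, the fused report (when >= 2 views),
    training histories and the raw held-out scores.
    """
    train_ds, tune_ds, valid_ds = _stratified_split(ds, valid_frac, tune_frac, cfg.seed)
    stats = compute_norm_stats(
        vol for e in train_ds.exams for vol in e.views.values()
    )
    y_valid = valid_ds.labels
    per_view_scores: dict[str, np.ndarray] = {}
    reports: dict[str, MetricsReport] = {}
    histories: dict[str, dict] = {}
    models: dict[str, SGNetModel] = {}
    for view in cfg.views:
        model, hist = train_view(train_ds, tune_ds, view, cfg, stats)
        scores = evaluate_view(model, valid_ds, view, cfg, stats)
        per_view_scores[view] = scores
        reports[view] = confusion_metrics(
            y_valid, (scores[:, 1] >= 0.5).astype(int), scores[:, 1]
        )
        histories[view] = hist
        models[view] = model
    result = {
        "reports": reports,
        "histories": histories,
        "scores": per_view_scores,
        "y_valid": y_valid,
        "models": models,
        "stats": stats,
    }
    if len(cfg.views) >= 2:
        preds, fscores = fuse_scores(per_view_scores)
        result["fused"] = confusion_metrics(y_valid, preds, fscores)
    return result


def run_ablation(
    ds: InMemoryDataset,
    cfg: TrainConfig,
    toggle_sets: list[dict] | None = None,
    valid_frac: float = 0.25,
    tune_frac: float = 0.2,
):
    """Module-efficacy table: one row per (view, toggle set) plus a fused row.

    Default toggles mirror the incremental design: Base, Base+DDA,
    Base+DDA+SG, with fusion applied to the final (full) configuration.
    Returns a pandas DataFrame plus the per-configuration raw results.
    """
    import pandas as pd
    from dataclasses import replace

    if toggle_sets is None:
        toggle_sets = [
            {"name": "base", "use_dda": False, "use_sg": False},
            {"name": "dda", "use_dda": True, "use_sg": False},
            {"name": "dda+sg", "use_dda": True, "use_sg": True},
        ]
    rows = []
    raw = {}
    for toggles in toggle_sets:
        run_cfg = replace(cfg, use_dda=toggles["use_dda"], use_sg=toggles["use_sg"])
        res = run_experiment(ds, run_cfg, valid_frac=valid_frac, tune_frac=tune_frac)
        raw[toggles["name"]] = res
        for view in cfg.views:
            r = res["reports"][view]
            rows.append(
                {"view": view, "modules": toggles["name"], "accuracy": r.accuracy,
                 "sensitivity": r.sensitivity, "specificity": r.specificity, "auc": r.auc}
            )
    if "fused" in raw[toggle_sets[-1]["name"]]:
        r = raw[toggle_sets[-1]["name"]]["fused"]
        rows.append(
            {"view": "all", "modules": toggle_sets[-1]["name"] + "+fusion",
             "accuracy": r.accuracy, "sensitivity": r.sensitivity,
             "specificity": r.specificity, "auc": r.auc}
        )
    return pd.DataFrame(rows), raw


def save_checkpoint(path, models: dict[str, SGNetModel], cfg: TrainConfig, stats: NormStats):
    """Persist per-view parameters, config and normalization stats."""
    path = Path(path)
    arrays = {}
    for view, model in models.items():
        for i, arr in enumerate(model.state_arrays()):
            arrays[f"{view}/{i}"] = arr
    meta = {
        "views": sorted(models),
        "stats": {"m": stats.m, "std": stats.std},
        "config": _config_meta(cfg),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _config_meta(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["group_sizes"] = list(cfg.group_sizes)
    d["views"] = list(cfg.views)
    return d


def load_checkpoint(path) -> tuple[dict[str, SGNetModel], TrainConfig, NormStats]:
    data = np.load(Path(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    c = meta["config"]
    cfg = TrainConfig(
        epochs=c["epochs"], batch_size=c["batch_size"], lr=c["lr"],
        weight_decay=c["weight_decay"], plateau_factor=c["plateau_factor"],
        plateau_patience=c["plateau_patience"],
        backbone=BackboneConfig(**c["backbone"]),
        use_dda=c["use_dda"], use_sg=c["use_sg"],
        augment=AugmentConfig(**c["augment"]), augment_style=c["augment_style"],
        group_sizes=tuple(c["group_sizes"]), reduction=c["reduction"],
        alpha=c["alpha"], gamma=c["gamma"], views=tuple(c["views"]), seed=c["seed"],
    )
    stats = NormStats(**meta["stats"])
    models = {}
    for view in meta["views"]:
        model = build_model(
            cfg.backbone, use_sg=cfg.use_sg, group_sizes=cfg.group_sizes,
            reduction=cfg.reduction, rng=substream(cfg.seed, f"init/{view}"),
        )
        n_params = len(model.parameters())
        model.load_state_arrays([data[f"{view}/{i}"] for i in range(n_params)])
        models[view] = model
    return models, cfg, stats
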