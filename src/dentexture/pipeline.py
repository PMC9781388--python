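"""End-to-end orchestration: manifests, runs, and the configuration sweep.

A run executes segmentation -> resize -> DWT texture mapping -> CNN
training -> evaluation on a labeled image dataset, persisting its
configuration, seeds, history, confusion matrix and metrics under a run
directory so that any run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from . import classifier, evaluation, segmentation, wavelet
from .errors import ParameterError, StageError
from .synthetic import CLASS_NAMES, ManifestRecord, load_gray_png

logger = logging.getLogger("dentexture")


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]
    root: Path

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records], dtype=np.int64)

    def paths(self) -> list[Path]:
        return [self.root / r.path for r in self.records]


def _label_from_folder(name: str) -> int:
    """Accept '<label>_<Name>' folders or bare Table-style class names."""
    head = name.split("_", 1)[0]
    if head.isdigit() and 0 <= int(head) <= 8:
        return int(head)
    flat = name.replace("_", " ").strip().lower()
    for i, cls in enumerate(CLASS_NAMES):
        if flat == cls.lower():
            return i
    raise ParameterError(f"unknown class folder: {name!r}")


def load_manifest(root: str | Path) -> DatasetManifest:
    """Load a dataset from a manifest CSV or a folder-per-class layout.

    Record order is deterministic (lexicographic by path). Every listed
    path must exist.
    """
    root = Path(root)
    if not root.exists():
        raise ParameterError(f"dataset root {root} does not exist")
    records: list[ManifestRecord] = []
    csv_path = root / "manifest.csv"
    if csv_path.exists():
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                label = int(row["label"])
                if not 0 <= label <= 8:
                    raise ParameterError(f"label out of range in manifest: {label}")
                if not (root / row["path"]).exists():
                    raise ParameterError(f"missing image file: {row['path']}")
                records.append(ManifestRecord(row["path"], label, row["class_name"]))
    else:
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            label = _label_from_folder(sub.name)
            for img in sorted(sub.glob("*.png")) + sorted(sub.glob("*.jpg")):
                records.append(
                    ManifestRecord(str(img.relative_to(root)), label, CLASS_NAMES[label])
                )
    records.sort(key=lambda r: r.path)
    return DatasetManifest(tuple(records), root)


def split_manifest(
    m: DatasetManifest,
    ratio: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[DatasetManifest, DatasetManifest]:
    """Seeded stratified split; per class, round(ratio * count) records go
    to the training set and the remainder to validation."""
    if not 0 < ratio < 1:
        raise ParameterError("split ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list[ManifestRecord] = []
    val: list[ManifestRecord] = []
    if stratified:
        by_class: dict[int, list[ManifestRecord]] = {}
        for rec in m.records:
            by_class.setdefault(rec.label, []).append(rec)
        for label in sorted(by_class):
            recs = by_class[label]
            if len(recs) < 2:
                raise ParameterError(
                    f"class {label} has {len(recs)} record(s); need >= 2 to stratify"
                )
            order = rng.permutation(len(recs))
            n_train = int(np.floor(ratio * len(recs) + 0.5))  # round half up
            n_train = min(max(n_train, 1), len(recs) - 1)
            for i, j in enumerate(order):
                (train if i < n_train else val).append(recs[j])
    else:
        order = rng.permutation(len(m.records))
        n_train = int(np.floor(ratio * len(m.records) + 0.5))
        for i, j in enumerate(order):
            (train if i < n_train else val).append(m.records[j])
    train.sort(key=lambda r: r.path)
    val.sort(key=lambda r: r.path)
    return (
        DatasetManifest(tuple(train), m.root),
        DatasetManifest(tuple(val), m.root),
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """One pipeline configuration of the batch/epoch/augmentation grid."""

    id: str
    batch_size: int = 32
    epochs: int = 250
    augmentation: bool = True
    dwt_level: int = 2
    image_size: int = 64
    seed: int = 0
    features: str = "dwt"  # "dwt" or "raw" (resized image, no segmentation)
    wavelet_family: str = "haar"
    texture_norm: str = "global"  # preserves inter-subband energy ratios
    early_stop_patience: int = 20

    def validate(self) -> None:
        if self.features not in ("dwt", "raw"):
            raise ParameterError(f"unknown feature mode {self.features!r}")
        if self.features == "dwt" and self.dwt_level not in (1, 2, 3):
            raise ParameterError(f"dwt_level must be in {{1,2,3}}, got {self.dwt_level}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be positive")
        if self.image_size % 8:
            raise ParameterError("image_size must be divisible by 8")


def texture_transform(cfg: ExperimentConfig):
    """The per-image feature map of ``cfg``: DWT pyramid mosaic, or None
    for raw mode. Returned as a callable so training can augment the image
    first and extract texture afterwards."""
    if cfg.features == "raw":
        return None
    spec = wavelet.WaveletSpec(cfg.wavelet_family, cfg.dwt_level)

    def transform(img: np.ndarray) -> np.ndarray:
        return wavelet.texture_map(
            wavelet.decompose(img, spec), cfg.texture_norm
        ).pixels

    return transform


def preprocess_image(path: str | Path, cfg: ExperimentConfig,
                     apply_texture: bool = True) -> np.ndarray:
    """Load one image and produce the classifier input for ``cfg``.

    DWT mode: front-face segmentation, resize to ``image_size``, multilevel
    decomposition at ``dwt_level`` and pyramid texture map (skipped when
    ``apply_texture`` is false, leaving the resized crop for training-time
    augmentation). Raw mode: plain resize of the unsegmented image (the
    ablation baseline).
    """
    img = load_gray_png(path)
    if cfg.features == "raw":
        return resize(img, (cfg.image_size, cfg.image_size), anti_aliasing=True)
    crop = segmentation.extract_front_face(img)
    small = resize(crop, (cfg.image_size, cfg.image_size), anti_aliasing=True)
    if not apply_texture:
        return small
    return texture_transform(cfg)(small)


def _prepare_features(m: DatasetManifest, cfg: ExperimentConfig,
                      apply_texture: bool = True) -> np.ndarray:
    feats = np.empty((len(m), cfg.image_size, cfg.image_size), dtype=np.float32)
    for i, path in enumerate(m.paths()):
        try:
            feats[i] = preprocess_image(path, cfg, apply_texture)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise StageError("preprocess", f"{path}: {exc}") from exc
    return feats


def run_pipeline(
    data: DatasetManifest,
    cfg: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute one full configuration and return its metrics report."""
    cfg.validate()
    t0 = time.time()
    train_m, val_m = split_manifest(data, 0.8, cfg.seed)
    logger.info("split: %d train / %d val", len(train_m), len(val_m))

    # training images stay in image space so augmentation precedes the
    # texture transform; validation gets the transform without augmentation
    x_train = _prepare_features(train_m, cfg, apply_texture=False)
    x_val = _prepare_features(val_m, cfg, apply_texture=True)
    logger.info("preprocess done in %.1fs", time.time() - t0)

    mcfg = classifier.ModelConfig(input_size=cfg.image_size)
    model = classifier.build_model(mcfg)
    tcfg = classifier.TrainConfig(
        batch_size=cfg.batch_size,
        max_epochs=cfg.epochs,
        seed=cfg.seed,
        early_stop_patience=cfg.early_stop_patience,
    )
    acfg = classifier.AugmentationConfig(enabled=cfg.augmentation)
    t1 = time.time()
    try:
        model, history = classifier.train(
            model, (x_train, train_m.labels()), (x_val, val_m.labels()), tcfg, acfg,
            feature_fn=texture_transform(cfg),
        )
    except ParameterError:
        raise
    except Exception as exc:  # pragma: no cover
        raise StageError("train", str(exc)) from exc
    logger.info("training done in %.1fs (%d epochs)", time.time() - t1,
                history.stopped_epoch)

    labels, _ = classifier.predict(model, x_val)
    cm = evaluation.confusion_matrix(val_m.labels(), labels, n_classes=mcfg.n_classes)
    report = evaluation.metrics_report(cm)
    best = int(np.argmin(history.val_loss))
    report.update(
        {
            "id": cfg.id,
            "config": asdict(cfg),
            "val_loss": history.val_loss[best],
            "best_epoch": best + 1,
            "epochs_run": history.stopped_epoch,
            "wall_seconds": time.time() - t0,
        }
    )

    if out_dir is not None:
        run_dir = Path(out_dir) / cfg.id
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
        pd.DataFrame(
            {
                "epoch": np.arange(1, len(history.train_loss) + 1),
                "train_loss": history.train_loss,
                "train_acc": history.train_acc,
                "val_loss": history.val_loss,
                "val_acc": history.val_acc,
            }
        ).to_csv(run_dir / "history.csv", index=False)
        cm.to_csv(run_dir / "confusion.csv")
        (run_dir / "metrics.json").write_text(json.dumps(report, indent=2))
        np.savez(run_dir / "weights.npz", *model.get_weights())
    return report


def run_sweep(
    data: DatasetManifest,
    configs: list[ExperimentConfig],
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run every configuration; return a table sorted by accuracy (desc)."""
    if not configs:
        raise ParameterError("empty configuration grid")
    ids = [c.id for c in configs]
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicate configuration ids in grid")
    rows = []
    for cfg in configs:
        report = run_pipeline(data, cfg, out_dir)
        rows.append(
            {
                "id": cfg.id,
                "batch_size": cfg.batch_size,
                "epochs": cfg.epochs,
                "augmented": cfg.augmentation,
                "accuracy": report["accuracy"],
                "loss": report["val_loss"],
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "accuracy", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    table["best"] = False
    table.loc[0, "best"] = True
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / "sweep.csv", index=False)
    return table


def default_sweep_grid(seed: int = 0, epochs_scale: float = 1.0) -> list[ExperimentConfig]:
    """The six-configuration comparison grid (batch size x epochs x
    augmentation); ``epochs_scale`` shrinks epoch budgets for quick runs."""
    combos = [
        ("cfg1", 16, 100, False),
        ("cfg2", 16, 150, True),
        ("cfg3", 32, 150, False),
        ("cfg4", 64, 250, True),
        ("cfg5", 32, 250, True),
        ("cfg6", 32, 300, False),
    ]
    return [
        ExperimentConfig(
            id=name,
            batch_size=b,
            epochs=max(1, int(e * epochs_scale)),
            augmentation=aug,
            seed=seed,
        )
        for name, b, e, aug in combos
    ]
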