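"""End-to-end orchestration: generate -> segment -> extract -> train ->
evaluate, with one root seed feeding every stage.

The heavy lifting lives in the stage modules; this module wires them
into a reproducible pipeline and persists intermediate artifacts
(crops, feature matrices with JSON sidecars, the model archive and the
evaluation report) so stages can be rerun independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .evaluation import EvaluationReport, evaluate
from .features import BispectralFeatures, FeatureConfig
from .lmoments import LMomentLayer
from .preprocess import adjust_intensity, crop_to_cell, rotate_augment, segment_with_fallback
from .softmax import SoftmaxRegression
from .synthetic import CLASS_NAMES, CellImage, DatasetManifest, generate_dataset

logger = logging.getLogger("hep2hos")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "split_dataset"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, round-trippable through YAML."""

    # synthetic data
    n_per_class: int = 50
    intensity_mix: float = 0.5
    image_size: int = 64
    noise_sd: float = 0.02
    # segmentation
    gac_iterations: int = 100
    gac_smoothing: int = 2
    gac_balloon: float = 1.0
    crop_size: int = 50
    # feature extraction
    angle_step: float = 2.0
    fft_len: int = 1024
    n_slopes: int = 256
    # L-moment layer
    grouping: str = "per_slope"
    block_size: Optional[int] = None
    scale_stat: str = "raw"
    standardize: bool = True
    # training
    eta: float = 0.01
    iterations: int = 500
    lam: float = 0.01
    init: str = "uniform"
    # protocol
    augment_step: Optional[int] = None
    train_fraction: float = 0.8
    seed: int = 0

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: EvaluationReport
    model: SoftmaxRegression
    y_true: np.ndarray
    y_pred: np.ndarray
    train_size: int
    test_size: int
    descriptor_dim: int


def split_dataset(
    manifest: DatasetManifest, train_fraction: float = 0.8, seed: int = 0
) -> DatasetManifest:
    """Reassign train/test splits stratified per class at the given
    fraction, seeded."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    records = [dataclasses.replace(r) for r in manifest.records]
    for label in sorted({r.label for r in records}):
        idx = [i for i, r in enumerate(records) if r.label == label]
        order = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        for pos, j in enumerate(order):
            records[idx[j]].split = "train" if pos < n_train else "test"
    return DatasetManifest(records)


def _segment_and_crop(image: CellImage, cfg: PipelineConfig) -> CellImage:
    adjusted = adjust_intensity(image)
    mask = segment_with_fallback(
        adjusted,
        iterations=cfg.gac_iterations,
        smoothing=cfg.gac_smoothing,
        balloon=cfg.gac_balloon,
    )
    return crop_to_cell(image, mask, out_size=cfg.crop_size)


def run_pipeline(
    config: PipelineConfig, out_dir: Optional[Path | str] = None
) -> PipelineResult:
    """Execute all stages on a synthetic dataset and evaluate on the
    held-out test split.

    Augmentation (when ``config.augment_step`` is set) applies rotation
    copies to training crops only; test images are never augmented.
    """
    cfg = config
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(out / "config.yaml")
    logger.info("pipeline start (config hash %s)", cfg.config_hash())

    manifest, items = generate_dataset(
        n_per_class=cfg.n_per_class,
        intensity_mix=cfg.intensity_mix,
        size=cfg.image_size,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
        train_fraction=cfg.train_fraction,
    )
    logger.info("generated %d images", len(items))

    crops = [_segment_and_crop(img, cfg) for img, _ in items]
    logger.info("segmented and cropped %d images to %dx%d",
                len(crops), cfg.crop_size, cfg.crop_size)

    class_index = {name: i + 1 for i, name in enumerate(CLASS_NAMES)}
    train_images, train_labels = [], []
    test_images, test_labels, test_levels = [], [], []
    for rec, crop in zip(manifest.records, crops):
        if rec.split == "train":
            if cfg.augment_step:
                aug = rotate_augment(crop, cfg.augment_step)
                train_images.extend(aug.images)
                train_labels.extend([class_index[rec.label]] * len(aug.images))
            else:
                train_images.append(crop)
                train_labels.append(class_index[rec.label])
        else:
            test_images.append(crop)
            test_labels.append(class_index[rec.label])
            test_levels.append(rec.intensity_level)
    logger.info("train %d (augment step %s), test %d",
                len(train_images), cfg.augment_step, len(test_images))

    extractor = BispectralFeatures(
        angle_step=cfg.angle_step, fft_len=cfg.fft_len, n_slopes=cfg.n_slopes
    ).fit()
    X_train = extractor.transform(train_images)
    X_test = extractor.transform(test_images)
    logger.info("extracted %d features per image", X_train.shape[1])

    layer = LMomentLayer(
        grouping=cfg.grouping,
        n_slopes=cfg.n_slopes,
        block_size=cfg.block_size,
        scale_stat=cfg.scale_stat,
    ).fit(X_train)
    D_train = layer.transform(X_train)
    D_test = layer.transform(X_test)
    logger.info("L-moment descriptors: %d units", D_train.shape[1])

    if cfg.standardize:
        mu = D_train.mean(axis=0)
        sd = D_train.std(axis=0)
        sd[sd == 0] = 1.0
        D_train = (D_train - mu) / sd
        D_test = (D_test - mu) / sd

    model = SoftmaxRegression(
        eta=cfg.eta,
        iterations=cfg.iterations,
        lam=cfg.lam,
        random_state=cfg.seed,
        init=cfg.init,
    ).fit(D_train, np.asarray(train_labels))
    logger.info("trained softmax layer: final cost %.4f", model.cost_trace_[-1])

    y_true = np.asarray(test_labels)
    y_pred = model.predict(D_test)
    report = evaluate(
        y_true,
        y_pred,
        k=len(CLASS_NAMES),
        levels=np.asarray(test_levels),
        class_names=CLASS_NAMES,
    )
    logger.info("MCA %.4f", report.mca)

    if out is not None:
        _persist(out, cfg, extractor, X_train, X_test, model, report)
    return PipelineResult(
        report=report,
        model=model,
        y_true=y_true,
        y_pred=y_pred,
        train_size=len(train_images),
        test_size=len(test_images),
        descriptor_dim=D_train.shape[1],
    )


def save_feature_matrix(
    path: Path | str, X: np.ndarray, cfg: FeatureConfig
) -> None:
    """Binary feature matrix with a JSON sidecar recording the settings."""
    path = Path(path)
    np.save(path, X)
    sidecar = {
        "n_angles": cfg.n_angles,
        "n_slopes": cfg.n_slopes,
        "fft_len": cfg.fft_len,
        "angle_step": cfg.angle_step,
        "shape": list(X.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def _persist(out, cfg, extractor, X_train, X_test, model, report) -> None:
    save_feature_matrix(out / "features_train.npy", X_train, extractor.config)
    save_feature_matrix(out / "features_test.npy", X_test, extractor.config)
    model.save(out / "model")
    (out / "report.txt").write_text(report.to_text(CLASS_NAMES) + "\n")
    np.savetxt(out / "confusion.csv", report.confusion.counts, fmt="%d", delimiter=",")
    if report.per_level_table is not None:
        report.per_level_table.to_csv(out / "level_report.csv", index=False)
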