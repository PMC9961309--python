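"""End-to-end orchestration: reject -> latent + radiomic -> fuse -> classify.

``run_pipeline`` executes the whole chain on a two-class image directory (or
an in-memory image stack) and returns a results bundle with per-fold
confusion counts, the full metrics suite and mean +- sd aggregates.  The
latent-feature network is retrained inside each cross-validation fold by
default (leakage-safe); ``per_fold_network=False`` trains it once on the
whole set, the cheaper replication mode.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import fusion
from .classification import cross_validate_fn, make_classifier
from .imaging_io import DatasetIndex, index_dataset, load_image, resize_to_input
from .nnet import NetworkSpec, TrainingConfig, build_network, train_network
from .radiomic import GLCMConfig, HOGConfig, LBPConfig, radiomic_feature_vector
from .rejection import RejectionConfig, apply_rejection

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    rejection: RejectionConfig = field(default_factory=RejectionConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    hog: HOGConfig = field(default_factory=HOGConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    classifier: str = "knn"
    classifier_args: dict = field(default_factory=dict)
    segments: tuple = fusion.SEGMENT_ORDER
    folds: int = 10
    seed: int = 0
    per_fold_network: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segments"] = list(self.segments)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Inverse of :meth:`to_dict`; unknown keys are rejected."""
        d = dict(d)
        sub = {
            "rejection": RejectionConfig,
            "training": TrainingConfig,
            "glcm": GLCMConfig,
            "hog": HOGConfig,
            "lbp": LBPConfig,
        }
        kwargs = {}
        for key, typ in sub.items():
            if key in d:
                kwargs[key] = typ(**d.pop(key))
        if "segments" in d:
            kwargs["segments"] = tuple(d.pop("segments"))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)


def load_kept_images(index: DatasetIndex, side: int = 64):
    """(images, labels, paths) for the non-rejected records of an index."""
    kept = index.kept()
    images = np.stack([resize_to_input(load_image(r.path), side) for r in kept])
    labels = np.array([r.label for r in kept], dtype=np.int64)
    return images, labels, [r.path for r in kept]


def extract_radiomic_matrix(images: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    return np.stack(
        [radiomic_feature_vector(img, cfg.glcm, cfg.hog, cfg.lbp) for img in images]
    )


def _train_and_extract(images, labels, cfg: PipelineConfig, train_idx=None):
    """Train the latent network (optionally on a subset) and featurize all."""
    net = build_network(NetworkSpec(), seed=cfg.training.seed)
    sel = slice(None) if train_idx is None else train_idx
    train_network(net, images[sel], labels[sel], cfg.training)
    return net.extract_latent_batch(images)


def run_pipeline(
    cfg: PipelineConfig,
    root: str | Path | None = None,
    *,
    images: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run rejection, feature extraction, fusion and cross-validation.

    Input is either a directory laid out as ``root/0``, ``root/1`` or an
    in-memory (images, labels) pair.  Returns the results bundle; with
    ``out_dir`` set, writes ``results.json`` and the resolved config
    alongside it.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    rejection_report = None
    if root is not None:
        index = index_dataset(root)
        index, report = apply_rejection(index, cfg.rejection)
        rejection_report = report.to_dict()
        images, labels, _ = load_kept_images(index)
    elif images is None or labels is None:
        raise ValueError("need either a dataset root or (images, labels)")
    else:
        sums = images.reshape(len(images), -1).astype(np.int64).sum(axis=1)
        keep = sums > cfg.rejection.threshold
        rejection_report = {
            "kept": {c: int((keep & (labels == c)).sum()) for c in (0, 1)},
            "rejected": {c: int((~keep & (labels == c)).sum()) for c in (0, 1)},
        }
        images, labels = images[keep], labels[keep]
    timings["rejection"] = time.perf_counter() - t0
    logger.info("after rejection: %d slices (%s)", len(images), rejection_report)

    t0 = time.perf_counter()
    radiomic = extract_radiomic_matrix(images, cfg)
    timings["radiomic"] = time.perf_counter() - t0

    seg_map = fusion.FeatureSegmentMap()

    def build_features(latent: np.ndarray) -> np.ndarray:
        hfs = np.concatenate([latent, radiomic], axis=1)
        if tuple(cfg.segments) != fusion.SEGMENT_ORDER:
            hfs, _ = fusion.select_segments(hfs, seg_map, cfg.segments)
        return hfs

    t0 = time.perf_counter()
    if cfg.per_fold_network:
        cache: dict[bytes, np.ndarray] = {}

        def fold_fn(train_idx, test_idx):
            key = train_idx.tobytes()
            if key not in cache:
                cache[key] = build_features(
                    _train_and_extract(images, labels, cfg, train_idx)
                )
            x = cache[key]
            model = fusion.fit_minmax(x[train_idx])
            clf = make_classifier(cfg.classifier, **cfg.classifier_args)
            clf.fit(fusion.apply_minmax(model, x[train_idx]), labels[train_idx])
            return clf.predict(fusion.apply_minmax(model, x[test_idx]))

    else:
        x_global = build_features(_train_and_extract(images, labels, cfg))

        def fold_fn(train_idx, test_idx):
            model = fusion.fit_minmax(x_global[train_idx])
            clf = make_classifier(cfg.classifier, **cfg.classifier_args)
            clf.fit(fusion.apply_minmax(model, x_global[train_idx]), labels[train_idx])
            return clf.predict(fusion.apply_minmax(model, x_global[test_idx]))

    results = cross_validate_fn(labels, fold_fn, cfg.folds, cfg.seed)
    timings["cross_validation"] = time.perf_counter() - t0

    bundle = {
        "config": cfg.to_dict(),
        "n_slices": int(len(images)),
        "feature_length": int(
            fusion.FeatureSegmentMap().select(cfg.segments).total_length
        ),
        "rejection": rejection_report,
        "results": results.to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "results.json").write_text(json.dumps(bundle, indent=1))
        logger.info("results written to %s", out_dir / "results.json")
    return bundle
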