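"""The desk-scale phantom study: the full pipeline at its canonical settings.

Runs rejection, latent-network training (5 epochs, trained once on the kept
slices), radiomic extraction, fusion and stratified 10-fold 1-NN
cross-validation on the default phantom dataset (200 images per class, 10%
blank slices), and reports cross-validated accuracy for the hybrid feature
set and for each individual segment.  This is the study the package's
reported numbers come from; real mpMRI data is plugged in through the same
pipeline functions with a dataset directory instead.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from . import fusion
from .classification import KNNClassifier, KNNConfig, cross_validate
from .nnet import NetworkSpec, TrainingConfig, build_network, train_network
from .phantoms import PhantomSpec, generate_arrays
from .radiomic import glcm_feature_vector, hog_feature_vector, lbp_feature_vector

logger = logging.getLogger(__name__)

SEGMENT_SETS = ("FC1", "FC2", "GLCM", "HOG", "LBP")


def phantom_study(seed: int = 0, *, epochs: int = 5, folds: int = 10) -> dict:
    """Run the canonical phantom experiment; returns all measured quantities."""
    t_start = time.perf_counter()
    spec = PhantomSpec(seed=seed)
    images, labels = generate_arrays(spec)

    sums = images.reshape(len(images), -1).astype(np.int64).sum(axis=1)
    keep = sums > 0
    n_rejected = int((~keep).sum())
    rejected_blank = bool(np.all(sums[~keep] == 0)) and bool(np.all(sums[keep] > 0))
    images, labels = images[keep], labels[keep]

    t0 = time.perf_counter()
    net = build_network(NetworkSpec(), seed=seed)
    train_network(net, images, labels, TrainingConfig(epochs=epochs, seed=seed))
    latent = net.extract_latent_batch(images)
    t_train = time.perf_counter() - t0

    radiomic = np.stack(
        [
            np.concatenate(
                [glcm_feature_vector(i), hog_feature_vector(i), lbp_feature_vector(i)]
            )
            for i in images
        ]
    )
    hfs = np.concatenate([latent, radiomic], axis=1)
    seg_map = fusion.FeatureSegmentMap()

    def cv_accuracy(x):
        res = cross_validate(
            x, labels, lambda: KNNClassifier(KNNConfig(k=1)), k=folds, seed=seed
        )
        return res

    results = {"HFS": cv_accuracy(hfs)}
    for name in SEGMENT_SETS:
        x_seg, _ = fusion.select_segments(hfs, seg_map, [name])
        results[name] = cv_accuracy(x_seg)

    out = {
        "n_total": int(len(keep)),
        "n_rejected": n_rejected,
        "n_expected_blank": 2 * spec.n_blank_per_class,
        "rejected_exactly_blanks": rejected_blank,
        "n_kept": int(len(images)),
        "train_seconds": round(t_train, 1),
        "total_seconds": round(time.perf_counter() - t_start, 1),
        "accuracy": {
            name: {"mean": res.mean_accuracy, "sd": res.accuracy_sd}
            for name, res in results.items()
        },
        "aggregate": {name: res.aggregate() for name, res in results.items()},
    }
    logger.info("phantom study: %s", out["accuracy"])
    return out
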