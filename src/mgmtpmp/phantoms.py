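"""Deterministic two-class texture phantoms standing in for brain-MRI slices.

The generator emulates just enough structure for every pipeline stage to be
exercised and tested without the real mpMRI download:

* class 0: an isotropic Gaussian random field with a long correlation
  length (smooth, blob-like texture);
* class 1: an oriented sinusoidal grating plus a short-correlation-length
  field (directional structure and rough micro-texture).

Each descriptor family is thereby individually informative — grating
orientation drives HOG, correlation length drives GLCM contrast and
correlation, micro-pattern density drives LBP — so "fusion at least matches
its parts" is a meaningful property on this data.  A configurable fraction
of all-zero (blank) slices is injected per class to exercise the rejection
filter.  All randomness flows from one seed through per-image
``SeedSequence`` spawns, so generation is reproducible image by image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging_io import DatasetIndex, index_dataset


@dataclass
class PhantomSpec:
    n_per_class: int = 200
    side: int = 64
    corr_length_0: float = 6.0   # class-0 field correlation length, px
    corr_length_1: float = 1.5   # class-1 micro-texture correlation length, px
    grating_period: float = 8.0  # class-1 grating period, px
    grating_angle_deg: float = 30.0
    noise_sd: float = 8.0        # additive pixel noise, gray levels
    blank_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if not 0 <= self.blank_fraction < 1:
            raise ValueError("blank_fraction must be in [0, 1)")
        if self.side < 16:
            raise ValueError("side must be >= 16")

    @property
    def n_blank_per_class(self) -> int:
        return int(round(self.blank_fraction * self.n_per_class))


def _random_field(rng: np.random.Generator, side: int, corr: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field (wrap-around filtered)."""
    field = gaussian_filter(rng.standard_normal((side, side)), corr, mode="wrap")
    sd = field.std()
    return field / sd if sd > 0 else field


def _phantom_image(spec: PhantomSpec, label: int, rng: np.random.Generator) -> np.ndarray:
    side = spec.side
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    if label == 0:
        tex = 45.0 * _random_field(rng, side, spec.corr_length_0)
    else:
        theta = np.deg2rad(spec.grating_angle_deg)
        phase = rng.uniform(0, 2 * np.pi)
        grating = np.sin(
            2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / spec.grating_period
            + phase
        )
        tex = 30.0 * grating + 25.0 * _random_field(rng, side, spec.corr_length_1)
    img = 120.0 + tex + spec.noise_sd * rng.standard_normal((side, side))
    return np.clip(np.floor(img + 0.5), 1, 255).astype(np.uint8)  # floor 1: never blank


def generate_arrays(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """In-memory phantom set: (images (N, side, side) uint8, labels (N,)).

    The first ``n_blank_per_class`` images of each class are all-zero.
    Image i of class c is a pure function of (seed, c, i).
    """
    images, labels = [], []
    for label in (0, 1):
        for i in range(spec.n_per_class):
            if i < spec.n_blank_per_class:
                img = np.zeros((spec.side, spec.side), dtype=np.uint8)
            else:
                rng = np.random.default_rng(
                    np.random.SeedSequence(spec.seed, spawn_key=(label, i))
                )
                img = _phantom_image(spec, label, rng)
            images.append(img)
            labels.append(label)
    return np.stack(images), np.array(labels, dtype=np.int64)


def generate_phantoms(spec: PhantomSpec, out_dir: str | Path) -> DatasetIndex:
    """Write the phantom set as PNGs under ``out/0`` and ``out/1``."""
    out_dir = Path(out_dir)
    images, labels = generate_arrays(spec)
    per_class = {0: 0, 1: 0}
    for img, label in zip(images, labels):
        class_dir = out_dir / str(label)
        class_dir.mkdir(parents=True, exist_ok=True)
        i = per_class[int(label)]
        stem = "blank" if i < spec.n_blank_per_class else "slice"
        iio.imwrite(class_dir / f"{stem}_{i:04d}.png", img)
        per_class[int(label)] += 1
    return index_dataset(out_dir)


_TOY_MATRICES = {
    # 4x4 constant image at level 2: all GLCM mass on (2, 2)
    "constant4": np.full((4, 4), 2, dtype=np.int64),
    # two-column stripes: M(0,1) = 2 at d=1, 0 deg, everything else 0
    "hstripes": np.array([[0, 1], [0, 1]], dtype=np.int64),
    # 4-level matrix whose d=1, 0-deg GLCM counts the pair (3, 0) four times
    "fig6-like": np.array(
        [[3, 0, 3, 0],
         [3, 0, 3, 0],
         [1, 2, 1, 2],
         [2, 1, 0, 1]],
        dtype=np.int64,
    ),
}


def toy_level_matrix(name: str) -> np.ndarray:
    """Small named integer matrices used as co-occurrence fixtures."""
    try:
        return _TOY_MATRICES[name].copy()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_TOY_MATRICES)}"
        ) from None
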