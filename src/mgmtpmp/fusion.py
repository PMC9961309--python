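"""Hybrid feature set (HFS) assembly and min-max normalization.

The HFS concatenates, in fixed order, the CNN latent features and the three
texture descriptors::

    FC1 (512) | FC2 (64) | GLCM (13) | HOG (36) | LBP (59)   -> 684 values

Any sub-hybrid (e.g. FC1-GLCM-HOG) is a segment selection that preserves
order and lengths.  Before classification, features are contrast-normalized
to [0, 1] per feature with statistics fit on the training fold only;
constant features map to 0 and test values are clipped into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnet import LatentFeatures

SEGMENT_LENGTHS = {"FC1": 512, "FC2": 64, "GLCM": 13, "HOG": 36, "LBP": 59}
SEGMENT_ORDER = ("FC1", "FC2", "GLCM", "HOG", "LBP")
HFS_LENGTH = sum(SEGMENT_LENGTHS.values())


@dataclass(frozen=True)
class FeatureSegmentMap:
    """Ordered, contiguous (name, offset, length) segments of a feature vector."""

    segments: tuple = tuple(
        (name, sum(SEGMENT_LENGTHS[s] for s in SEGMENT_ORDER[:k]), SEGMENT_LENGTHS[name])
        for k, name in enumerate(SEGMENT_ORDER)
    )

    def __post_init__(self) -> None:
        offset = 0
        for name, off, length in self.segments:
            if off != offset or length <= 0:
                raise ValueError(f"segment {name!r} is not contiguous")
            offset += length

    @property
    def total_length(self) -> int:
        return sum(length for _, _, length in self.segments)

    @property
    def names(self) -> tuple:
        return tuple(name for name, _, _ in self.segments)

    def slice_of(self, name: str) -> slice:
        for seg, off, length in self.segments:
            if seg == name:
                return slice(off, off + length)
        raise KeyError(f"no segment named {name!r}")

    def share_pct(self, name: str) -> float:
        """Percentage share of a segment in the full vector, 2 decimals."""
        from .rejection import round_half_up

        sl = self.slice_of(name)
        return round_half_up(100.0 * (sl.stop - sl.start) / self.total_length, 2)

    def column_names(self) -> list[str]:
        return [
            f"{name.lower()}_{k + 1}"
            for name, _, length in self.segments
            for k in range(length)
        ]

    def select(self, names) -> "FeatureSegmentMap":
        """Sub-map keeping the given segments, in canonical order."""
        keep = [s for s in self.names if s in set(names)]
        unknown = set(names) - set(self.names)
        if unknown:
            raise KeyError(f"unknown segments: {sorted(unknown)}")
        segs, offset = [], 0
        for name in keep:
            sl = self.slice_of(name)
            segs.append((name, offset, sl.stop - sl.start))
            offset += sl.stop - sl.start
        return FeatureSegmentMap(tuple(segs))


def select_segments(x: np.ndarray, segment_map: FeatureSegmentMap, names):
    """Columns of x for the named segments; returns (sub-x, sub-map)."""
    sub = segment_map.select(names)
    cols = np.concatenate(
        [np.arange(*segment_map.slice_of(n).indices(segment_map.total_length))
         for n in sub.names]
    )
    x = np.asarray(x)
    return x[..., cols], sub


def assemble_hfs(
    latent: LatentFeatures,
    glcm: np.ndarray,
    hog: np.ndarray,
    lbp: np.ndarray,
) -> np.ndarray:
    """Concatenate FC1|FC2|GLCM|HOG|LBP into the 684-d hybrid vector."""
    parts = {
        "FC1": np.asarray(latent.x_fc1, dtype=np.float64).ravel(),
        "FC2": np.asarray(latent.x_fc2, dtype=np.float64).ravel(),
        "GLCM": np.asarray(glcm, dtype=np.float64).ravel(),
        "HOG": np.asarray(hog, dtype=np.float64).ravel(),
        "LBP": np.asarray(lbp, dtype=np.float64).ravel(),
    }
    for name, vec in parts.items():
        if len(vec) != SEGMENT_LENGTHS[name]:
            raise ValueError(
                f"segment {name} has length {len(vec)}, "
                f"expected {SEGMENT_LENGTHS[name]}"
            )
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"segment {name} contains non-finite values")
    return np.concatenate([parts[name] for name in SEGMENT_ORDER])


@dataclass
class MinMaxModel:
    lo: np.ndarray
    hi: np.ndarray

    @property
    def span(self) -> np.ndarray:
        return self.hi - self.lo


def fit_minmax(train_vectors: np.ndarray) -> MinMaxModel:
    """Per-feature min/max from the training vectors (at least 2 required)."""
    x = np.asarray(train_vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("min-max fit needs a 2-D array with >= 2 rows")
    return MinMaxModel(lo=x.min(axis=0), hi=x.max(axis=0))


def apply_minmax(model: MinMaxModel, vectors: np.ndarray) -> np.ndarray:
    """Map to [0, 1]; constant features map to 0, values outside are clipped."""
    x = np.asarray(vectors, dtype=np.float64)
    span = model.span
    safe = np.where(span > 0, span, 1.0)
    out = (x - model.lo) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)
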