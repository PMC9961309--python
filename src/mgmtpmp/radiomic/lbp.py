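"""Uniform local binary patterns over a circular neighborhood.

For each interior pixel, p sample points on the radius-r circle (angular
origin at the rightmost point, proceeding counter-clockwise; non-integer
coordinates bilinearly interpolated) are thresholded against the center by
the step function H(x) = 1 for x >= 0, and the bits weighted by 2^position
form the code.  The descriptor is the normalized histogram over the 58
uniform codes (at most two circular 0<->1 transitions) for p = 8, plus one
bin pooling all non-uniform codes: p*(p-1) + 3 bins in general (59 at the
default p = 8, computed over the whole 64x64 slice as a single cell).
Pixels closer than r to the border are excluded.

Because the bits depend only on the sign of intensity differences, the
descriptor is invariant to any monotone intensity transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

def _as_gray_float(img: np.ndarray) -> np.ndarray:
    """Any finite 2-D gray image is acceptable: the codes depend only on the
    sign of intensity differences, not on the intensity scale."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


@dataclass
class LBPConfig:
    n_neighbors: int = 8
    radius: int = 5

    def __post_init__(self) -> None:
        if self.n_neighbors < 2 or self.radius < 1:
            raise ValueError("need n_neighbors >= 2 and radius >= 1")

    @property
    def n_bins(self) -> int:
        return lbp_bin_count(self.n_neighbors)


def lbp_bin_count(p: int) -> int:
    """p(p-1) + 3 histogram bins: 58 uniform + 1 pooled bin at p = 8."""
    return p * (p - 1) + 3


def _transitions(code: int, p: int) -> int:
    bits = [(code >> k) & 1 for k in range(p)]
    return sum(bits[k] != bits[(k + 1) % p] for k in range(p))


@lru_cache(maxsize=None)
def _uniform_bin_map(p: int) -> np.ndarray:
    """code -> histogram bin; uniform codes in ascending order, pooled bin last."""
    uniform = [c for c in range(1 << p) if _transitions(c, p) <= 2]
    table = np.full(1 << p, len(uniform), dtype=np.int64)
    for rank, code in enumerate(uniform):
        table[code] = rank
    return table


def _sample_offsets(p: int, r: float) -> np.ndarray:
    """(p, 2) row/col offsets; origin at the rightmost point, counter-clockwise."""
    angles = 2.0 * np.pi * np.arange(p) / p
    return np.stack([-r * np.sin(angles), r * np.cos(angles)], axis=1)


def _bilinear(arr: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    fr, fc = rows - r0, cols - c0
    r1 = np.minimum(r0 + 1, arr.shape[0] - 1)
    c1 = np.minimum(c0 + 1, arr.shape[1] - 1)
    return (
        arr[r0, c0] * (1 - fr) * (1 - fc)
        + arr[r0, c1] * (1 - fr) * fc
        + arr[r1, c0] * fr * (1 - fc)
        + arr[r1, c1] * fr * fc
    )


def lbp_code(window: np.ndarray, cfg: LBPConfig | None = None) -> int:
    """LBP code of the center pixel of a (2r+1)x(2r+1) window.

    All-equal neighborhoods give the all-ones code 2^p - 1 (the threshold is
    inclusive: H(0) = 1).
    """
    cfg = cfg or LBPConfig()
    arr = np.asarray(window, dtype=np.float64)
    need = 2 * cfg.radius + 1
    if arr.shape[0] < need or arr.shape[1] < need:
        raise ValueError(
            f"window must be at least {need}x{need} for radius {cfg.radius}"
        )
    cr, cc = (arr.shape[0] - 1) / 2, (arr.shape[1] - 1) / 2
    offs = _sample_offsets(cfg.n_neighbors, cfg.radius)
    vals = _bilinear(arr, cr + offs[:, 0], cc + offs[:, 1])
    bits = vals >= arr[int(cr), int(cc)] - 1e-9
    return int((bits << np.arange(cfg.n_neighbors)).sum())


def lbp_code_image(img: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """LBP codes for all interior pixels (border of width r excluded)."""
    cfg = cfg or LBPConfig()
    arr = _as_gray_float(img)
    r = cfg.radius
    h, w = arr.shape
    if h <= 2 * r or w <= 2 * r:
        raise ValueError(
            f"image {h}x{w} too small for radius {r}: no interior pixels"
        )
    rows, cols = np.meshgrid(np.arange(r, h - r), np.arange(r, w - r),
                             indexing="ij")
    center = arr[r : h - r, r : w - r]
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (dr, dc) in enumerate(_sample_offsets(cfg.n_neighbors, r)):
        vals = _bilinear(arr, rows + dr, cols + dc)
        codes |= (vals >= center - 1e-9).astype(np.int64) << k
    return codes


def lbp_feature_vector(img: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Normalized uniform-pattern histogram x_LBP (59 bins at the defaults)."""
    cfg = cfg or LBPConfig()
    codes = lbp_code_image(img, cfg)
    bins = _uniform_bin_map(cfg.n_neighbors)[codes]
    hist = np.bincount(bins.ravel(), minlength=cfg.n_bins).astype(np.float64)
    return hist / hist.sum()
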