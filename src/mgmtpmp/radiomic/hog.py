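"""Histogram of oriented gradients with Sobel derivatives.

Gradients are taken with the 3x3 Sobel kernels; each pixel votes its
gradient magnitude into a 9-bin unsigned-orientation histogram (0-180
degrees) of its 32x32 cell, with circular linear interpolation between the
two nearest bin centers (centers at 0, 20, ..., 160 degrees, so a pure
horizontal gradient votes entirely into bin 0).  Cells are grouped into
2x2-cell blocks (stride one cell) and each block vector T is L2-normalized
as T / sqrt(||T||^2 + eps^2).  On a 64x64 image at the default geometry
there is exactly one block of 4 cells: descriptor length 4 * 9 = 36.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from ..imaging_io import validate_image8

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = _SOBEL_X.T


@dataclass
class HOGConfig:
    n_bins: int = 9
    cell_side: int = 32
    block_cells: int = 2
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.cell_side < 2 or self.block_cells < 1:
            raise ValueError("invalid HOG geometry")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    def descriptor_length(self, side: int) -> int:
        cells = side // self.cell_side
        blocks = (cells - self.block_cells + 1) ** 2
        return blocks * self.block_cells ** 2 * self.n_bins


def sobel_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(E_x, E_y) Sobel derivatives with reflective borders."""
    arr = validate_image8(img).astype(np.float64)
    ex = convolve(arr, _SOBEL_X, mode="reflect")
    ey = convolve(arr, _SOBEL_Y, mode="reflect")
    return ex, ey


def cell_histograms(img: np.ndarray, cfg: HOGConfig) -> np.ndarray:
    """(cells, cells, n_bins) magnitude-weighted orientation histograms."""
    arr = validate_image8(img)
    side = arr.shape[0]
    if arr.shape[0] != arr.shape[1] or side % cfg.cell_side:
        raise ValueError(
            f"image side must be square and divisible by cell side "
            f"{cfg.cell_side}, got {arr.shape}"
        )
    ex, ey = sobel_gradients(arr)
    mag = np.hypot(ex, ey)
    ang = np.degrees(np.arctan2(ey, ex)) % 180.0  # unsigned orientation

    bin_width = 180.0 / cfg.n_bins
    pos = ang / bin_width  # bin centers at k * bin_width
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    lo %= cfg.n_bins
    hi = (lo + 1) % cfg.n_bins

    cells = side // cfg.cell_side
    hist = np.zeros((cells, cells, cfg.n_bins), dtype=np.float64)
    rows = np.arange(side) // cfg.cell_side
    cell_r = np.repeat(rows, side).reshape(side, side)
    cell_c = cell_r.T
    flat_cell = (cell_r * cells + cell_c).ravel()
    np.add.at(hist.reshape(-1, cfg.n_bins).reshape(-1),
              flat_cell * cfg.n_bins + lo.ravel(),
              (mag * (1 - frac)).ravel())
    np.add.at(hist.reshape(-1, cfg.n_bins).reshape(-1),
              flat_cell * cfg.n_bins + hi.ravel(),
              (mag * frac).ravel())
    return hist


def hog_feature_vector(img: np.ndarray, cfg: HOGConfig | None = None) -> np.ndarray:
    """Block-normalized HOG descriptor (length 36 on 64x64 at the defaults)."""
    cfg = cfg or HOGConfig()
    hist = cell_histograms(img, cfg)
    cells = hist.shape[0]
    b = cfg.block_cells
    if cells < b:
        raise ValueError(f"image has {cells} cells per side; block needs {b}")
    out = []
    for r in range(cells - b + 1):
        for c in range(cells - b + 1):
            block = hist[r : r + b, c : c + b].ravel()
            out.append(block / np.sqrt((block ** 2).sum() + cfg.eps ** 2))
    return np.concatenate(out)
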