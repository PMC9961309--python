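"""Gray-level co-occurrence matrices and the 13 Haralick texture features.

The GLCM M(i, j) counts ordered pixel pairs: level i at (x, y) and level j
at the offset fixed by distance d and direction theta, for the four
directions 0/45/90/135 degrees without symmetric double-counting.  The 13
classic Haralick summaries (angular second moment through the two
information measures of correlation) are computed per direction and
arithmetically averaged into the 13-vector x_GLCM.

Conventions (recorded because the literature varies):

* gray levels are quantized uniformly to ``n_levels`` bins (default 8);
* offsets in (row, col) terms: 0 -> (0, d), 45 -> (-d, d), 90 -> (-d, 0),
  135 -> (-d, -d);
* counts are normalized by the total number of counted pairs, so the
  normalized matrix p sums to 1;
* logarithms are natural; 0*log(0) is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging_io import validate_image8

ANGLES = (0, 45, 90, 135)

#: (row, col) pixel offset per direction at unit distance
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMConfig:
    distance: int = 3
    angles: tuple = ANGLES
    n_levels: int = 8
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.angles = tuple(self.angles)
        if self.distance < 1:
            raise ValueError("GLCM distance must be >= 1")
        if not 2 <= self.n_levels <= 256:
            raise ValueError("n_levels must be in [2, 256]")
        if any(a not in _OFFSETS for a in self.angles):
            raise ValueError(f"angles must be among {ANGLES}")


def quantize_levels(img: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniformly bin [0, 255] into levels 0..n_levels-1 (identity at 256)."""
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    arr = validate_image8(img)
    return (arr.astype(np.int64) * n_levels) // 256


def compute_glcm(levels: np.ndarray, d: int, theta: int, n_levels: int | None = None,
                 *, symmetric: bool = False) -> np.ndarray:
    """Integer co-occurrence counts M(i, j) at distance d, direction theta.

    Pairs whose offset pixel falls outside the image are skipped.  With
    ``symmetric`` each pair is counted in both (i, j) and (j, i).
    """
    levels = np.asarray(levels)
    if n_levels is None:
        n_levels = int(levels.max()) + 1
    dr, dc = _OFFSETS[theta]
    dr, dc = dr * d, dc * d
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"distance {d} at {theta} deg leaves no valid pixel pairs "
            f"in a {h}x{w} image"
        )
    i = levels[r0:r1, c0:c1].ravel()
    j = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    m = np.zeros((n_levels, n_levels), dtype=np.int64)
    np.add.at(m, (i, j), 1)
    if symmetric:
        m = m + m.T
    return m


def normalize_glcm(m: np.ndarray) -> np.ndarray:
    """Divide counts by the total number of counted pairs; sums to 1."""
    total = m.sum()
    if total == 0:
        raise ValueError("empty GLCM: no counted pairs")
    return m.astype(np.float64) / total


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln(p) with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


@dataclass
class GLCMProfile:
    """A normalized GLCM with its marginal and entropy bookkeeping."""

    p: np.ndarray
    px: np.ndarray = field(init=False)
    py: np.ndarray = field(init=False)
    p_xplusy: np.ndarray = field(init=False)
    p_xminusy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("normalized GLCM must sum to 1")
        self.p = p
        n = p.shape[0]
        self.px = p.sum(axis=1)
        self.py = p.sum(axis=0)
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        self.p_xplusy = np.bincount((i + j).ravel(), weights=p.ravel(),
                                    minlength=2 * n - 1)
        self.p_xminusy = np.bincount(np.abs(i - j).ravel(), weights=p.ravel(),
                                     minlength=n)

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


FEATURE_NAMES = [
    "angular_second_moment", "contrast", "correlation", "variance",
    "inverse_difference_moment", "sum_average", "sum_variance", "sum_entropy",
    "entropy", "difference_variance", "difference_entropy",
    "info_correlation_1", "info_correlation_2",
]


def haralick13(profile: GLCMProfile | np.ndarray) -> np.ndarray:
    """The 13 Haralick features F1..F13 of a normalized GLCM.

    Degenerate cases are pinned down: F3 is 0 when either marginal deviation
    vanishes, F12 is 0 when max(HX, HY) = 0 and F13's radicand is clamped at
    0 (a single-atom distribution then gives F13 = 0).
    """
    if not isinstance(profile, GLCMProfile):
        profile = GLCMProfile(np.asarray(profile))
    p = profile.p
    n = profile.n_levels
    idx = np.arange(n, dtype=np.float64)
    i, j = np.meshgrid(idx, idx, indexing="ij")

    mu_x = float((idx * profile.px).sum())
    mu_y = float((idx * profile.py).sum())
    sig_x = float(np.sqrt(((idx - mu_x) ** 2 * profile.px).sum()))
    sig_y = float(np.sqrt(((idx - mu_y) ** 2 * profile.py).sum()))

    f1 = float((p ** 2).sum())
    k = np.arange(n, dtype=np.float64)
    f2 = float((k ** 2 * profile.p_xminusy).sum())
    if sig_x > 0 and sig_y > 0:
        f3 = float(((i * j * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        f3 = 0.0
    # variance of the pooled gray-level distribution of paired pixels;
    # the pooled marginal keeps F4 symmetric in the pair order, so the
    # direction-averaged vector is invariant under 90-degree rotations
    m_pool = 0.5 * (profile.px + profile.py)
    mu = float((idx * m_pool).sum())
    f4 = float(((idx - mu) ** 2 * m_pool).sum())
    f5 = float((p / (1.0 + (i - j) ** 2)).sum())
    s = np.arange(2 * n - 1, dtype=np.float64)
    f6 = float((s * profile.p_xplusy).sum())
    f8 = float(-_xlogx(profile.p_xplusy).sum())
    f7 = float(((s - f8) ** 2 * profile.p_xplusy).sum())
    f9 = float(-_xlogx(p).sum())
    mu_d = float((k * profile.p_xminusy).sum())
    f10 = float(((k - mu_d) ** 2 * profile.p_xminusy).sum())
    f11 = float(-_xlogx(profile.p_xminusy).sum())

    hx = float(-_xlogx(profile.px).sum())
    hy = float(-_xlogx(profile.py).sum())
    hxy = f9
    pxpy = np.outer(profile.px, profile.py)
    log_pxpy = np.where(pxpy > 0, np.log(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-_xlogx(pxpy).sum())
    denom = max(hx, hy)
    f12 = (hxy - hxy1) / denom if denom > 0 else 0.0
    f13 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13])


def glcm_feature_vector(img: np.ndarray, cfg: GLCMConfig | None = None,
                        *, average_glcms: bool = False) -> np.ndarray:
    """Direction-averaged 13-vector x_GLCM for an image.

    By default the 13 features are computed per direction and averaged
    ("directions averaged features"); ``average_glcms`` instead averages the
    four co-occurrence matrices first and computes one feature set, the
    alternative reading of the fusion step.
    """
    cfg = cfg or GLCMConfig()
    levels = quantize_levels(img, cfg.n_levels)
    mats = [
        compute_glcm(levels, cfg.distance, a, cfg.n_levels, symmetric=cfg.symmetric)
        for a in cfg.angles
    ]
    if average_glcms:
        pooled = np.mean([normalize_glcm(m) for m in mats], axis=0)
        return haralick13(GLCMProfile(pooled))
    feats = [haralick13(GLCMProfile(normalize_glcm(m))) for m in mats]
    return np.mean(feats, axis=0)
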