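"""Hand-crafted radiomic texture descriptors: Haralick/GLCM, HOG, uniform LBP."""

from __future__ import annotations

import numpy as np

from .glcm import (
    ANGLES,
    FEATURE_NAMES,
    GLCMConfig,
    GLCMProfile,
    compute_glcm,
    glcm_feature_vector,
    haralick13,
    normalize_glcm,
    quantize_levels,
)
from .hog import HOGConfig, cell_histograms, hog_feature_vector, sobel_gradients
from .lbp import (
    LBPConfig,
    lbp_bin_count,
    lbp_code,
    lbp_code_image,
    lbp_feature_vector,
)


def radiomic_feature_vector(
    img: np.ndarray,
    glcm_cfg: GLCMConfig | None = None,
    hog_cfg: HOGConfig | None = None,
    lbp_cfg: LBPConfig | None = None,
) -> np.ndarray:
    """x_radiomic = [x_GLCM | x_HOG | x_LBP], 13 + 36 + 59 = 108 values."""
    return np.concatenate(
        [
            glcm_feature_vector(img, glcm_cfg),
            hog_feature_vector(img, hog_cfg),
            lbp_feature_vector(img, lbp_cfg),
        ]
    )


__all__ = [
    "ANGLES",
    "FEATURE_NAMES",
    "GLCMConfig",
    "GLCMProfile",
    "HOGConfig",
    "LBPConfig",
    "cell_histograms",
    "compute_glcm",
    "glcm_feature_vector",
    "haralick13",
    "hog_feature_vector",
    "lbp_bin_count",
    "lbp_code",
    "lbp_code_image",
    "lbp_feature_vector",
    "normalize_glcm",
    "quantize_levels",
    "radiomic_feature_vector",
    "sobel_gradients",
]
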