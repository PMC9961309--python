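"""The three radiomic texture descriptors on contrasting inputs.

Computes Haralick/GLCM, HOG and uniform-LBP features for a smooth blob
texture (phantom class 0) and an oriented grating (phantom class 1) and
prints the values that tell them apart.
"""

import numpy as np

from mgmtpmp.phantoms import PhantomSpec, generate_arrays
from mgmtpmp.radiomic import (
    FEATURE_NAMES,
    glcm_feature_vector,
    hog_feature_vector,
    lbp_feature_vector,
)

images, labels = generate_arrays(PhantomSpec(n_per_class=1, blank_fraction=0, seed=2))
smooth, grating = images[labels == 0][0], images[labels == 1][0]

for name, img in [("smooth field", smooth), ("oriented grating", grating)]:
    glcm = glcm_feature_vector(img)
    hog = hog_feature_vector(img)
    lbp = lbp_feature_vector(img)
    print(f"{name}:")
    print(f"  GLCM contrast (F2)    = {glcm[FEATURE_NAMES.index('contrast')]:.3f}")
    print(f"  GLCM correlation (F3) = {glcm[FEATURE_NAMES.index('correlation')]:.3f}")
    print(f"  HOG dominant bin      = {int(np.argmax(hog))} of {len(hog)}")
    print(f"  LBP non-uniform mass  = {lbp[-1]:.3f}")

# The long-correlation field shows low GLCM contrast and high correlation;
# the grating concentrates HOG energy in the bins aligned with its 30-degree
# orientation and its rough micro-texture lifts the LBP non-uniform bin.
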