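"""Collagen/background segmentation by a two-component Gaussian mixture.

Pixels are modelled as a mixture of a dim background and a bright collagen
component; a pixel is collagen when its posterior probability for the
higher-mean component is at least 0.5.
"""

from __future__ import annotations

import numpy as np
from sklearn.mixture import GaussianMixture

from .image import SHGImage


class DegenerateImageError(ValueError):
    """Raised when an image carries no intensity contrast to segment."""


_MAX_FIT_PIXELS = 60_000


def segment_collagen(image: SHGImage, seed: int = 0) -> np.ndarray:
    """Binary collagen mask from a 2-component Gaussian mixture fit.

    The mixture is fit on (a subsample of) the pixel intensities; the
    collagen class is the component with the higher mean and a pixel is
    assigned to it when its posterior is >= 0.5.

    Returns a uint8 array of 0/1 with the image's shape.
    """
    vals = image.intensities.ravel()
    if float(vals.var()) == 0.0:
        raise DegenerateImageError(
            "constant image: intensity variance is zero, nothing to segment"
        )
    rng = np.random.default_rng(seed)
    if vals.size > _MAX_FIT_PIXELS:
        fit_vals = rng.choice(vals, size=_MAX_FIT_PIXELS, replace=False)
    else:
        fit_vals = vals
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        random_state=int(rng.integers(2**31 - 1)),
        n_init=1,
        reg_covar=1e-6 * max(float(fit_vals.var()), 1e-12),
    )
    gm.fit(fit_vals[:, None])
    hi = int(np.argmax(gm.means_.ravel()))
    post = gm.predict_proba(vals[:, None])[:, hi]
    mask = (post >= 0.5).astype(np.uint8).reshape(image.shape)
    return mask
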