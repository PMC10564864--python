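"""Beer-Lambert stain rendering and color deconvolution for H-DAB slides.

Brightfield immunohistochemistry obeys, to a good approximation, the
Lambert-Beer law: each stain attenuates transmitted light exponentially in
its amount, with a characteristic absorbance (optical density) spectrum.
In base-10 optical density a pixel's RGB transmittance is

    rgb = 10 ** (-(concentrations @ M))

where the rows of ``M`` are the unit OD vectors of hematoxylin, DAB and a
residual channel.  The inverse (color deconvolution) recovers per-stain
"concentration" maps from an RGB image.  The standard published H-DAB
vectors shipped with scikit-image are used for ``M``.

Concentrations are dimensionless OD multiples of the unit stain vector;
0 means no stain, values around 0.5-1.0 are typical of a well-stained
section.
"""

from __future__ import annotations

import numpy as np
from skimage.color import hdx_from_rgb, rgb_from_hdx

#: Row-wise unit OD vectors: hematoxylin, DAB, residual.
STAIN_MATRIX = rgb_from_hdx
#: Inverse of :data:`STAIN_MATRIX`, used for deconvolution.
STAIN_MATRIX_INV = hdx_from_rgb

# Transmittance floor: a uint8 image cannot encode less than ~1/255 of
# incident light, so ODs are capped accordingly during deconvolution.
_MIN_TRANSMITTANCE = 1.0 / 512.0


def rgb_from_concentrations(concentrations: np.ndarray) -> np.ndarray:
    """Render float RGB in [0, 1] from an H×W×3 stain-concentration array.

    Channel order of the last axis is (hematoxylin, DAB, residual).
    Zero concentration everywhere renders pure white.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim != 3 or conc.shape[-1] != 3:
        raise ValueError("concentrations must be an H×W×3 array")
    od = conc @ STAIN_MATRIX
    return np.clip(10.0 ** (-od), 0.0, 1.0)


def concentrations_from_rgb(rgb: np.ndarray) -> np.ndarray:
    """Deconvolve an RGB image into H-DAB stain concentrations.

    Accepts uint8 (0-255) or float (0-1) input; returns an H×W×3 float
    array in the same concentration units used by
    :func:`rgb_from_concentrations`.
    """
    img = np.asarray(rgb)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("rgb must be an H×W×3 array")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    img = np.maximum(img.astype(float), _MIN_TRANSMITTANCE)
    od = -np.log10(img)
    return od @ STAIN_MATRIX_INV
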