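"""Retinal background estimation and foreground suppression.

The background ``Ibg`` is a large-window median per channel: robust to
lesions and vessels occupying up to roughly half of any window.  From it two
derived images are built: ``Ibg_bri`` (dark structures replaced by the
background — only bright structures survive relative to the background) and
``Ibg_dark`` (the mirror image).  A pixel counts as dark/bright when its
value-channel deviation from ``Ibg`` exceeds ``tau`` (default 0.03).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .core import BackgroundModel, FundusImage
from .preprocess import _nearest_fill


@dataclass
class BackgroundConfig:
    window_frac: float = 0.20   # median window side as a fraction of D
    tau: float = 0.03           # value-channel deviation defining dark/bright pixels
    max_kernel: int = 15        # largest median kernel actually run (downsampling above)


DEFAULT_CONFIG = BackgroundConfig()


def _value(rgb: np.ndarray) -> np.ndarray:
    """HSV value channel (max over RGB)."""
    return rgb.max(axis=2)


def estimate_background(img: FundusImage, config: BackgroundConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Median-filter background per channel (square window of side
    ``window_frac * D``).

    For large windows the median is computed on a proportionally downsampled
    grid and resized back, which preserves the large-scale background while
    keeping the kernel small.
    """
    win = max(3, int(round(config.window_frac * img.fov_diameter)))
    # the filter must not see the black outside-FOV region
    ext = _nearest_fill(img.rgb, img.fov_mask)
    factor = max(1, int(np.ceil(win / config.max_kernel)))
    if factor == 1:
        out = ndi.median_filter(ext, size=(win, win, 1), mode="nearest")
    else:
        h, w = ext.shape[:2]
        hs, ws = max(8, h // factor), max(8, w // factor)
        small = resize(ext, (hs, ws), order=1, anti_aliasing=True)
        k = max(3, int(round(win / factor)))
        med = ndi.median_filter(small, size=(k, k, 1), mode="nearest")
        out = resize(med, (h, w), order=1)
    return np.clip(out, 0.0, 1.0)


def suppress_dark(iprep: np.ndarray, ibg: np.ndarray, tau: float = DEFAULT_CONFIG.tau) -> np.ndarray:
    """Replace dark pixels (value below background by more than ``tau``) with
    the background, producing ``Ibg_bri``."""
    if iprep.shape != ibg.shape:
        raise ValueError("shape mismatch")
    dark = _value(iprep) < _value(ibg) - tau
    out = iprep.copy()
    out[dark] = ibg[dark]
    return out


def suppress_bright(iprep: np.ndarray, ibg: np.ndarray, tau: float = DEFAULT_CONFIG.tau) -> np.ndarray:
    """Replace bright pixels (value above background by more than ``tau``)
    with the background, producing ``Ibg_dark``."""
    if iprep.shape != ibg.shape:
        raise ValueError("shape mismatch")
    bright = _value(iprep) > _value(ibg) + tau
    out = iprep.copy()
    out[bright] = ibg[bright]
    return out


def compute_background_model(img: FundusImage, config: BackgroundConfig = DEFAULT_CONFIG) -> BackgroundModel:
    """Run the full stage: estimate ``Ibg`` and derive ``Ibg_dark``/``Ibg_bri``."""
    ibg = estimate_background(img, config)
    return BackgroundModel(
        ibg=ibg,
        ibg_dark=suppress_bright(img.rgb, ibg, config.tau),
        ibg_bri=suppress_dark(img.rgb, ibg, config.tau),
    )
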