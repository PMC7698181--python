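"""Appearance normalization of color fundus photographs.

Five sequential operations are applied to every input image: bright border
artifact removal, background extension, illumination and color equalization,
denoising, and contrast enhancement.  All spatial sizes are fractions of the
field-of-view diameter ``D`` so behaviour is resolution independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color, exposure, filters, measure
from scipy.ndimage import binary_fill_holes, distance_transform_edt

from .core import FundusImage


class FOVError(ValueError):
    """Raised when no plausible circular field of view can be found."""


@dataclass
class PreprocessConfig:
    annulus_frac: float = 0.015     # width of the rim annulus replaced near the FOV edge
    mean_window_frac: float = 0.25  # local-mean window for illumination equalization
    clahe_tile_frac: float = 0.125  # CLAHE tile side
    # clip limit kept gentle: stronger equalization mixes a background-hued
    # component into structure residuals, compressing their hues against the
    # candidate-range boundaries downstream
    clahe_clip: float = 0.005


DEFAULT_CONFIG = PreprocessConfig()


# ---------------------------------------------------------------------------
# FOV geometry
# ---------------------------------------------------------------------------

def estimate_fov(rgb: np.ndarray):
    """Locate the circular field of view and measure its diameter ``D``.

    The FOV is the largest bright connected region against the dark surround;
    ``D`` is twice the maximum of the Euclidean distance transform inside it
    (the diameter of the largest inscribed circle).

    Returns ``(fov_mask, fov_diameter)``; raises :class:`FOVError` when the
    image is entirely dark or entirely bright.
    """
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("raster must have at least 3 channels")
    if min(rgb.shape[:2]) < 64:
        raise ValueError("both image dimensions must be >= 64")
    lum = rgb[..., :3].mean(axis=2)
    spread = lum.max() - lum.min()
    if spread < 1e-3:
        raise FOVError("no FOV found: image has no brightness contrast")
    thr = max(0.05, 0.5 * float(filters.threshold_otsu(lum)))
    mask = lum > thr
    if not mask.any():
        raise FOVError("no FOV found: image entirely dark")
    if mask.mean() > 0.995:
        raise FOVError("no FOV found: image entirely bright")
    lab = measure.label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = binary_fill_holes(lab == counts.argmax())
    d = 2.0 * float(distance_transform_edt(mask).max())
    d = min(d, float(min(mask.shape)))
    if d <= 0:
        raise FOVError("no FOV found: degenerate region")
    return mask, d


def _nearest_fill(rgb: np.ndarray, source_mask: np.ndarray) -> np.ndarray:
    """Replace pixels outside ``source_mask`` with their nearest in-mask value."""
    if source_mask.all():
        return rgb.copy()
    _, (ir, ic) = distance_transform_edt(~source_mask, return_indices=True)
    return rgb[ir, ic]


# ---------------------------------------------------------------------------
# the five operations
# ---------------------------------------------------------------------------

def remove_border_artifacts(img: FundusImage, config: PreprocessConfig = DEFAULT_CONFIG) -> FundusImage:
    """Replace the bright rim just inside the FOV boundary with values
    propagated inward from the adjacent interior (nearest interior pixel)."""
    width = config.annulus_frac * img.fov_diameter
    edt = distance_transform_edt(img.fov_mask)
    annulus = img.fov_mask & (edt <= width)
    interior = img.fov_mask & ~annulus
    if not annulus.any() or not interior.any():
        return img.copy_with(img.rgb.copy(), "remove_border_artifacts")
    filled = _nearest_fill(img.rgb, interior)
    out = img.rgb.copy()
    out[annulus] = filled[annulus]
    return img.copy_with(out, "remove_border_artifacts")


def extend_background(img: FundusImage, config: PreprocessConfig = DEFAULT_CONFIG) -> FundusImage:
    """Fill the region outside the FOV with nearest in-FOV values so filters
    near the rim see no hard edge; in-FOV pixels are untouched."""
    out = _nearest_fill(img.rgb, img.fov_mask)
    return img.copy_with(out, "extend_background")


def equalize_illumination_color(img: FundusImage, config: PreprocessConfig = DEFAULT_CONFIG) -> FundusImage:
    """Per channel, subtract a large-scale local mean (square window of side
    ``mean_window_frac * D``) and re-center on the channel's global in-FOV
    mean.  Removes slow illumination gradients and color casts."""
    win = max(3, int(round(config.mean_window_frac * img.fov_diameter)) | 1)
    out = np.empty_like(img.rgb)
    for c in range(3):
        ch = img.rgb[..., c]
        local = ndi.uniform_filter(ch, size=win, mode="nearest")
        out[..., c] = ch - local + ch[img.fov_mask].mean()
    return img.copy_with(np.clip(out, 0.0, 1.0), "equalize_illumination_color")


def denoise(img: FundusImage, config: PreprocessConfig = DEFAULT_CONFIG) -> FundusImage:
    """3×3 median filter per channel; removes impulse noise, preserves edges."""
    out = ndi.median_filter(img.rgb, size=(3, 3, 1), mode="nearest")
    return img.copy_with(out, "denoise")


def enhance_contrast(img: FundusImage, config: PreprocessConfig = DEFAULT_CONFIG) -> FundusImage:
    """CLAHE on the value channel (tile side ``clahe_tile_frac * D``,
    clip limit ``clahe_clip``); hue and saturation preserved."""
    hsv = color.rgb2hsv(img.rgb)
    v = hsv[..., 2]
    if v.std() < 1e-6:
        return img.copy_with(img.rgb.copy(), "enhance_contrast")
    tile = max(8, int(round(config.clahe_tile_frac * img.fov_diameter)))
    hsv[..., 2] = exposure.equalize_adapthist(
        np.clip(v, 0, 1), kernel_size=tile, clip_limit=config.clahe_clip
    )
    out = np.clip(color.hsv2rgb(hsv), 0.0, 1.0)
    return img.copy_with(out, "enhance_contrast")


def preprocess(rgb: np.ndarray, config: PreprocessConfig = DEFAULT_CONFIG) -> FundusImage:
    """Full normalization chain producing ``Iprep``.

    Applies, in order: bright border artifact removal, background extension,
    illumination and color equalization, denoising, contrast enhancement;
    finally zeroes everything outside the FOV.
    """
    fov_mask, d = estimate_fov(rgb)
    img = FundusImage(np.clip(np.asarray(rgb, dtype=np.float64)[..., :3], 0, 1),
                      fov_mask, d, ["ingest"])
    img = remove_border_artifacts(img, config)
    img = extend_background(img, config)
    img = equalize_illumination_color(img, config)
    img = denoise(img, config)
    img = enhance_contrast(img, config)
    out = img.rgb.copy()
    out[~img.fov_mask] = 0.0
    img = img.copy_with(out, "mask_fov")
    img.validate()
    return img
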