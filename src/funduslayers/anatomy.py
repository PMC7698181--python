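"""Vessel segmentation and optic-disc / fovea localization.

This stage is a pluggable interface: downstream code depends only on the
contract (a binary vessel mask, the OD center with fixed radius
``ROD = D / 12``, and the fovea center).  The baseline implementations here
use a multiscale Sato vesselness with hysteresis thresholding, a
brightness × vessel-density saliency product for the OD, and a darkest-point
search in an annulus around the OD for the fovea.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.ndimage import distance_transform_edt
from skimage import filters, measure, morphology
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

from .core import FundusImage, RetinalAnatomy
from .preprocess import _nearest_fill


@dataclass
class AnatomyConfig:
    vessel_scales_frac: tuple = (0.002, 0.004, 0.008)  # vesselness sigmas / D
    min_sigma: float = 1.0           # floor so scales stay meaningful at low resolution
    high_percentile: float = 99.0    # hysteresis: high = 0.5 * this percentile of response
    high_factor: float = 0.5
    min_object_frac: float = 0.0005  # small-object removal, fraction of D^2
    round_area_frac: float = 0.002   # roundish components below this D^2 fraction are
    round_ecc: float = 0.95          # not vessels (lesion-sized blobs)
    vessel_dilate: int = 1           # final dilation so the mask spans full vessel width
    od_smooth_frac: float = 0.08     # saliency smoothing window / D
    fovea_annulus: tuple = (1.5, 3.5)  # search radii in units of ROD
    fovea_cone_deg: float = 60.0     # half-opening of the search cone toward the macula
    fovea_smooth_frac: float = 0.02
    fovea_min_depth: float = 0.01    # minimum contrast for a "clear" fovea minimum


DEFAULT_CONFIG = AnatomyConfig()


def vesselness_response(inv_green: np.ndarray, sigmas) -> np.ndarray:
    """Multiscale Hessian line measure ``sigma^2 * ((-lambda2) - |lambda1|)``.

    For a bright ridge the cross-ridge eigenvalue ``lambda2`` is strongly
    negative while the along-ridge one is near zero; for a rotationally
    symmetric blob both eigenvalues are similar and the measure vanishes —
    so round lesions are suppressed before any thresholding.
    """
    best = np.zeros_like(inv_green)
    for s in sigmas:
        H = hessian_matrix(inv_green, sigma=s, order="rc",
                           use_gaussian_derivatives=False)
        l1, l2 = hessian_matrix_eigvals(H)         # l1 >= l2
        v = (s ** 2) * np.maximum(0.0, -l2 - np.abs(l1))
        np.maximum(best, v, out=best)
    return best


def segment_vessels(img: FundusImage, config: AnatomyConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Baseline vessel mask: multiscale Hessian line measure on the inverted
    green channel, hysteresis-thresholded.

    A per-component roundness filter (small, near-circular components are
    dropped) is a second line of defense keeping lesion-sized round blobs —
    microaneurysms — out of the vessel mask; a final 1-px dilation makes the
    mask span the full vessel width.
    """
    d = img.fov_diameter
    green = _nearest_fill(img.rgb, img.fov_mask)[..., 1]
    inv = 1.0 - green
    sigmas = sorted({max(config.min_sigma, f * d) for f in config.vessel_scales_frac})
    resp = vesselness_response(inv, sigmas)
    resp[~img.fov_mask] = 0.0
    pos = resp[img.fov_mask]
    if pos.size == 0 or pos.max() <= 0:
        return np.zeros(img.shape, dtype=bool)
    high = config.high_factor * np.percentile(pos, config.high_percentile)
    if high <= 0:
        return np.zeros(img.shape, dtype=bool)
    mask = filters.apply_hysteresis_threshold(resp, high / 2.0, high)
    mask &= img.fov_mask
    min_px = max(1, int(round(config.min_object_frac * d * d)))
    round_px = config.round_area_frac * d * d
    lab = measure.label(mask, connectivity=2)
    for rp in measure.regionprops(lab):
        drop = rp.area < min_px or (rp.area < round_px
                                    and rp.eccentricity < config.round_ecc)
        if drop:
            mask[lab == rp.label] = False
    if config.vessel_dilate > 0:
        # hysteresis tracks the ridge core; pad to the full vessel width
        mask = morphology.dilation(mask, morphology.disk(config.vessel_dilate))
        mask &= img.fov_mask
    return mask


def locate_od(img: FundusImage, mvess: np.ndarray, config: AnatomyConfig = DEFAULT_CONFIG):
    """Optic-disc center as the argmax of a brightness × vessel-density
    saliency product; the radius is always ``D / 12``.

    Brightness saliency combines a vessel-filling grayscale closing (the
    disc is crossed by dark vessels) with a center-surround response tuned
    to disc-sized blobs; the vessel-density map rewards peaks the
    vasculature converges on.  The outermost rim band (width ``0.1 D``) is
    excluded from the search: with a 45–50° macula-centered field of view
    the disc never touches the FOV edge.
    """
    d = img.fov_diameter
    rod = d / 12.0
    sigma = max(1.0, config.od_smooth_frac * d / 2.0)
    value = img.rgb.max(axis=2)
    closed = morphology.closing(value, morphology.disk(max(2, int(round(0.04 * d)))))
    smooth = ndi.gaussian_filter(closed, sigma)
    center_surround = smooth - ndi.gaussian_filter(closed, 4.0 * sigma)
    dens = ndi.gaussian_filter(mvess.astype(np.float64), 2.0 * sigma)
    search = distance_transform_edt(img.fov_mask) > 0.1 * d
    if not search.any():
        search = img.fov_mask

    def _norm(a):
        v = a[search]
        lo, hi = v.min(), v.max()
        return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)

    saliency = (_norm(smooth) * _norm(center_surround)
                * (0.5 + 0.5 * _norm(dens)))
    saliency[~search] = -1.0
    r, c = np.unravel_index(int(saliency.argmax()), saliency.shape)
    if not img.fov_mask[r, c]:
        raise ValueError("optic-disc saliency peak outside the field of view")
    return (float(r), float(c)), rod


def locate_fovea(img: FundusImage, mvess: np.ndarray, od_center, config: AnatomyConfig = DEFAULT_CONFIG):
    """Fovea center: darkest smoothed value-channel point in the vessel-free
    annulus of radii ``[1.5, 3.5] * ROD`` around the OD, restricted to a cone
    toward the FOV center (the macula lies temporal to the disc).

    Falls back to the point at ``2.5 * ROD`` from the OD toward the FOV
    center when no clear minimum exists; returns ``(center, fallback_flag)``.
    """
    d = img.fov_diameter
    rod = d / 12.0
    rows, cols = np.indices(img.shape)
    dist = np.hypot(rows - od_center[0], cols - od_center[1])
    lo, hi = config.fovea_annulus
    annulus = img.fov_mask & (dist >= lo * rod) & (dist <= hi * rod)

    h, w = img.shape
    to_center = np.array([h / 2.0 - od_center[0], w / 2.0 - od_center[1]])
    nrm = np.linalg.norm(to_center)
    to_center = to_center / nrm if nrm > 0 else np.array([0.0, 1.0])
    vr, vc = rows - od_center[0], cols - od_center[1]
    cosang = (vr * to_center[0] + vc * to_center[1]) / (dist + 1e-12)
    cone = cosang >= np.cos(np.deg2rad(config.fovea_cone_deg))
    vfree = annulus & cone & ~morphology.dilation(mvess, morphology.disk(2))

    fallback = (float(od_center[0] + 2.5 * rod * to_center[0]),
                float(od_center[1] + 2.5 * rod * to_center[1]))

    if not vfree.any():
        return fallback, True
    v = ndi.gaussian_filter(img.rgb.max(axis=2), max(1.0, config.fovea_smooth_frac * d))
    vals = np.where(vfree, v, np.inf)
    r, c = np.unravel_index(int(vals.argmin()), vals.shape)
    depth = v[vfree].mean() - v[r, c]
    if depth < config.fovea_min_depth:
        return fallback, True
    return (float(r), float(c)), False


def detect_anatomy(img: FundusImage, config: AnatomyConfig = DEFAULT_CONFIG) -> RetinalAnatomy:
    """Run the full stage and bundle the results."""
    mvess = segment_vessels(img, config)
    od_center, rod = locate_od(img, mvess, config)
    fovea, flag = locate_fovea(img, mvess, od_center, config)
    return RetinalAnatomy(
        vessel_mask=mvess, od_center=od_center, od_radius=rod,
        fovea_center=fovea, fovea_fallback=flag,
    )
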