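"""Dark/bright residual images and HSV-defined layer separation.

This is the heart of the method: the preprocessed image is split into a dark
residual ``Idark`` (everything darker than the background, colored by the
per-channel magnitude of the deviation) and a bright residual ``Ibri``; each
residual is then separated into layers by fixed inclusive HSV ranges —
choroidal/tigroid texture, reflective streaks along major vessels, and the
red-lesion / exudate candidate layers whose non-black pixels form the
candidate masks.

The printed hue intervals for the choroidal layers wrap past 1.0
(``[0.75, 0.1]`` means ``[0.75, 1] ∪ [0, 0.1]``): reds straddle hue zero.
When ranges overlap, the confounder layers (choroidal, reflective) take
precedence — their pixels are removed from the candidate layers before
binarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color, morphology

from .core import BackgroundModel, FundusImage, HSVRange, LayerStack, RetinalAnatomy


@dataclass(frozen=True)
class DecompositionRanges:
    """The five HSV boxes used for layer separation (inclusive bounds)."""

    rl_chor: HSVRange = HSVRange(0.75, 0.10, 0.20, 1.0, 0.05, 1.0)
    rl_cand: HSVRange = HSVRange(0.10, 0.45, 0.10, 1.0, 0.20, 1.0)
    ex_chor: HSVRange = HSVRange(0.75, 0.15, 0.00, 1.0, 0.00, 1.0)
    ex_reflective: HSVRange = HSVRange(0.25, 0.85, 0.00, 1.0, 0.00, 1.0)
    ex_cand: HSVRange = HSVRange(0.15, 0.45, 0.10, 1.0, 0.10, 1.0)


DEFAULT_RANGES = DecompositionRanges()


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

def dark_residual(ibg_dark: np.ndarray, ibg: np.ndarray) -> np.ndarray:
    """Complemented subtraction ``Idark = clip(Ibg − Ibg_dark, 0, 1)``.

    Dark structures appear colored by the per-channel magnitude of their
    deviation from the background; zero-difference pixels stay black.
    """
    if ibg_dark.shape != ibg.shape:
        raise ValueError("shape mismatch")
    return np.clip(ibg - ibg_dark, 0.0, 1.0)


def bright_residual(ibg_bri: np.ndarray, ibg: np.ndarray) -> np.ndarray:
    """``Ibri = clip(Ibg_bri − Ibg, 0, 1)``; zero-difference pixels stay black."""
    if ibg_bri.shape != ibg.shape:
        raise ValueError("shape mismatch")
    return np.clip(ibg_bri - ibg, 0.0, 1.0)


def mask_vessels(idark: np.ndarray, mvess: np.ndarray) -> np.ndarray:
    """Set vessel pixels black, producing ``Idark2``."""
    if mvess.shape != idark.shape[:2]:
        raise ValueError("shape mismatch")
    out = idark.copy()
    out[mvess] = 0.0
    return out


# ---------------------------------------------------------------------------
# HSV layer machinery
# ---------------------------------------------------------------------------

def hsv_in_range(raster: np.ndarray, rng: HSVRange) -> np.ndarray:
    """Binary mask of pixels whose HSV triple lies in ``rng``.

    Black pixels (all channels exactly 0) are never selected — on a residual
    image black means "no structure", not a color.
    """
    hsv = color.rgb2hsv(raster)
    nonblack = raster.max(axis=2) > 0
    return rng.contains(hsv[..., 0], hsv[..., 1], hsv[..., 2]) & nonblack


def extract_layer(raster: np.ndarray, rng: HSVRange) -> np.ndarray:
    """Keep raster values at in-range pixels, black elsewhere."""
    return raster * hsv_in_range(raster, rng)[..., None]


def _apply(raster: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return raster * mask[..., None]


# ---------------------------------------------------------------------------
# dark-side decomposition (red-lesion candidates)
# ---------------------------------------------------------------------------

def decompose_dark(
    iprep: FundusImage,
    bg: BackgroundModel,
    anat: RetinalAnatomy,
    ranges: DecompositionRanges = DEFAULT_RANGES,
    precedence: bool = True,
):
    """Dark residual → vessel masking → choroidal / red-lesion layers.

    Returns ``(idark, idark2, lchor_dark, lrl_cand, mrl_cand)``.  With
    ``precedence`` on (default) choroidal pixels are removed from the
    candidate layer before binarization.
    """
    idark = dark_residual(bg.ibg_dark, bg.ibg)
    idark[~iprep.fov_mask] = 0.0
    idark2 = mask_vessels(idark, anat.vessel_mask)
    m_chor = hsv_in_range(idark2, ranges.rl_chor)
    m_cand = hsv_in_range(idark2, ranges.rl_cand)
    if precedence:
        m_cand &= ~m_chor
    lchor_dark = _apply(idark2, m_chor)
    lrl_cand = _apply(idark2, m_cand)
    return idark, idark2, lchor_dark, lrl_cand, m_cand


# ---------------------------------------------------------------------------
# bright-side decomposition (exudate candidates)
# ---------------------------------------------------------------------------

def reflective_layer(
    ibri: np.ndarray,
    mvess: np.ndarray,
    ranges: DecompositionRanges,
    fov_diameter: float,
    od_radius: float,
):
    """Reflective (nerve-fiber-layer) features: greenish-bluish residual pixels
    restricted to a band around the major vessels.

    ``Ibm1`` is the reflective-range layer of ``Ibri``; ``Ibm2`` is the band
    mask — the vessel mask opened with a disk of radius ``ROD/10`` (removes
    thin vessels) then dilated with a disk of radius ``D/60``; ``Lbm`` is
    their product.
    """
    r_open = max(1, int(round(od_radius / 10.0)))
    r_dil = max(1, int(round(fov_diameter / 60.0)))
    ibm1 = extract_layer(ibri, ranges.ex_reflective)
    wide = morphology.opening(mvess, footprint=morphology.disk(r_open))
    ibm2 = morphology.dilation(wide, footprint=morphology.disk(r_dil))
    lbm = _apply(ibm1, ibm2)
    return ibm1, ibm2, lbm


def decompose_bright(
    iprep: FundusImage,
    bg: BackgroundModel,
    anat: RetinalAnatomy,
    ranges: DecompositionRanges = DEFAULT_RANGES,
    precedence: bool = True,
):
    """Bright residual → choroidal / reflective / exudate layers.

    Returns ``(ibri, lchor_bri, lbm, lex_cand, mex_cand)``.  Choroidal and
    reflective pixels are removed from the candidate layer before
    binarization (precedence), and pixels inside the OD circle are excluded
    from ``mex_cand``.
    """
    ibri = bright_residual(bg.ibg_bri, bg.ibg)
    ibri[~iprep.fov_mask] = 0.0
    m_chor = hsv_in_range(ibri, ranges.ex_chor)
    _, _, lbm = reflective_layer(ibri, anat.vessel_mask, ranges,
                                 iprep.fov_diameter, anat.od_radius)
    m_bm = lbm.max(axis=2) > 0
    m_cand = hsv_in_range(ibri, ranges.ex_cand)
    if precedence:
        m_cand &= ~m_chor & ~m_bm
    rows, cols = np.indices(iprep.shape)
    od_circle = np.hypot(rows - anat.od_center[0], cols - anat.od_center[1]) <= anat.od_radius
    m_cand &= ~od_circle
    lchor_bri = _apply(ibri, m_chor)
    lex_cand = _apply(ibri, m_cand)
    return ibri, lchor_bri, lbm, lex_cand, m_cand


def decompose(
    iprep: FundusImage,
    bg: BackgroundModel,
    anat: RetinalAnatomy,
    ranges: DecompositionRanges = DEFAULT_RANGES,
    precedence: bool = True,
) -> LayerStack:
    """Run both decompositions and bundle every layer into a stack."""
    idark, idark2, lchor_dark, lrl_cand, mrl = decompose_dark(iprep, bg, anat, ranges, precedence)
    ibri, lchor_bri, lbm, lex_cand, mex = decompose_bright(iprep, bg, anat, ranges, precedence)
    return LayerStack(
        idark=idark, idark2=idark2, lchor_dark=lchor_dark,
        lrl_cand=lrl_cand, mrl_cand=mrl,
        ibri=ibri, lchor_bri=lchor_bri, lbm=lbm,
        lex_cand=lex_cand, mex_cand=mex,
    )
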