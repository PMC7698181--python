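"""Core data model shared by every stage of the lesion-detection pipeline.

Conventions
-----------
* Coordinates are ``(row, col)``, 0-based, origin at the top-left corner.
* All rasters are ``float64`` with channel values in ``[0, 1]``; binary masks
  are boolean arrays of the same height/width.
* Every size used by the pipeline is expressed as a fraction of the field-of-view
  diameter ``D`` (pixels), so the method transfers across image resolutions.
* Connected components are 8-connected everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import imageio.v3 as iio


# ---------------------------------------------------------------------------
# carriers
# ---------------------------------------------------------------------------

@dataclass
class FundusImage:
    """A color fundus photograph with its circular field of view.

    Attributes
    ----------
    rgb : (H, W, 3) float array
        Channel values in [0, 1]; zero outside ``fov_mask`` once preprocessed.
    fov_mask : (H, W) bool array
        True inside the circular field of view.
    fov_diameter : float
        Diameter ``D`` in pixels of the largest circle inscribed in the FOV.
    history : list of str
        Names of the processing stages applied so far.
    """

    rgb: np.ndarray
    fov_mask: np.ndarray
    fov_diameter: float
    history: list = field(default_factory=list)

    def validate(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H×W×3")
        if self.fov_mask.shape != self.rgb.shape[:2]:
            raise ValueError("fov_mask shape mismatch")
        if not (self.fov_diameter > 0):
            raise ValueError("fov_diameter must be positive")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("rgb values must lie in [0, 1]")

    def copy_with(self, rgb: np.ndarray, stage: Optional[str] = None) -> "FundusImage":
        hist = list(self.history) + ([stage] if stage else [])
        return FundusImage(rgb, self.fov_mask, self.fov_diameter, hist)

    @property
    def shape(self):
        return self.rgb.shape[:2]

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(
            path,
            rgb=self.rgb,
            fov_mask=self.fov_mask,
            fov_diameter=np.float64(self.fov_diameter),
            history=np.array(json.dumps(self.history)),
        )

    @classmethod
    def load(cls, path) -> "FundusImage":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                rgb=z["rgb"],
                fov_mask=z["fov_mask"].astype(bool),
                fov_diameter=float(z["fov_diameter"]),
                history=json.loads(str(z["history"])),
            )


@dataclass
class RetinalAnatomy:
    """Vessel mask and optic-disc / fovea geometry.

    The optic disc is modeled as a circle of radius ``ROD = D / 12`` pixels.
    """

    vessel_mask: np.ndarray
    od_center: tuple
    od_radius: float
    fovea_center: tuple
    fovea_fallback: bool = False

    def to_json_dict(self) -> dict:
        return {
            "od_center": [float(v) for v in self.od_center],
            "od_radius": float(self.od_radius),
            "fovea_center": [float(v) for v in self.fovea_center],
            "fovea_fallback": bool(self.fovea_fallback),
            "coordinate_order": "row,col",
        }


@dataclass
class BackgroundModel:
    """Smooth background estimate and the two structure-suppressed images.

    ``ibg_bri`` equals the preprocessed image wherever no dark structure was
    present and the background fill at dark-structure pixels; ``ibg_dark`` is
    the mirror image (bright structures replaced by background).
    """

    ibg: np.ndarray
    ibg_dark: np.ndarray
    ibg_bri: np.ndarray


@dataclass(frozen=True)
class HSVRange:
    """Inclusive HSV box; the hue interval wraps past 1.0 when ``h_lo > h_hi``.

    A wrapping hue interval ``[h_lo, h_hi]`` with ``h_lo > h_hi`` denotes
    ``[h_lo, 1] ∪ [0, h_hi]`` — required because reds straddle hue 0.
    """

    h_lo: float
    h_hi: float
    s_lo: float
    s_hi: float
    v_lo: float
    v_hi: float

    def __post_init__(self):
        for v in (self.h_lo, self.h_hi, self.s_lo, self.s_hi, self.v_lo, self.v_hi):
            if not 0.0 <= v <= 1.0:
                raise ValueError("HSV bounds must lie in [0, 1]")
        if self.s_lo > self.s_hi:
            raise ValueError("s_lo must not exceed s_hi")
        if self.v_lo > self.v_hi:
            raise ValueError("v_lo must not exceed v_hi")

    @property
    def hue_wraps(self) -> bool:
        return self.h_lo > self.h_hi

    def contains_hue(self, h):
        h = np.asarray(h)
        if self.hue_wraps:
            return (h >= self.h_lo) | (h <= self.h_hi)
        return (h >= self.h_lo) & (h <= self.h_hi)

    def contains(self, h, s, v):
        s = np.asarray(s)
        v = np.asarray(v)
        return (
            self.contains_hue(h)
            & (s >= self.s_lo) & (s <= self.s_hi)
            & (v >= self.v_lo) & (v <= self.v_hi)
        )

    def shifted(self, dh: float = 0.0, ds: float = 0.0, dv: float = 0.0) -> "HSVRange":
        """Return a copy with every bound shifted (clipped to [0,1])."""
        c = lambda x: float(np.clip(x, 0.0, 1.0))
        return HSVRange(
            c(self.h_lo + dh), c(self.h_hi + dh),
            c(self.s_lo + ds), c(self.s_hi + ds),
            c(self.v_lo + dv), c(self.v_hi + dv),
        )


@dataclass
class LayerStack:
    """Products of the dark/bright decomposition.

    Dark side: ``idark`` (colored dark residual), ``idark2`` (vessels removed),
    ``lchor_dark`` (choroidal/tigroid layer), ``lrl_cand`` (red-lesion candidate
    layer) and its binary mask ``mrl_cand``.  Bright side: ``ibri`` (bright
    residual), ``lchor_bri``, ``lbm`` (reflective features along major
    vessels), ``lex_cand`` and ``mex_cand``.
    """

    idark: np.ndarray = None
    idark2: np.ndarray = None
    lchor_dark: np.ndarray = None
    lrl_cand: np.ndarray = None
    mrl_cand: np.ndarray = None
    ibri: np.ndarray = None
    lchor_bri: np.ndarray = None
    lbm: np.ndarray = None
    lex_cand: np.ndarray = None
    mex_cand: np.ndarray = None

    LAYER_NAMES = (
        "idark", "idark2", "lchor_dark", "lrl_cand", "mrl_cand",
        "ibri", "lchor_bri", "lbm", "lex_cand", "mex_cand",
    )

    def save(self, path) -> None:
        np.savez_compressed(path, **{
            n: getattr(self, n) for n in self.LAYER_NAMES if getattr(self, n) is not None
        })

    @classmethod
    def load(cls, path) -> "LayerStack":
        with np.load(path, allow_pickle=False) as z:
            kw = {n: z[n] for n in cls.LAYER_NAMES if n in z}
        for n in ("mrl_cand", "mex_cand"):
            if n in kw:
                kw[n] = kw[n].astype(bool)
        return cls(**kw)


@dataclass
class CandidateRegion:
    """One 8-connected component of a candidate mask.

    ``pixels`` is an (N, 2) integer array of (row, col) coordinates;
    ``bbox`` is ``(min_row, min_col, height, width)`` and tightly encloses the
    pixels; ``features`` (once extracted) has exactly 100 finite entries,
    indexed 1..100 in the feature catalog's order.
    """

    label: int
    pixels: np.ndarray
    bbox: tuple
    features: Optional[np.ndarray] = None

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))

    def to_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class LesionModel:
    """Trained classifier bundle for one lesion kind ('rl' or 'ex').

    Carries the ordered selected feature indices (1-based catalog indices),
    per-feature normalization constants, the 3-layer perceptron weights
    (tanh hidden layer, logistic output) and the decision threshold.
    """

    lesion_kind: str
    selected_indices: np.ndarray
    feat_mean: np.ndarray
    feat_std: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    n_hidden: int
    reg_lambda: float
    threshold: float = 0.5

    def validate(self) -> None:
        k = len(self.selected_indices)
        if self.lesion_kind not in ("rl", "ex"):
            raise ValueError("lesion_kind must be 'rl' or 'ex'")
        if np.any(self.feat_std <= 0):
            raise ValueError("feat_std entries must be positive")
        if self.W1.shape != (self.n_hidden, k) or self.W2.shape != (1, self.n_hidden):
            raise ValueError("weight shapes inconsistent with n_selected/n_hidden")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    def save(self, path) -> None:
        header = json.dumps({
            "lesion_kind": self.lesion_kind,
            "n_hidden": int(self.n_hidden),
            "reg_lambda": float(self.reg_lambda),
            "threshold": float(self.threshold),
            "selected_indices": [int(i) for i in self.selected_indices],
        })
        np.savez_compressed(
            path, header=np.array(header),
            feat_mean=self.feat_mean, feat_std=self.feat_std,
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
        )

    @classmethod
    def load(cls, path) -> "LesionModel":
        with np.load(path, allow_pickle=False) as z:
            h = json.loads(str(z["header"]))
            return cls(
                lesion_kind=h["lesion_kind"],
                selected_indices=np.asarray(h["selected_indices"], dtype=int),
                feat_mean=z["feat_mean"], feat_std=z["feat_std"],
                W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
                n_hidden=h["n_hidden"], reg_lambda=h["reg_lambda"],
                threshold=h["threshold"],
            )


@dataclass
class EvaluationReport:
    """Lesion-level (SEp/PPVp) and image-level (SEi/SPi/ACCi) results.

    Rates are percentages; a rate whose denominator is empty is ``None``.
    An image counts as pathological when at least ``min_pixels`` lesion
    pixels are predicted (default 30).
    """

    n_gt_lesions: int = 0
    n_detected_lesions: int = 0
    n_candidate_regions: int = 0
    n_true_positive_regions: int = 0
    se_p: Optional[float] = None
    ppv_p: Optional[float] = None
    n_images: int = 0
    tp_images: int = 0
    tn_images: int = 0
    fp_images: int = 0
    fn_images: int = 0
    se_i: Optional[float] = None
    sp_i: Optional[float] = None
    acc_i: Optional[float] = None
    min_pixels: int = 30

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float, indent=2)


# ---------------------------------------------------------------------------
# raster I/O helpers
# ---------------------------------------------------------------------------

def read_rgb(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as float64 RGB in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    return arr


def write_rgb(path, rgb: np.ndarray) -> None:
    """Write a [0,1] float raster as an 8-bit PNG."""
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a 0/255 PNG."""
    iio.imwrite(path, np.where(mask, 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)
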