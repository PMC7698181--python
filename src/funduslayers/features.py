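"""The 100-feature description of a candidate region.

Features (1-based catalog indices):

* 1–11    shape: area, bbox width/height, convex-hull area, eccentricity,
          hole count, extent, major/minor axis length, perimeter, solidity.
* 12–23   mean/median/std/entropy of region pixels in the RGB channels of Iprep.
* 24–35   the same statistics in the HSV channels of the candidate layer
          (Lrl_cand for red lesions, Lex_cand for exudates).
* 36–95   the same statistics over all pixels of a circle of radius ROD
          centered on the region, in the HSV channels of Lrl_cand (36–47),
          Lchor_dark (48–59), Lchor_bri (60–71), Lex_cand (72–83), Lbm (84–95).
          Black pixels are included: on a sparse layer the fraction of
          non-black mass near the candidate is itself the signal.
* 96      mean of the V channel of Lbm over the whole FOV.
* 97      mean Prewitt gradient magnitude (value channel of Iprep) over the
          region's boundary pixels — exudates have sharp edges.
* 98      mean over region pixels of the maximum multiscale line-operator
          response (inverted green channel) — separates elongated vessel
          fragments from round lesions.
* 99–100  centroid distance to the OD center and fovea center, in units of D.

Entropy is Shannon entropy in bits over a 64-bin histogram of [0, 1] values.
The published selected subsets (24 features for red lesions, 34 for
exudates) ship as :data:`RL_SELECTED` and :data:`EX_SELECTED`.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage import color

from .core import CandidateRegion, FundusImage, LayerStack, RetinalAnatomy

N_FEATURES = 100

#: Catalog indices selected for red-lesion classification (24 features).
RL_SELECTED = (5, 11, 13, 18, 19, 22, 23, 24, 26, 28, 29, 32, 35, 44, 59,
               63, 64, 65, 66, 90, 96, 97, 98, 100)

#: Catalog indices selected for exudate classification (34 features).
EX_SELECTED = (5, 7, 17, 18, 19, 20, 21, 22, 23, 26, 27, 29, 30, 32, 34, 35,
               42, 57, 62, 64, 65, 73, 74, 78, 79, 80, 83, 91, 93, 96, 97,
               98, 99, 100)

ENTROPY_BINS = 64
LINE_N_ORIENTATIONS = 12


def _stat_block_names(prefix, channels):
    names = []
    for stat in ("mean", "median", "std", "entropy"):
        names += [f"{prefix}_{stat}_{ch}" for ch in channels]
    return names


FEATURE_NAMES = (
    ["area", "bbox_width", "bbox_height", "convex_area", "eccentricity",
     "n_holes", "extent", "major_axis_length", "minor_axis_length",
     "perimeter", "solidity"]
    + _stat_block_names("region_iprep", "rgb")
    + _stat_block_names("region_cand_layer", "hsv")
    + _stat_block_names("circle_lrl_cand", "hsv")
    + _stat_block_names("circle_lchor_dark", "hsv")
    + _stat_block_names("circle_lchor_bri", "hsv")
    + _stat_block_names("circle_lex_cand", "hsv")
    + _stat_block_names("circle_lbm", "hsv")
    + ["lbm_v_mean_fov", "boundary_prewitt_mean", "line_operator_mean",
       "dist_to_od", "dist_to_fovea"]
)
assert len(FEATURE_NAMES) == N_FEATURES


def catalog_json() -> str:
    """Export the feature catalog (index, name) as JSON for documentation."""
    return json.dumps(
        [{"index": i + 1, "name": n} for i, n in enumerate(FEATURE_NAMES)], indent=2
    )


# ---------------------------------------------------------------------------
# shape features (1-11)
# ---------------------------------------------------------------------------

def _convex_area(pixels: np.ndarray) -> float:
    """Number of pixels whose centers lie inside the convex hull of the
    region's pixel centers (so convex shapes get solidity exactly 1)."""
    pts = pixels.astype(np.float64)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return float(len(pixels))  # collinear region: hull degenerates to the pixels
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    a, b = hull.equations[:, :2], hull.equations[:, 2]
    inside = (grid @ a.T + b <= 1e-9).all(axis=1)
    return float(inside.sum())


def _region_patch(region: CandidateRegion):
    r0, c0, h, w = region.bbox
    patch = np.zeros((h, w), dtype=bool)
    patch[region.pixels[:, 0] - r0, region.pixels[:, 1] - c0] = True
    return patch


def _count_holes(patch: np.ndarray) -> int:
    """8-connected-foreground holes = enclosed 4-connected background parts."""
    padded = np.pad(~patch, 1, constant_values=True)
    lab, n = ndi.label(padded, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return int(n - 1)


def _perimeter(patch: np.ndarray) -> float:
    """Crack-boundary polygon length: count of exposed unit pixel edges."""
    area = patch.sum()
    horiz = (patch[:, :-1] & patch[:, 1:]).sum()
    vert = (patch[:-1, :] & patch[1:, :]).sum()
    return float(4 * area - 2 * (horiz + vert))


def _ellipse_params(pixels: np.ndarray):
    """Eccentricity and axis lengths of the same-second-moments ellipse."""
    pts = pixels.astype(np.float64)
    mu = pts.mean(axis=0)
    d = pts - mu
    mu20 = (d[:, 0] ** 2).mean()
    mu02 = (d[:, 1] ** 2).mean()
    mu11 = (d[:, 0] * d[:, 1]).mean()
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11 ** 2)
    l1 = (mu20 + mu02) / 2.0 + common
    l2 = (mu20 + mu02) / 2.0 - common
    l2 = max(l2, 0.0)
    major = 4.0 * np.sqrt(l1)
    minor = 4.0 * np.sqrt(l2)
    ecc = np.sqrt(1.0 - l2 / l1) if l1 > 0 else 1.0
    return float(ecc), float(major), float(minor)


def shape_features(region: CandidateRegion) -> np.ndarray:
    """Features 1–11."""
    if region.area < 2:
        raise ValueError("region must have at least 2 pixels")
    patch = _region_patch(region)
    h, w = patch.shape
    area = float(region.area)
    hull_area = _convex_area(region.pixels)
    ecc, major, minor = _ellipse_params(region.pixels)
    if minor == 0.0:  # degenerate 1-D region
        ecc = 1.0
        hull_area = area
    return np.array([
        area,
        float(w),                      # bounding-box width  (columns)
        float(h),                      # bounding-box height (rows)
        hull_area,
        ecc,
        float(_count_holes(patch)),
        area / (h * w),                # extent
        major,
        minor,
        _perimeter(patch),
        area / hull_area,              # solidity
    ])


# ---------------------------------------------------------------------------
# intensity statistics
# ---------------------------------------------------------------------------

def _entropy(vals: np.ndarray) -> float:
    """Shannon entropy (bits) of a 64-bin histogram of [0,1] values."""
    hist, _ = np.histogram(vals, bins=ENTROPY_BINS, range=(0.0, 1.0))
    p = hist[hist > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def _stats_12(vals3: np.ndarray) -> np.ndarray:
    """(N, 3) channel values → [means(3), medians(3), stds(3), entropies(3)]."""
    out = np.empty(12)
    for c in range(3):
        v = vals3[:, c]
        out[c] = v.mean()
        out[3 + c] = np.median(v)
        out[6 + c] = v.std()
        out[9 + c] = _entropy(v)
    return out


def region_stats(raster: np.ndarray, region: CandidateRegion) -> np.ndarray:
    """Mean/median/std/entropy of region pixels per channel (12 values)."""
    vals = raster[region.pixels[:, 0], region.pixels[:, 1], :]
    return _stats_12(vals)


def circle_pixels(shape, center, radius: float):
    """(row, col) arrays of all pixels within Euclidean distance ``radius``
    of ``center``, clipped to the raster bounds."""
    cy, cx = center
    r0 = max(0, int(np.floor(cy - radius)))
    r1 = min(shape[0] - 1, int(np.ceil(cy + radius)))
    c0 = max(0, int(np.floor(cx - radius)))
    c1 = min(shape[1] - 1, int(np.ceil(cx + radius)))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    keep = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius ** 2
    return rr[keep], cc[keep]


def circle_stats(raster: np.ndarray, center, radius: float) -> np.ndarray:
    """Statistics over all pixels (black included) of a circle of radius
    ``radius`` centered on ``center`` (12 values)."""
    rr, cc = circle_pixels(raster.shape[:2], center, radius)
    vals = raster[rr, cc, :]
    return _stats_12(vals)


# ---------------------------------------------------------------------------
# global / local context features (96-100)
# ---------------------------------------------------------------------------

def prewitt_magnitude(channel: np.ndarray) -> np.ndarray:
    gr = ndi.prewitt(channel, axis=0, mode="nearest")
    gc = ndi.prewitt(channel, axis=1, mode="nearest")
    return np.hypot(gr, gc)


def boundary_pixels(region: CandidateRegion) -> np.ndarray:
    """Region pixels with at least one 4-neighbor outside the region."""
    patch = _region_patch(region)
    inner = ndi.binary_erosion(
        patch, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0
    )
    br, bc = np.nonzero(patch & ~inner)
    r0, c0 = region.bbox[0], region.bbox[1]
    return np.column_stack([br + r0, bc + c0])


def line_offsets(length: int, theta: float) -> np.ndarray:
    """Integer (dr, dc) offsets of a centered digital line segment."""
    half = length // 2
    t = np.arange(-half, half + 1)
    dr = np.round(t * np.sin(theta)).astype(int)
    dc = np.round(t * np.cos(theta)).astype(int)
    return np.unique(np.column_stack([dr, dc]), axis=0)


def line_operator_lengths(od_radius: float):
    """Line lengths {ROD/4, ROD/2, ROD} as odd integers >= 3."""
    out = []
    for f in (0.25, 0.5, 1.0):
        L = max(3, int(round(f * od_radius)) | 1)
        out.append(L)
    return sorted(set(out))


def line_response_map(inv_green: np.ndarray, od_radius: float) -> np.ndarray:
    """Maximum over scales/orientations of (mean along a digital line) minus
    (mean of the L×L surround) — high for elongated bright structures."""
    best = np.full(inv_green.shape, -np.inf)
    for L in line_operator_lengths(od_radius):
        box = ndi.uniform_filter(inv_green, size=L, mode="nearest")
        for k in range(LINE_N_ORIENTATIONS):
            theta = k * np.pi / LINE_N_ORIENTATIONS
            offs = line_offsets(L, theta)
            half = int(np.abs(offs).max())
            kern = np.zeros((2 * half + 1, 2 * half + 1))
            kern[offs[:, 0] + half, offs[:, 1] + half] = 1.0 / len(offs)
            line_mean = ndi.correlate(inv_green, kern, mode="nearest")
            np.maximum(best, line_mean - box, out=best)
    return best


# ---------------------------------------------------------------------------
# extractor
# ---------------------------------------------------------------------------

class FeatureExtractor:
    """Precomputes per-image maps once, then extracts 100 features per region.

    ``kind`` selects the candidate layer used for features 24–35:
    ``'rl'`` → Lrl_cand, ``'ex'`` → Lex_cand.
    """

    def __init__(self, iprep: FundusImage, stack: LayerStack,
                 anat: RetinalAnatomy, kind: str,
                 share_from: "FeatureExtractor" = None):
        if kind not in ("rl", "ex"):
            raise ValueError("kind must be 'rl' or 'ex'")
        self.kind = kind
        self.iprep = iprep
        self.anat = anat
        self.rod = anat.od_radius
        self.d = iprep.fov_diameter

        if share_from is not None:
            # every map except the candidate-layer HSV is kind-independent
            self.circle_hsv = share_from.circle_hsv
            self.prewitt = share_from.prewitt
            self.line_map = share_from.line_map
            self.f96 = share_from.f96
        else:
            self.circle_hsv = [
                color.rgb2hsv(stack.lrl_cand),
                color.rgb2hsv(stack.lchor_dark),
                color.rgb2hsv(stack.lchor_bri),
                color.rgb2hsv(stack.lex_cand),
                color.rgb2hsv(stack.lbm),
            ]
            value = iprep.rgb.max(axis=2)
            self.prewitt = prewitt_magnitude(value)
            inv_green = 1.0 - iprep.rgb[..., 1]
            inv_green[~iprep.fov_mask] = 0.0
            self.line_map = line_response_map(inv_green, self.rod)
            lbm_v = stack.lbm.max(axis=2)
            self.f96 = float(lbm_v[iprep.fov_mask].mean())
        self.cand_hsv = (self.circle_hsv[0] if kind == "rl"
                         else self.circle_hsv[3])

    def extract(self, region: CandidateRegion) -> np.ndarray:
        f = np.empty(N_FEATURES)
        f[0:11] = shape_features(region)
        f[11:23] = region_stats(self.iprep.rgb, region)
        f[23:35] = _stats_12(self.cand_hsv[region.pixels[:, 0], region.pixels[:, 1], :])
        centroid = region.centroid
        for i, hsv in enumerate(self.circle_hsv):
            rr, cc = circle_pixels(hsv.shape[:2], centroid, self.rod)
            f[35 + 12 * i: 47 + 12 * i] = _stats_12(hsv[rr, cc, :])
        f[95] = self.f96
        bp = boundary_pixels(region)
        f[96] = self.prewitt[bp[:, 0], bp[:, 1]].mean()
        f[97] = self.line_map[region.pixels[:, 0], region.pixels[:, 1]].mean()
        f[98] = np.hypot(centroid[0] - self.anat.od_center[0],
                         centroid[1] - self.anat.od_center[1]) / self.d
        f[99] = np.hypot(centroid[0] - self.anat.fovea_center[0],
                         centroid[1] - self.anat.fovea_center[1]) / self.d
        return f


def global_and_local_features(region: CandidateRegion, extractor: FeatureExtractor) -> np.ndarray:
    """Features 96–100 for one region (from a prepared extractor)."""
    return extractor.extract(region)[95:100]


def extract_all(regions, stack: LayerStack, iprep: FundusImage,
                anat: RetinalAnatomy, kind: str,
                extractor: FeatureExtractor = None) -> np.ndarray:
    """Feature matrix, one row per region in the given order; all finite.

    Raises listing the offending (region label, feature index) pairs when a
    non-finite value is produced.
    """
    ext = extractor if extractor is not None else FeatureExtractor(iprep, stack, anat, kind)
    X = np.empty((len(regions), N_FEATURES))
    for i, region in enumerate(regions):
        X[i] = ext.extract(region)
        region.features = X[i].copy()
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        pairs = [(regions[i].label, j + 1) for i, j in bad[:20]]
        raise ValueError(f"non-finite features at (region, feature): {pairs}")
    return X


def normalize(X: np.ndarray, mean: np.ndarray = None, std: np.ndarray = None):
    """Column-wise z-score.

    Training call (no constants given) computes and returns mean/std;
    inference reuses the stored constants.  Zero-variance columns pass
    through with std recorded as 1 (a warning is emitted).
    """
    if mean is None or std is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        # constant columns have std ~1e-16 from float summation, not exactly 0
        zero = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance feature column(s); passing through",
                stacklevel=2,
            )
            std = np.where(zero, 1.0, std)
    return (X - mean) / std, mean, std
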