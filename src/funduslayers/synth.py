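"""Parametric synthetic-fundus generator with exact ground truth.

Emulates the structures the pipeline models: a circular FOV on a black
surround, an orange-red retinal background with a slow illumination
gradient, a darker vessel tree converging on a bright optic disc, a dark
fovea, small round dark microaneurysms, irregular dark hemorrhages, bright
sharp-edged yellowish exudates, pinkish choroidal (tigroid) texture, and
greenish-bluish reflective streaks along the major vessels.

Every structure is painted as a *residual* against the local background —
a per-channel color difference — so that, after background subtraction,
lesions land inside the printed candidate HSV ranges and confounders land in
their own layers by construction.  The residual colors are asserted against
the decomposition ranges at generation time.

Not emulated: camera optics, JPEG artifacts, inter-patient pigmentation
statistics; see the methods note for what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import draw as skdraw

from .decompose import DEFAULT_RANGES

# Residual colors (per-channel difference magnitudes against the background).
# Chosen so that the residuals OBSERVED after the full preprocessing chain sit
# mid-range in the layers they must land in: contrast enhancement rescales the
# value channel locally, which mixes a background-hued (orange, hue ~0.06)
# component into every structure's residual and drags its hue toward the red
# end by roughly 0.05-0.10.  Dark-structure residuals are therefore designed
# green-dominant (hemoglobin absorbs green hardest, so this is also the
# physical expectation) with enough hue headroom to stay mid-range.
RL_DIFF = (0.12, 0.40, 0.06)        # dark red lesion   -> rl_cand  (design hue 0.31,
                                    # strong contrast: lesions are well below the
                                    # printed value floor's shifted variants)
VESSEL_DIFF = (0.13, 0.36, 0.06)    # vessels: same residual family (hue 0.30)
CHOR_DARK_DIFF = (0.30, 0.05, 0.15)  # dark tigroid     -> rl_chor  (hue ~0.93, wraps)
FOVEA_DIFF = (0.20, 0.10, 0.02)     # fovea             -> rl_chor  (hue ~0.07, wraps)
EX_DIFF = (0.25, 0.45, 0.06)        # bright exudate    -> ex_cand  (design hue 0.25:
                                    # observed hue stays between the candidate and
                                    # reflective boundaries)
CHOR_BRI_DIFF = (0.30, 0.05, 0.10)  # bright tigroid    -> ex_chor  (hue ~0.97, wraps)
STREAK_DIFF = (0.03, 0.30, 0.38)    # reflective streak -> ex_reflective (~0.54)
OD_DIFF = (0.30, 0.42, 0.28)        # optic disc (bright; excluded by the OD circle)

# Minimum drawn sizes in pixels so structures stay resolvable when the
# scene is rendered at reduced resolution (inactive at the native
# ~1500 px FOV of real fundus cameras).
MIN_MA_DIAMETER_PX = 4
MIN_HE_DIAMETER_PX = 5
MIN_EX_DIAMETER_PX = 5
MIN_TRUNK_WIDTH_PX = 6


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; ``seed`` makes it deterministic."""

    side: int = 256
    fov_frac: float = 0.94          # FOV diameter as a fraction of the side
    base_color: tuple = (0.72, 0.42, 0.14)
    illum_amplitude: float = 0.10   # linear + radial illumination modulation
    n_trunks: int = 5               # main vessels leaving the optic disc
    vessel_depth: int = 3           # branching depth
    trunk_width_frac: float = 0.014  # trunk width / D (floored at 6 px)
    od_offset_frac: tuple = (0.0, 0.28)  # OD center offset from FOV center, /D
    n_ma: int = 4
    ma_diam_frac: tuple = (0.003, 0.010)  # floored at 4 px
    n_he: int = 2
    he_diam_frac: tuple = (0.010, 0.050)  # floored at 5 px
    he_roughness: float = 0.25
    n_ex: int = 3
    ex_diam_frac: tuple = (0.008, 0.030)  # floored at 5 px
    tigroid: bool = True
    tigroid_amplitude: float = 0.55
    streaks: bool = True
    noise_sigma: float = 0.008
    seed: int = 0


def _hsv_of(diff) -> tuple:
    h, s, v = skcolor.rgb2hsv(np.asarray(diff, dtype=float).reshape(1, 1, 3))[0, 0]
    return float(h), float(s), float(v)


def assert_color_placement(ranges=DEFAULT_RANGES) -> None:
    """Check that each residual color lands in (only) its intended layer."""
    checks = [
        (RL_DIFF, ranges.rl_cand, True), (RL_DIFF, ranges.rl_chor, False),
        (CHOR_DARK_DIFF, ranges.rl_chor, True), (CHOR_DARK_DIFF, ranges.rl_cand, False),
        (EX_DIFF, ranges.ex_cand, True),
        (CHOR_BRI_DIFF, ranges.ex_chor, True), (CHOR_BRI_DIFF, ranges.ex_cand, False),
        (STREAK_DIFF, ranges.ex_reflective, True), (STREAK_DIFF, ranges.ex_cand, False),
    ]
    for diff, rng, want in checks:
        h, s, v = _hsv_of(diff)
        got = bool(rng.contains(h, s, v))
        if got != want:
            raise ValueError(
                f"residual color {diff} (hsv {h:.3f},{s:.3f},{v:.3f}) "
                f"{'not in' if want else 'unexpectedly in'} range {rng}"
            )


# ---------------------------------------------------------------------------
# drawing helpers
# ---------------------------------------------------------------------------

def _disk_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.disk(center, max(radius, 1.0), shape=shape)
    m[rr, cc] = True
    return m


def _blob_mask(shape, center, radius, roughness, rng):
    """Irregular blob: a polygon with a smoothly perturbed radius profile."""
    n = 24
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pert = rng.normal(0.0, 1.0, 4)
    prof = 1.0 + roughness * (
        pert[0] * np.cos(theta) + pert[1] * np.sin(theta)
        + 0.5 * pert[2] * np.cos(2 * theta) + 0.5 * pert[3] * np.sin(2 * theta)
    )
    prof = np.clip(prof, 0.4, 1.8)
    r = center[0] + radius * prof * np.sin(theta)
    c = center[1] + radius * prof * np.cos(theta)
    m = np.zeros(shape, dtype=bool)
    rr, cc = skdraw.polygon(r, c, shape=shape)
    m[rr, cc] = True
    return m


def _displaced_polyline(p0, p1, rng, n_seg=8, jitter_frac=0.12):
    """Midpoint-displacement polyline between two points."""
    pts = [np.asarray(p0, float), np.asarray(p1, float)]
    t = np.linspace(0, 1, n_seg + 1)
    base = np.outer(1 - t, pts[0]) + np.outer(t, pts[1])
    seg = np.linalg.norm(pts[1] - pts[0])
    normal = np.array([-(pts[1] - pts[0])[1], (pts[1] - pts[0])[0]])
    nrm = np.linalg.norm(normal)
    if nrm > 0:
        normal /= nrm
    bump = np.sin(np.pi * t) * rng.normal(0, jitter_frac * seg)
    wig = 0.3 * jitter_frac * seg * np.sin(3 * np.pi * t + rng.uniform(0, 2 * np.pi))
    return base + np.outer(bump + wig, normal)


def _stamp_polyline(mask, poly, width, width_end=None):
    """Stamp disks along a polyline onto ``mask``; the diameter tapers
    linearly from ``width`` to ``width_end`` (vessels narrow distally)."""
    if width_end is None:
        width_end = width
    m = len(poly) - 1
    for i, (a, b) in enumerate(zip(poly[:-1], poly[1:])):
        n = max(2, int(np.ceil(np.linalg.norm(b - a))) + 1)
        for t in np.linspace(0, 1, n):
            frac = (i + t) / m
            r = max((width + frac * (width_end - width)) / 2.0, 0.6)
            p = a + t * (b - a)
            rr, cc = skdraw.disk(p, r, shape=mask.shape)
            mask[rr, cc] = True


def _vessel_tree(spec: SceneSpec, od_center, fov_center, fov_radius, rng):
    """Recursive branching tree from the OD; returns (vessel_mask,
    trunk_polylines) where trunk polylines feed the reflective streaks."""
    d = 2 * fov_radius
    trunk_w = max(MIN_TRUNK_WIDTH_PX, spec.trunk_width_frac * d)
    mask = np.zeros((spec.side, spec.side), dtype=bool)
    trunks = []

    def grow(pos, angle, length, width, depth):
        end = pos + length * np.array([np.sin(angle), np.cos(angle)])
        # keep endpoints inside the FOV
        off = end - fov_center
        dist = np.linalg.norm(off)
        if dist > 0.92 * fov_radius:
            end = fov_center + off / dist * 0.92 * fov_radius
        poly = _displaced_polyline(pos, end, rng)
        w_end = max(2.0, width * 0.7)
        _stamp_polyline(mask, poly, width, w_end)
        if depth == 0:
            trunks.append((poly, width))
        if depth < spec.vessel_depth:
            for sgn in (-1.0, 1.0):
                grow(end, angle + sgn * rng.uniform(0.3, 0.7),
                     length * 0.72, max(2.0, w_end * 0.85), depth + 1)

    # trunks leave the OD pointing into the retina (away from the rim)
    to_center = np.arctan2(*(fov_center - np.asarray(od_center)))
    for i in range(spec.n_trunks):
        ang = to_center + (i - (spec.n_trunks - 1) / 2) * (2.6 / max(spec.n_trunks - 1, 1))
        ang += rng.uniform(-0.1, 0.1)
        grow(np.asarray(od_center, float), ang,
             rng.uniform(0.30, 0.42) * d, trunk_w, 0)
    return mask, trunks


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _sample_positions(n, rng, fov_center, fov_radius, forbidden, min_sep, shape):
    """Rejection-sample lesion centers inside the FOV, off the forbidden mask."""
    out = []
    tries = 0
    while len(out) < n and tries < 4000:
        tries += 1
        ang = rng.uniform(0, 2 * np.pi)
        rad = fov_radius * 0.82 * np.sqrt(rng.uniform())
        p = fov_center + rad * np.array([np.sin(ang), np.cos(ang)])
        r, c = int(round(p[0])), int(round(p[1]))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]) or forbidden[r, c]:
            continue
        if any(np.linalg.norm(p - q) < min_sep for q in out):
            continue
        out.append(p)
    return out


def generate(spec: SceneSpec):
    """Render the scene; returns ``(rgb, truth)``.

    ``truth`` maps structure names to exact pixel masks (``vessels``, ``od``,
    ``fovea``, ``tigroid``, ``streaks``, per-lesion lists ``ma``/``he``/``ex``
    and union masks ``rl``/``ex_union``) plus the generating geometry.
    """
    assert_color_placement()
    rng = np.random.default_rng(spec.seed)
    s = spec.side
    shape = (s, s)
    fov_center = np.array([s / 2.0, s / 2.0])
    fov_radius = spec.fov_frac * s / 2.0
    d = 2 * fov_radius
    rod = d / 12.0

    rows, cols = np.indices(shape, dtype=float)
    fov = np.hypot(rows - fov_center[0], cols - fov_center[1]) <= fov_radius

    od_center = fov_center + d * np.asarray(spec.od_offset_frac)
    if np.linalg.norm(od_center - fov_center) + rod > fov_radius:
        raise ValueError("optic disc placed outside the field of view")

    # background with illumination gradient (linear ramp + radial vignette)
    ang = rng.uniform(0, 2 * np.pi)
    ramp = ((rows - fov_center[0]) * np.sin(ang)
            + (cols - fov_center[1]) * np.cos(ang)) / d
    vign = (np.hypot(rows - fov_center[0], cols - fov_center[1]) / fov_radius) ** 2
    illum = 1.0 + spec.illum_amplitude * (ramp - 0.5 * vign)
    img = np.clip(np.asarray(spec.base_color) * illum[..., None], 0.02, 0.98)

    truth = {
        "fov": fov, "fov_diameter": d, "od_center": tuple(od_center),
        "od_radius": rod, "ma": [], "he": [], "ex": [],
    }

    # tigroid (choroidal) texture: smooth band-pass patches, dark and bright
    tig_mask = np.zeros(shape, dtype=bool)
    if spec.tigroid:
        for diff, sign in ((CHOR_DARK_DIFF, -1.0), (CHOR_BRI_DIFF, +1.0)):
            noise = ndi.gaussian_filter(rng.standard_normal(shape), 0.025 * d)
            noise -= ndi.gaussian_filter(noise, 0.08 * d)
            lim = np.quantile(noise[fov], 0.90)
            w = np.clip((noise - lim) / (noise[fov].max() - lim + 1e-9), 0, 1)
            img += sign * spec.tigroid_amplitude * w[..., None] * np.asarray(diff)
            tig_mask |= (w > 0.15) & fov
    truth["tigroid"] = tig_mask

    # optic disc (bright, slightly soft edge), then vessels over it
    od_mask = _disk_mask(shape, od_center, rod)
    od_soft = ndi.gaussian_filter(od_mask.astype(float), 0.5)   # crisp disc margin
    img += od_soft[..., None] * np.asarray(OD_DIFF)
    truth["od"] = od_mask

    vess_mask, trunks = _vessel_tree(spec, od_center, fov_center, fov_radius, rng)
    vess_mask &= fov
    vess_soft = ndi.gaussian_filter(vess_mask.astype(float), 0.6)
    img -= vess_soft[..., None] * np.asarray(VESSEL_DIFF)
    truth["vessels"] = vess_mask

    # fovea: dark gaussian pit in the annulus around the OD
    to_center = fov_center - od_center
    to_center /= np.linalg.norm(to_center) + 1e-12
    fovea_center = od_center + 2.8 * rod * to_center
    fov_pit = np.exp(-(((rows - fovea_center[0]) ** 2 + (cols - fovea_center[1]) ** 2)
                       / (2 * (0.55 * rod) ** 2)))
    img -= fov_pit[..., None] * np.asarray(FOVEA_DIFF)
    truth["fovea_center"] = tuple(fovea_center)
    truth["fovea"] = fov_pit > 0.5

    # reflective streaks parallel to the trunks
    streak_mask = np.zeros(shape, dtype=bool)
    if spec.streaks:
        for poly, width in trunks:
            tang = np.gradient(poly, axis=0)
            nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
            nrm /= np.linalg.norm(nrm, axis=1, keepdims=True) + 1e-12
            side_sign = 1.0 if rng.uniform() < 0.5 else -1.0
            offset = poly + side_sign * (width / 2.0 + 2.0) * nrm
            _stamp_polyline(streak_mask, offset, 1.6)
        streak_mask &= fov & ~vess_mask
        streak_soft = ndi.gaussian_filter(streak_mask.astype(float), 0.5)
        img += streak_soft[..., None] * np.asarray(STREAK_DIFF)
    truth["streaks"] = streak_mask

    # lesions — positions avoid vessels, OD and each other
    forbidden = (ndi.binary_dilation(vess_mask, iterations=3)
                 | _disk_mask(shape, od_center, 1.5 * rod)
                 | ~fov)
    occupied = np.zeros(shape, dtype=bool)

    def _place(n, diam_lo, diam_hi, floor_px, kind):
        nonlocal occupied
        if n == 0:
            return []
        sizes = rng.uniform(diam_lo, diam_hi, size=n) * d
        sizes = np.maximum(sizes, floor_px)
        centers = _sample_positions(n, rng, fov_center, fov_radius,
                                    forbidden | occupied, 2.5 * sizes.max(), shape)
        placed = []
        for p, diam in zip(centers, sizes):
            if kind == "ma":
                m = _disk_mask(shape, p, diam / 2.0)
            elif kind == "he":
                m = _blob_mask(shape, p, diam / 2.0, spec.he_roughness, rng)
            else:
                m = _blob_mask(shape, p, diam / 2.0, 0.15, rng)
            m &= fov
            if m.sum() < 2:
                continue
            placed.append(m)
            occupied |= ndi.binary_dilation(m, iterations=2)
        return placed

    truth["ma"] = _place(spec.n_ma, *spec.ma_diam_frac, MIN_MA_DIAMETER_PX, "ma")
    truth["he"] = _place(spec.n_he, *spec.he_diam_frac, MIN_HE_DIAMETER_PX, "he")
    truth["ex"] = _place(spec.n_ex, *spec.ex_diam_frac, MIN_EX_DIAMETER_PX, "ex")

    for m in truth["ma"] + truth["he"]:
        soft = ndi.gaussian_filter(m.astype(float), 0.5)   # mildly soft dark lesions
        img -= soft[..., None] * np.asarray(RL_DIFF)
    for m in truth["ex"]:
        img += m[..., None].astype(float) * np.asarray(EX_DIFF)  # sharp edges

    rl_union = np.zeros(shape, dtype=bool)
    for m in truth["ma"] + truth["he"]:
        rl_union |= m
    ex_union = np.zeros(shape, dtype=bool)
    for m in truth["ex"]:
        ex_union |= m
    truth["rl"] = rl_union
    truth["ex_union"] = ex_union

    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)
    img[~fov] = 0.0
    return img, truth


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def generate_corpus(n_images: int, seed: int, pathological_frac: float = 0.5,
                    side: int = 256, out_dir=None):
    """Generate ``n_images`` scenes (a deterministic pathological/normal mix).

    Returns a list of records ``{image, truth, spec, pathological}``; when
    ``out_dir`` is given the images (float TIFF), truth masks (PNG) and a
    TSV manifest are also written there.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    n_path = int(round(pathological_frac * n_images))
    flags = np.array([True] * n_path + [False] * (n_images - n_path))
    records = []
    for i, is_path in enumerate(flags):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        if is_path:
            spec = SceneSpec(side=side, seed=sub,
                             n_ma=int(rng.integers(3, 7)),
                             n_he=int(rng.integers(1, 4)),
                             n_ex=int(rng.integers(2, 6)))
        else:
            spec = SceneSpec(side=side, seed=sub, n_ma=0, n_he=0, n_ex=0)
        img, truth = generate(spec)
        records.append({
            "id": f"img{i:03d}", "image": img, "truth": truth,
            "spec": spec, "pathological": bool(is_path),
        })
    if out_dir is not None:
        _write_corpus(records, out_dir)
    return records


def _write_corpus(records, out_dir):
    import tifffile
    from pathlib import Path
    from .core import write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        iid = rec["id"]
        tifffile.imwrite(out / f"{iid}.tif", rec["image"].astype(np.float32),
                         photometric="rgb")
        write_mask(out / f"{iid}_rl.png", rec["truth"]["rl"])
        write_mask(out / f"{iid}_ex.png", rec["truth"]["ex_union"])
        rows.append({
            "id": iid, "image": f"{iid}.tif",
            "rl_mask": f"{iid}_rl.png", "ex_mask": f"{iid}_ex.png",
            "pathological": rec["pathological"],
        })
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
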