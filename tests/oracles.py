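"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written from the mathematical definitions
(per-pixel loops, colorsys conversions, dict-based counting) and shares no
code path with the package implementation it checks.
"""

import colorsys
import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# HSV range / layer oracles
# ---------------------------------------------------------------------------

def pixel_in_range(r, g, b, rng):
    if r == 0.0 and g == 0.0 and b == 0.0:
        return False
    h, s, v = colorsys.rgb_to_hsv(r, g, b)
    if rng.h_lo > rng.h_hi:
        hue_ok = h >= rng.h_lo or h <= rng.h_hi
    else:
        hue_ok = rng.h_lo <= h <= rng.h_hi
    return hue_ok and rng.s_lo <= s <= rng.s_hi and rng.v_lo <= v <= rng.v_hi


def hsv_mask_bruteforce(raster, rng):
    H, W = raster.shape[:2]
    out = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            out[i, j] = pixel_in_range(*raster[i, j], rng)
    return out


def dark_residual_bruteforce(ibg_dark, ibg):
    H, W = ibg.shape[:2]
    out = np.zeros_like(ibg)
    for i in range(H):
        for j in range(W):
            for c in range(3):
                out[i, j, c] = min(max(ibg[i, j, c] - ibg_dark[i, j, c], 0.0), 1.0)
    return out


def bright_residual_bruteforce(ibg_bri, ibg):
    H, W = ibg.shape[:2]
    out = np.zeros_like(ibg)
    for i in range(H):
        for j in range(W):
            for c in range(3):
                out[i, j, c] = min(max(ibg_bri[i, j, c] - ibg[i, j, c], 0.0), 1.0)
    return out


def _disk_offsets(radius):
    offs = []
    r = int(radius)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr * dr + dc * dc <= radius * radius:
                offs.append((dr, dc))
    return offs


def binary_erosion_bruteforce(mask, radius):
    H, W = mask.shape
    offs = _disk_offsets(radius)
    out = np.zeros_like(mask)
    for i in range(H):
        for j in range(W):
            ok = True
            for dr, dc in offs:
                r, c = i + dr, j + dc
                if not (0 <= r < H and 0 <= c < W) or not mask[r, c]:
                    ok = False
                    break
            out[i, j] = ok
    return out


def binary_dilation_bruteforce(mask, radius):
    H, W = mask.shape
    offs = _disk_offsets(radius)
    out = np.zeros_like(mask)
    for i in range(H):
        for j in range(W):
            hit = False
            for dr, dc in offs:
                r, c = i + dr, j + dc
                if 0 <= r < H and 0 <= c < W and mask[r, c]:
                    hit = True
                    break
            out[i, j] = hit
    return out


def lbm_bruteforce(ibri, mvess, reflective_range, fov_diameter, od_radius):
    r_open = max(1, round(od_radius / 10.0))
    r_dil = max(1, round(fov_diameter / 60.0))
    ibm1_mask = hsv_mask_bruteforce(ibri, reflective_range)
    ibm1 = ibri * ibm1_mask[..., None]
    wide = binary_dilation_bruteforce(binary_erosion_bruteforce(mvess, r_open), r_open)
    ibm2 = binary_dilation_bruteforce(wide, r_dil)
    return ibm1 * ibm2[..., None]


# ---------------------------------------------------------------------------
# connected components (8-connectivity flood fill)
# ---------------------------------------------------------------------------

def flood_fill_components(mask):
    """List of pixel-coordinate lists, one per 8-connected component."""
    H, W = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(H):
        for j in range(W):
            if mask[i, j] and not seen[i, j]:
                comp = []
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    r, c = q.popleft()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < H and 0 <= cc < W
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                q.append((rr, cc))
                comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# feature oracles (loops + closed formulas)
# ---------------------------------------------------------------------------

def shape_oracle(pixels):
    """Features 1-11 recomputed from first principles."""
    from scipy.spatial import Delaunay, QhullError

    pts = [(int(r), int(c)) for r, c in pixels]
    n = len(pts)
    rs = [p[0] for p in pts]
    cs = [p[1] for p in pts]
    r0, r1 = min(rs), max(rs)
    c0, c1 = min(cs), max(cs)
    h, w = r1 - r0 + 1, c1 - c0 + 1

    # hull area: pixel centers inside the hull of pixel centers (Delaunay test)
    degenerate = False
    try:
        tri = Delaunay(np.array(pts, dtype=float))
        hull_area = 0
        for i in range(r0, r1 + 1):
            for j in range(c0, c1 + 1):
                if tri.find_simplex((float(i), float(j))) >= 0:
                    hull_area += 1
    except QhullError:
        degenerate = True
        hull_area = n

    # moments
    rbar = sum(rs) / n
    cbar = sum(cs) / n
    mu20 = sum((r - rbar) ** 2 for r in rs) / n
    mu02 = sum((c - cbar) ** 2 for c in cs) / n
    mu11 = sum((r - rbar) * (c - cbar) for r, c in pts) / n
    common = math.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11 ** 2)
    l1 = (mu20 + mu02) / 2.0 + common
    l2 = max((mu20 + mu02) / 2.0 - common, 0.0)
    major = 4.0 * math.sqrt(l1)
    minor = 4.0 * math.sqrt(l2)
    ecc = math.sqrt(1.0 - l2 / l1) if l1 > 0 else 1.0
    if minor == 0.0:
        ecc = 1.0
        hull_area = n

    pixset = set(pts)
    # holes: 4-connected background components of the padded patch not
    # touching the pad border
    bg = [(i, j) for i in range(r0 - 1, r1 + 2) for j in range(c0 - 1, c1 + 2)
          if (i, j) not in pixset]
    bgset = set(bg)
    seen = set()
    holes = 0
    for start in bg:
        if start in seen:
            continue
        q = deque([start])
        seen.add(start)
        comp = []
        touches = False
        while q:
            r, c = q.popleft()
            comp.append((r, c))
            if r in (r0 - 1, r1 + 1) or c in (c0 - 1, c1 + 1):
                touches = True
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (r + dr, c + dc)
                if nb in bgset and nb not in seen:
                    seen.add(nb)
                    q.append(nb)
        if not touches:
            holes += 1

    perim = 0
    for r, c in pts:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (r + dr, c + dc) not in pixset:
                perim += 1

    return [
        float(n), float(w), float(h), float(hull_area), ecc, float(holes),
        n / (h * w), major, minor, float(perim), n / hull_area,
    ]


def entropy_oracle(vals):
    counts = {}
    for v in vals:
        b = min(63, int(v * 64))
        counts[b] = counts.get(b, 0) + 1
    n = len(vals)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def stats12_oracle(vals3):
    """[means, medians, stds, entropies] per channel from loops."""
    out = []
    for stat in ("mean", "median", "std", "entropy"):
        for ch in range(3):
            vals = sorted(float(v) for v in vals3[:, ch])
            n = len(vals)
            if stat == "mean":
                out.append(sum(vals) / n)
            elif stat == "median":
                out.append(vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2)
            elif stat == "std":
                m = sum(vals) / n
                out.append(math.sqrt(sum((v - m) ** 2 for v in vals) / n))
            else:
                out.append(entropy_oracle(vals))
    return out


def circle_pixels_oracle(shape, center, radius):
    cy, cx = center
    pix = []
    for i in range(shape[0]):
        for j in range(shape[1]):
            if (i - cy) ** 2 + (j - cx) ** 2 <= radius ** 2:
                pix.append((i, j))
    return pix


def prewitt_magnitude_oracle(channel, i, j):
    """|∇| at one pixel; derivative kernel [-1,0,1], smoothing [1,1,1],
    nearest-edge clamping (matches correlate semantics)."""
    H, W = channel.shape

    def at(r, c):
        return channel[min(max(r, 0), H - 1), min(max(c, 0), W - 1)]

    gr = sum(at(i + 1, j + v) - at(i - 1, j + v) for v in (-1, 0, 1))
    gc = sum(at(i + u, j + 1) - at(i + u, j - 1) for u in (-1, 0, 1))
    return math.hypot(gr, gc)


def line_response_oracle(inv_green, i, j, od_radius, n_orient=12):
    """Max over scales/orientations of line mean minus box mean at (i, j)."""
    H, W = inv_green.shape

    def at(r, c):
        return inv_green[min(max(r, 0), H - 1), min(max(c, 0), W - 1)]

    lengths = sorted({max(3, int(round(f * od_radius)) | 1) for f in (0.25, 0.5, 1.0)})
    best = -math.inf
    for L in lengths:
        half = L // 2
        box = 0.0
        for u in range(-half, half + 1):
            for v in range(-half, half + 1):
                box += at(i + u, j + v)
        box /= L * L
        for k in range(n_orient):
            theta = k * math.pi / n_orient
            offs = set()
            for t in range(-half, half + 1):
                offs.add((round(t * math.sin(theta)), round(t * math.cos(theta))))
            line = sum(at(i + dr, j + dc) for dr, dc in offs) / len(offs)
            best = max(best, line - box)
    return best


# ---------------------------------------------------------------------------
# FCBF reference (independent implementation of the published algorithm)
# ---------------------------------------------------------------------------

def _entropy_dict(xs):
    counts = {}
    for x in xs:
        counts[x] = counts.get(x, 0) + 1
    n = len(xs)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def su_reference(x, y):
    hx = _entropy_dict(list(x))
    hy = _entropy_dict(list(y))
    if hx + hy == 0:
        return 0.0
    hxy = _entropy_dict(list(zip(x, y)))
    return 2.0 * (hx + hy - hxy) / (hx + hy)


def discretize_reference(col, n_bins=10):
    n = len(col)
    if n == 0:
        return []
    if all(v == col[0] for v in col):
        return [0] * n
    order = sorted(range(n), key=lambda i: (col[i], i))   # stable by index
    ranks = [0] * n
    for rank, i in enumerate(order):
        ranks[i] = rank
    return [rank * n_bins // n for rank in ranks]


def fcbf_reference(X, y, delta=0.0, n_bins=10):
    """Relevance ranking + backward redundancy scan, per the FCBF paper."""
    n, p = X.shape
    cols = [discretize_reference(list(X[:, j]), n_bins) for j in range(p)]
    su_c = [su_reference(cols[j], list(y)) for j in range(p)]
    slist = [j for j in sorted(range(p), key=lambda j: (-su_c[j], j))
             if su_c[j] > delta]
    alive = list(slist)
    pos = 0
    while pos < len(alive):
        fp = alive[pos]
        q = pos + 1
        while q < len(alive):
            fq = alive[q]
            if su_reference(cols[fp], cols[fq]) >= su_c[fq]:
                alive.pop(q)
            else:
                q += 1
        pos += 1
    return alive


# ---------------------------------------------------------------------------
# evaluation oracles
# ---------------------------------------------------------------------------

def pixel_based_oracle(pred, gt):
    gt_comps = flood_fill_components(gt)
    pred_comps = flood_fill_components(pred)
    detected = sum(1 for comp in gt_comps if any(pred[r, c] for r, c in comp))
    tp_regions = sum(1 for comp in pred_comps if any(gt[r, c] for r, c in comp))
    se = 100.0 * detected / len(gt_comps) if gt_comps else None
    ppv = 100.0 * tp_regions / len(pred_comps) if pred_comps else None
    return se, ppv, len(gt_comps), detected, len(pred_comps), tp_regions


def image_based_oracle(counts, labels, min_pixels=30):
    tp = sum(1 for c, l in zip(counts, labels) if l and c >= min_pixels)
    fn = sum(1 for c, l in zip(counts, labels) if l and c < min_pixels)
    fp = sum(1 for c, l in zip(counts, labels) if not l and c >= min_pixels)
    tn = sum(1 for c, l in zip(counts, labels) if not l and c < min_pixels)
    se = 100.0 * tp / (tp + fn) if tp + fn else None
    sp = 100.0 * tn / (tn + fp) if tn + fp else None
    acc = 100.0 * (tp + tn) / len(counts) if counts else None
    return se, sp, acc, (tp, tn, fp, fn)
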