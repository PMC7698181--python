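"""Connected-component labeling of candidate masks."""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure

from .core import CandidateRegion


def label_regions(mask: np.ndarray, min_area: int = 2) -> list:
    """Split a binary candidate mask into 8-connected regions.

    Components smaller than ``min_area`` pixels are discarded (single-pixel
    blobs are camera noise at fundus resolutions).  Regions are ordered by
    ``(min_row, min_col)`` of their bounding box and relabeled 1..n for
    determinism.
    """
    lab = measure.label(mask, connectivity=2)
    regions = []
    for rp in measure.regionprops(lab):
        if rp.area < min_area:
            continue
        r0, c0, r1, c1 = rp.bbox
        regions.append(CandidateRegion(
            label=0,
            pixels=np.ascontiguousarray(rp.coords),
            bbox=(r0, c0, r1 - r0, c1 - c0),
        ))
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    for i, r in enumerate(regions, start=1):
        r.label = i
    return regions


def regions_table(regions) -> pd.DataFrame:
    """One row per region: label, area, bbox, centroid."""
    rows = []
    for r in regions:
        cy, cx = r.centroid
        rows.append({
            "label": r.label, "area": r.area,
            "min_row": r.bbox[0], "min_col": r.bbox[1],
            "height": r.bbox[2], "width": r.bbox[3],
            "centroid_row": cy, "centroid_col": cx,
        })
    return pd.DataFrame(rows, columns=[
        "label", "area", "min_row", "min_col", "height", "width",
        "centroid_row", "centroid_col",
    ])
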