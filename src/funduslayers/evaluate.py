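"""Lesion-level and image-level evaluation of predicted lesion masks.

Lesion-level ("pixel-based") criterion: a ground-truth lesion counts as
detected when at least one of its pixels is predicted; SEp is the percentage
of detected ground-truth lesions.  PPVp is counted per predicted region (a
predicted region is correct when it overlaps at least one ground-truth lesion
pixel); a per-pixel variant is available via ``ppv_mode='pixel'``.

Image-level criterion: an image is predicted pathological when at least
``min_pixels`` lesion pixels are predicted (default 30 — smaller detections
are treated as noise); SEi/SPi/ACCi follow from the 2×2 confusion table.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .core import EvaluationReport

MIN_PATHOLOGICAL_PIXELS = 30


def pixel_based(pred_mask: np.ndarray, gt_lesion_mask: np.ndarray,
                ppv_mode: str = "region") -> dict:
    """Lesion-level sensitivity and positive predictive value.

    Ground-truth connected components (8-connected) are individual lesions.
    Returns a dict with SEp/PPVp (percent, ``None`` when the denominator is
    empty) and the underlying counts.
    """
    if pred_mask.shape != gt_lesion_mask.shape:
        raise ValueError("shape mismatch")
    if ppv_mode not in ("region", "pixel"):
        raise ValueError("ppv_mode must be 'region' or 'pixel'")
    gt_lab = measure.label(gt_lesion_mask, connectivity=2)
    n_gt = int(gt_lab.max())
    detected = len(np.unique(gt_lab[(gt_lab > 0) & pred_mask]))

    pred_lab = measure.label(pred_mask, connectivity=2)
    n_pred = int(pred_lab.max())
    tp_regions = len(np.unique(pred_lab[(pred_lab > 0) & gt_lesion_mask]))

    se_p = 100.0 * detected / n_gt if n_gt > 0 else None
    if ppv_mode == "region":
        ppv_p = 100.0 * tp_regions / n_pred if n_pred > 0 else None
    else:
        n_pred_px = int(pred_mask.sum())
        tp_px = int((pred_mask & gt_lesion_mask).sum())
        ppv_p = 100.0 * tp_px / n_pred_px if n_pred_px > 0 else None
    return {
        "se_p": se_p,
        "ppv_p": ppv_p,
        "n_gt_lesions": n_gt,
        "n_detected_lesions": int(detected),
        "n_candidate_regions": n_pred,
        "n_true_positive_regions": int(tp_regions),
    }


def image_based(pred_masks, gt_image_labels,
                min_pixels: int = MIN_PATHOLOGICAL_PIXELS) -> dict:
    """Image-level confusion counts and rates under the minimum-pixel rule.

    ``pred_masks`` may be binary masks or precomputed predicted-pixel counts;
    ``gt_image_labels`` are booleans (True = pathological).
    """
    if len(pred_masks) != len(gt_image_labels):
        raise ValueError("list length mismatch")
    tp = tn = fp = fn = 0
    for pred, is_path in zip(pred_masks, gt_image_labels):
        n_px = int(np.sum(pred)) if not np.isscalar(pred) else int(pred)
        flagged = n_px >= min_pixels
        if is_path and flagged:
            tp += 1
        elif is_path and not flagged:
            fn += 1
        elif not is_path and flagged:
            fp += 1
        else:
            tn += 1
    n = tp + tn + fp + fn
    se_i = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    sp_i = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    acc_i = 100.0 * (tp + tn) / n if n > 0 else None
    return {
        "se_i": se_i, "sp_i": sp_i, "acc_i": acc_i,
        "n_images": n, "tp_images": tp, "tn_images": tn,
        "fp_images": fp, "fn_images": fn, "min_pixels": min_pixels,
    }


def build_report(pred_masks, gt_masks, gt_image_labels=None,
                 min_pixels: int = MIN_PATHOLOGICAL_PIXELS,
                 ppv_mode: str = "region") -> EvaluationReport:
    """Aggregate lesion-level counts over a set of images and add the
    image-level rates.

    SEp/PPVp are computed from the pooled counts across images (one lesion =
    one ground-truth component on its image).  When ``gt_image_labels`` is
    omitted, an image is pathological iff its ground-truth mask is non-empty.
    """
    if len(pred_masks) != len(gt_masks):
        raise ValueError("list length mismatch")
    totals = dict(n_gt_lesions=0, n_detected_lesions=0,
                  n_candidate_regions=0, n_true_positive_regions=0)
    for pred, gt in zip(pred_masks, gt_masks):
        c = pixel_based(pred, gt, ppv_mode=ppv_mode)
        for k in totals:
            totals[k] += c[k]
    se_p = (100.0 * totals["n_detected_lesions"] / totals["n_gt_lesions"]
            if totals["n_gt_lesions"] > 0 else None)
    ppv_p = (100.0 * totals["n_true_positive_regions"] / totals["n_candidate_regions"]
             if totals["n_candidate_regions"] > 0 else None)
    if gt_image_labels is None:
        gt_image_labels = [bool(np.any(gt)) for gt in gt_masks]
    img = image_based(pred_masks, gt_image_labels, min_pixels)
    return EvaluationReport(
        **totals, se_p=se_p, ppv_p=ppv_p,
        n_images=img["n_images"], tp_images=img["tp_images"],
        tn_images=img["tn_images"], fp_images=img["fp_images"],
        fn_images=img["fn_images"], se_i=img["se_i"], sp_i=img["sp_i"],
        acc_i=img["acc_i"], min_pixels=min_pixels,
    )
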