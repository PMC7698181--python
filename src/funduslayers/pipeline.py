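"""End-to-end orchestration: preprocess → background → anatomy → decompose →
candidates → features → classify, plus the training protocol."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .anatomy import AnatomyConfig, detect_anatomy
from .background import BackgroundConfig, compute_background_model
from .candidates import label_regions
from .core import FundusImage, LayerStack, LesionModel
from .decompose import DEFAULT_RANGES, DecompositionRanges, decompose
from .evaluate import MIN_PATHOLOGICAL_PIXELS
from .fcbf import fcbf_select
from .features import (EX_SELECTED, RL_SELECTED, FeatureExtractor,
                       extract_all, normalize)
from .mlp import (EX_HYPERPARAMS, RL_HYPERPARAMS, balance_classes,
                  grid_search_cv, predict, train)
from .preprocess import PreprocessConfig, preprocess


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    ranges: DecompositionRanges = field(default_factory=DecompositionRanges)
    precedence: bool = True
    min_area: int = 2
    min_pixels: int = MIN_PATHOLOGICAL_PIXELS

    def hash(self) -> str:
        blob = json.dumps({
            "preprocess": vars(self.preprocess),
            "background": vars(self.background),
            "anatomy": {k: list(v) if isinstance(v, tuple) else v
                        for k, v in vars(self.anatomy).items()},
            "ranges": {k: vars(v) for k, v in vars(self.ranges).items()},
            "precedence": self.precedence,
            "min_area": self.min_area, "min_pixels": self.min_pixels,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


DEFAULT_PIPELINE = PipelineConfig()


@dataclass
class StageResult:
    """Everything the pipeline computes for one image before classification."""

    iprep: FundusImage
    background: object
    anatomy: object
    stack: LayerStack
    rl_regions: list
    ex_regions: list
    rl_features: np.ndarray
    ex_features: np.ndarray


def run_stages(rgb: np.ndarray, config: PipelineConfig = DEFAULT_PIPELINE) -> StageResult:
    """Run every stage up to (not including) classification."""
    iprep = preprocess(rgb, config.preprocess)
    bg = compute_background_model(iprep, config.background)
    anat = detect_anatomy(iprep, config.anatomy)
    stack = decompose(iprep, bg, anat, config.ranges, config.precedence)
    rl_regions = label_regions(stack.mrl_cand, config.min_area)
    ex_regions = label_regions(stack.mex_cand, config.min_area)
    ext_rl = FeatureExtractor(iprep, stack, anat, "rl")
    ext_ex = FeatureExtractor(iprep, stack, anat, "ex", share_from=ext_rl)
    rl_X = (extract_all(rl_regions, stack, iprep, anat, "rl", extractor=ext_rl)
            if rl_regions else np.empty((0, 100)))
    ex_X = (extract_all(ex_regions, stack, iprep, anat, "ex", extractor=ext_ex)
            if ex_regions else np.empty((0, 100)))
    return StageResult(iprep, bg, anat, stack, rl_regions, ex_regions, rl_X, ex_X)


def _predicted_mask(regions, X, model: LesionModel, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if len(regions) == 0:
        return mask
    labels, _ = predict(model, X)
    for region, keep in zip(regions, labels):
        if keep:
            mask[region.pixels[:, 0], region.pixels[:, 1]] = True
    return mask


def detect(rgb: np.ndarray, model_rl: LesionModel, model_ex: LesionModel,
           config: PipelineConfig = DEFAULT_PIPELINE) -> dict:
    """Detect both lesion kinds in one image.

    Returns predicted masks plus a JSON-ready summary with region/pixel
    counts, the pathological flag under the minimum-pixel rule, and a
    reproducibility block.
    """
    stages = run_stages(rgb, config)
    shape = stages.iprep.shape
    mrl = _predicted_mask(stages.rl_regions, stages.rl_features, model_rl, shape)
    mex = _predicted_mask(stages.ex_regions, stages.ex_features, model_ex, shape)
    n_rl_px, n_ex_px = int(mrl.sum()), int(mex.sum())
    summary = {
        "rl": {"n_candidates": len(stages.rl_regions), "n_pixels": n_rl_px,
               "pathological": n_rl_px >= config.min_pixels},
        "ex": {"n_candidates": len(stages.ex_regions), "n_pixels": n_ex_px,
               "pathological": n_ex_px >= config.min_pixels},
        "pathological": (n_rl_px + n_ex_px) >= config.min_pixels,
        "reproducibility": {"config_hash": config.hash(), "version": __version__},
    }
    return {"mrl_pred": mrl, "mex_pred": mex, "summary": summary,
            "stages": stages}


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _truth_mask(record, kind):
    return record["truth"]["rl"] if kind == "rl" else record["truth"]["ex_union"]


def _label_candidates(st: StageResult, rec, kind: str):
    regions = st.rl_regions if kind == "rl" else st.ex_regions
    gt = _truth_mask(rec, kind)
    return np.array([gt[r.pixels[:, 0], r.pixels[:, 1]].any() for r in regions],
                    dtype=int)


def collect_training_sets(records, config: PipelineConfig = DEFAULT_PIPELINE):
    """Run the candidate stages once per image and label the candidates of
    both lesion kinds.

    A candidate is positive iff it overlaps at least one ground-truth lesion
    pixel (the same semantics as the detection criterion).  Returns
    ``{kind: (X, y)}``.
    """
    parts = {"rl": ([], []), "ex": ([], [])}
    for rec in records:
        st = run_stages(rec["image"], config)
        for kind in ("rl", "ex"):
            X = st.rl_features if kind == "rl" else st.ex_features
            parts[kind][0].append(X)
            parts[kind][1].append(_label_candidates(st, rec, kind))
    out = {}
    for kind, (X_parts, y_parts) in parts.items():
        X = np.vstack(X_parts) if X_parts else np.empty((0, 100))
        y = np.concatenate(y_parts) if y_parts else np.empty(0, dtype=int)
        out[kind] = (X, y)
    return out


def collect_training_set(records, kind: str,
                         config: PipelineConfig = DEFAULT_PIPELINE):
    """Single-kind variant of :func:`collect_training_sets`; returns (X, y)."""
    X, y = collect_training_sets(records, config)[kind]
    return X, y


def train_pipeline(records, kind: str, seed: int,
                   config: PipelineConfig = DEFAULT_PIPELINE,
                   feature_set: str = "published", grid: str = "off",
                   n_hidden=None, reg_lambda=None, max_iter: int = 500,
                   precollected=None):
    """Full training protocol for one lesion kind.

    Candidate extraction → overlap labeling → class balancing →
    z-normalization → feature selection (the published subsets by default,
    or a fresh FCBF run with ``feature_set='fcbf'``) → perceptron training
    (optionally hyperparameter grid search with ``grid='cv'``).

    ``precollected`` may carry an ``(X, y)`` pair from
    :func:`collect_training_sets` to avoid re-running the image stages when
    training both kinds on one corpus.  Returns ``(model, log)``.
    """
    if kind not in ("rl", "ex"):
        raise ValueError("kind must be 'rl' or 'ex'")
    if precollected is not None:
        X_all, y_all = precollected
    else:
        X_all, y_all = collect_training_set(records, kind, config)
    if len(y_all) == 0 or y_all.sum() == 0:
        raise ValueError("no positive candidates in the training corpus")

    idx = balance_classes(y_all, seed)
    X, y = X_all[idx], y_all[idx]

    if feature_set == "published":
        selected = np.asarray(RL_SELECTED if kind == "rl" else EX_SELECTED)
    elif feature_set == "fcbf":
        Xz_all, _, _ = normalize(X)
        kept = fcbf_select(Xz_all, y)
        if not kept:
            raise ValueError("FCBF kept no features")
        selected = np.asarray(kept) + 1          # 1-based catalog indices
    else:
        raise ValueError("feature_set must be 'published' or 'fcbf'")

    Xs = X[:, selected - 1]
    Xz, mean, std = normalize(Xs)

    default_h, default_l = RL_HYPERPARAMS if kind == "rl" else EX_HYPERPARAMS
    cv_surface = None
    if grid == "cv":
        n_hidden, reg_lambda, cv_surface = grid_search_cv(Xz, y, seed=seed)
    else:
        n_hidden = default_h if n_hidden is None else n_hidden
        reg_lambda = default_l if reg_lambda is None else reg_lambda

    model = train(Xz, y, n_hidden, reg_lambda, seed=seed, max_iter=max_iter,
                  lesion_kind=kind, selected_indices=selected,
                  feat_mean=mean, feat_std=std)
    log = {
        "kind": kind,
        "n_candidates": int(len(y_all)),
        "n_positive": int(y_all.sum()),
        "n_balanced": int(len(y)),
        "selected_indices": [int(i) for i in selected],
        "n_hidden": int(n_hidden),
        "reg_lambda": float(reg_lambda),
        "seed": int(seed),
        "config_hash": config.hash(),
        "version": __version__,
    }
    if cv_surface is not None:
        log["cv_surface_shape"] = list(cv_surface.shape)
        log["cv_best_accuracy"] = float(cv_surface.max())
    return model, log
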