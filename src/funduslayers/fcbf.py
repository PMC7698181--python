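"""Fast correlation-based filter (FCBF) feature selection.

Features are ranked by symmetrical uncertainty with the class,
``SU(x, y) = 2 I(x; y) / (H(x) + H(y))``, then scanned in decreasing
relevance: a feature ``j`` is redundant (and removed) when some
already-kept, more relevant feature ``i`` satisfies ``SU(i, j) >= SU(j, class)``.
Continuous columns are discretized by equal-frequency binning first.
"""

from __future__ import annotations

import numpy as np


def _entropy_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def entropy(x: np.ndarray) -> float:
    """Empirical Shannon entropy (bits) of a discrete vector."""
    _, counts = np.unique(np.asarray(x), return_counts=True)
    return _entropy_counts(counts)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Empirical mutual information (bits) from joint frequencies."""
    x = np.asarray(x)
    y = np.asarray(y)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    hx = _entropy_counts(joint.sum(axis=1))
    hy = _entropy_counts(joint.sum(axis=0))
    hxy = _entropy_counts(joint.ravel())
    return hx + hy - hxy


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """``SU = 2 I(x;y) / (H(x) + H(y))`` in [0, 1]; 0 when both entropies
    vanish (two constant vectors carry no information)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    hx, hy = entropy(x), entropy(y)
    if hx + hy == 0:
        return 0.0
    su = 2.0 * mutual_information(x, y) / (hx + hy)
    return float(min(max(su, 0.0), 1.0))


def discretize(column: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` bins.

    Ties are resolved by stable rank (so a monotone transform of the column
    yields the identical discretization); a constant column maps to a single
    bin.
    """
    column = np.asarray(column, dtype=np.float64)
    if not np.all(np.isfinite(column)):
        raise ValueError("column must be finite")
    n = column.size
    if n == 0:
        return np.zeros(0, dtype=int)
    if np.all(column == column[0]):
        return np.zeros(n, dtype=int)
    order = np.argsort(column, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins // n).astype(int)


def fcbf_select(X: np.ndarray, y: np.ndarray, delta: float = 0.0,
                n_bins: int = 10) -> list:
    """FCBF selection over the columns of ``X`` against labels ``y``.

    Returns kept column indices (0-based) in decreasing relevance order.
    Deterministic under ties: the lower index ranks first.  May return an
    empty list when no feature clears ``delta``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n, p = X.shape
    cols = [discretize(X[:, j], n_bins) for j in range(p)]
    su_c = np.array([symmetrical_uncertainty(cols[j], y) for j in range(p)])
    ranked = sorted((j for j in range(p) if su_c[j] > delta),
                    key=lambda j: (-su_c[j], j))
    kept = []
    removed = set()
    for j in ranked:
        if j in removed:
            continue
        kept.append(j)
        for k in ranked:
            if k == j or k in kept or k in removed:
                continue
            if symmetrical_uncertainty(cols[j], cols[k]) >= su_c[k]:
                removed.add(k)
    return kept
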