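"""Three-layer perceptron (tanh hidden, logistic output) for candidate
classification, trained by scaled conjugate gradient on cross-entropy with an
L2 penalty on the weights (not the biases).

Default architecture/regularization per lesion kind: 51 hidden units with
lambda = 0.5 for red lesions, 55 with 0.4 for exudates; the hyperparameter
grid searched during training is hidden units 1..100 step 1 and lambda
0..1 step 0.1, with stratified 10-fold cross-validation.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core import LesionModel

#: (n_hidden, reg_lambda) defaults per lesion kind.
RL_HYPERPARAMS = (51, 0.5)
EX_HYPERPARAMS = (55, 0.4)

#: Hyperparameter grids searched during training.
DEFAULT_HIDDEN_GRID = tuple(range(1, 101))
DEFAULT_REG_GRID = tuple(round(0.1 * i, 1) for i in range(11))

# Møller SCG constants
SCG_SIGMA0 = 1e-4
SCG_LAMBDA0 = 1e-6


# ---------------------------------------------------------------------------
# parameter handling
# ---------------------------------------------------------------------------

def init_model(n_in: int, n_hidden: int, seed: int) -> dict:
    """Uniform init in [-1/sqrt(fan_in), +1/sqrt(fan_in)]; zero biases."""
    if n_in < 1 or n_hidden < 1:
        raise ValueError("n_in and n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    r1 = 1.0 / np.sqrt(n_in)
    r2 = 1.0 / np.sqrt(n_hidden)
    return {
        "W1": rng.uniform(-r1, r1, size=(n_hidden, n_in)),
        "b1": np.zeros(n_hidden),
        "W2": rng.uniform(-r2, r2, size=(1, n_hidden)),
        "b2": np.zeros(1),
    }


def _pack(w: dict) -> np.ndarray:
    return np.concatenate([w["W1"].ravel(), w["b1"], w["W2"].ravel(), w["b2"]])


def _unpack(theta: np.ndarray, n_in: int, n_hidden: int) -> dict:
    i = 0
    W1 = theta[i:i + n_hidden * n_in].reshape(n_hidden, n_in); i += n_hidden * n_in
    b1 = theta[i:i + n_hidden]; i += n_hidden
    W2 = theta[i:i + n_hidden].reshape(1, n_hidden); i += n_hidden
    b2 = theta[i:i + 1]
    return {"W1": W1, "b1": b1, "W2": W2, "b2": b2}


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(weights: dict, X: np.ndarray) -> np.ndarray:
    """Probabilities ``sigmoid(W2 tanh(W1 x + b1) + b2)``, one per sample."""
    X = np.atleast_2d(X)
    if X.shape[1] != weights["W1"].shape[1]:
        raise ValueError("input width does not match W1")
    h = np.tanh(X @ weights["W1"].T + weights["b1"])
    return _sigmoid(h @ weights["W2"].T + weights["b2"]).ravel()


def _loss_grad(theta, X, y, lam, n_in, n_hidden):
    """Mean cross-entropy + lam * mean squared weight, with gradient."""
    w = _unpack(theta, n_in, n_hidden)
    n = X.shape[0]
    a1 = X @ w["W1"].T + w["b1"]
    h = np.tanh(a1)
    p = _sigmoid(h @ w["W2"].T + w["b2"]).ravel()
    eps = 1e-12
    ce = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    n_w = w["W1"].size + w["W2"].size
    reg = lam * (np.sum(w["W1"] ** 2) + np.sum(w["W2"] ** 2)) / n_w
    # backprop
    delta2 = (p - y)[:, None] / n                     # (n,1)
    gW2 = delta2.T @ h + 2.0 * lam * w["W2"] / n_w
    gb2 = delta2.sum(axis=0)
    delta1 = (delta2 @ w["W2"]) * (1.0 - h ** 2)      # (n,H)
    gW1 = delta1.T @ X + 2.0 * lam * w["W1"] / n_w
    gb1 = delta1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return ce + reg, grad


def scg_minimize(fun_grad, theta0: np.ndarray, max_iter: int = 500,
                 grad_tol: float = 1e-6):
    """Møller's scaled conjugate gradient (sigma = 1e-4, lambda_init = 1e-6).

    ``fun_grad(theta) -> (value, gradient)``.  Returns ``(theta, n_iter)``.
    """
    theta = theta0.copy()
    nparam = theta.size
    f, g = fun_grad(theta)
    r = -g
    p = r.copy()
    lam = SCG_LAMBDA0
    lam_bar = 0.0
    success = True
    delta = 1.0
    for k in range(1, max_iter + 1):
        if np.linalg.norm(r) < grad_tol:
            break
        p_sq = p @ p
        if p_sq == 0:
            break
        p_norm = np.sqrt(p_sq)
        if success:
            sigma = SCG_SIGMA0 / p_norm
            _, g_plus = fun_grad(theta + sigma * p)
            s = (g_plus - g) / sigma
            delta = p @ s
        delta_k = delta + (lam - lam_bar) * p_sq
        if delta_k <= 0:           # make the Hessian approximation positive definite
            lam_bar = 2.0 * (lam - delta_k / p_sq)
            delta_k = -delta_k + lam * p_sq
            lam = lam_bar
        mu = p @ r
        alpha = mu / delta_k
        f_new, g_new = fun_grad(theta + alpha * p)
        Delta = 2.0 * delta_k * (f - f_new) / (mu ** 2)
        if Delta >= 0:             # successful step
            theta = theta + alpha * p
            f, g = f_new, g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % nparam == 0:    # restart
                p = r_new.copy()
            else:
                beta = (r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lam = max(lam / 4.0, 1e-15)
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam = lam + delta_k * (1.0 - Delta) / p_sq
            lam = min(lam, 1e20)
    return theta, k


def train(X_z: np.ndarray, y: np.ndarray, n_hidden: int, reg_lambda: float,
          seed: int, max_iter: int = 500, lesion_kind: str = "rl",
          selected_indices=None, feat_mean=None, feat_std=None,
          threshold: float = 0.5) -> LesionModel:
    """Fit the perceptron on an (already selected and z-scored) matrix.

    Deterministic given ``seed`` (initialization is the only stochastic
    element).  Raises on single-class input.
    """
    X_z = np.asarray(X_z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n_in = X_z.shape[1]
    w0 = init_model(n_in, n_hidden, seed)
    theta0 = _pack(w0)
    theta, _ = scg_minimize(
        lambda t: _loss_grad(t, X_z, y, reg_lambda, n_in, n_hidden),
        theta0, max_iter=max_iter,
    )
    w = _unpack(theta, n_in, n_hidden)
    if selected_indices is None:
        selected_indices = np.arange(1, n_in + 1)
    if feat_mean is None:
        feat_mean = np.zeros(n_in)
    if feat_std is None:
        feat_std = np.ones(n_in)
    return LesionModel(
        lesion_kind=lesion_kind,
        selected_indices=np.asarray(selected_indices, dtype=int),
        feat_mean=np.asarray(feat_mean, dtype=np.float64),
        feat_std=np.asarray(feat_std, dtype=np.float64),
        W1=w["W1"], b1=w["b1"], W2=w["W2"], b2=w["b2"],
        n_hidden=n_hidden, reg_lambda=reg_lambda, threshold=threshold,
    )


def grid_search_cv(X_z: np.ndarray, y: np.ndarray,
                   hidden_grid=DEFAULT_HIDDEN_GRID, reg_grid=DEFAULT_REG_GRID,
                   k: int = 10, seed: int = 0, max_iter: int = 200):
    """Stratified k-fold mean validation accuracy over the whole grid.

    Returns ``(best_hidden, best_reg, cv_surface)`` with the surface shaped
    ``len(hidden_grid) × len(reg_grid)``; ties resolve to fewer hidden units,
    then smaller regularization.
    """
    X_z = np.asarray(X_z, dtype=np.float64)
    y = np.asarray(y).ravel().astype(int)
    if X_z.shape[0] < k:
        raise ValueError("need at least k samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X_z, y))
    surface = np.zeros((len(hidden_grid), len(reg_grid)))
    for i, nh in enumerate(hidden_grid):
        for j, lam in enumerate(reg_grid):
            accs = []
            for fold_id, (tr, va) in enumerate(folds):
                model = train(X_z[tr], y[tr], nh, lam,
                              seed=seed + 1000 * fold_id, max_iter=max_iter)
                w = {"W1": model.W1, "b1": model.b1, "W2": model.W2, "b2": model.b2}
                pred = forward(w, X_z[va]) >= 0.5
                accs.append(np.mean(pred == (y[va] == 1)))
            surface[i, j] = np.mean(accs)
    best = np.argwhere(surface == surface.max())
    bi, bj = min(map(tuple, best))      # fewer hidden units, then smaller reg
    return hidden_grid[bi], reg_grid[bj], surface


def balance_classes(labels: np.ndarray, seed: int) -> np.ndarray:
    """Indices of all minority samples plus an equal-size uniform random
    subset of the majority; sorted, reproducible from ``seed``."""
    labels = np.asarray(labels).ravel().astype(int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    sub = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, sub]))


def predict(model: LesionModel, feature_matrix: np.ndarray):
    """Apply a trained model to raw 100-column feature rows.

    Selection and normalization are applied internally; returns
    ``(labels, probabilities)`` with ``label = p >= threshold``.
    """
    X = np.atleast_2d(np.asarray(feature_matrix, dtype=np.float64))
    idx = np.asarray(model.selected_indices, dtype=int) - 1
    if X.shape[1] <= idx.max():
        raise ValueError("feature matrix is missing required columns")
    Xs = (X[:, idx] - model.feat_mean) / model.feat_std
    w = {"W1": model.W1, "b1": model.b1, "W2": model.W2, "b2": model.b2}
    p = forward(w, Xs)
    return (p >= model.threshold), p
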