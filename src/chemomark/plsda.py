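"""Two-class partial least squares discriminant analysis with VIP scores.

PLS-DA regresses a class-indicator response on the abundance matrix
through a small number of latent variables (LVs) — directions in
variable space maximizing covariance with class membership — and
classifies by the sign of the predicted indicator.  The class is coded
-1 (class_a) / +1 (class_b) and centered, so a positive regression
coefficient reads directly as "more abundant in class_b".

The decomposition is PLS1 NIPALS: for each LV, the weight vector is
the (normalized) covariance of the deflated X with the response, the
score is the projection of X on it, and X is deflated by the rank-one
score/loading product.  Variable importance in projection (VIP)
aggregates each variable's weight across LVs, weighted by the share of
class-membership variance each LV explains:

    VIP_j = sqrt( p * sum_a SSY_a * w_ja^2 / sum_a SSY_a )

with ``SSY_a = q_a^2 * t_a' t_a`` and unit-norm weight vectors, so the
mean of squared VIPs over the p variables is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PLSDAModel", "plsda_fit", "plsda_predict", "vip_scores", "coefficient_report"]

_EPS = 1e-12


def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, n_lv: int):
    """Core PLS1 decomposition of centered/scaled X against centered y.

    Returns (W, T, P, q) truncated if a component collapses (no
    remaining covariance with the response).
    """
    n, p = Xs.shape
    W = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    X = Xs.copy()
    a = 0
    for _ in range(n_lv):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < _EPS:
            break
        pl = (X.T @ t) / tt
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pl, (yc @ t) / tt
        X -= np.outer(t, pl)
        a += 1
    return W[:, :a], T[:, :a], P[:, :a], q[:a]


@dataclass
class PLSDAModel:
    """Fitted two-class PLS-DA model.

    Coefficients live on the autoscaled X scale; ``column_means`` /
    ``column_sds`` and ``y_mean`` are retained so new raw samples can be
    projected with the training scaling.  ``explained_x_pct`` and
    ``explained_y_pct`` give each LV's share of X variance and of
    (centered) class-membership variance.
    """

    n_lv: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    x_scores: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    vip: np.ndarray
    explained_x_pct: np.ndarray
    explained_y_pct: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    y_mean: float
    classes: tuple = (0, 1)


def plsda_fit(
    matrix: np.ndarray, labels: np.ndarray, n_lv: int, scale: bool = True
) -> PLSDAModel:
    """Fit a PLS-DA model of binary labels on an abundance matrix.

    Parameters
    ----------
    matrix : samples x variables
        Raw abundances if ``scale`` (autoscaling applied internally,
        statistics stored for prediction); already-scaled data otherwise.
    labels : array of 0/1
        0 = class_a, 1 = class_b.
    n_lv : int
        Latent variables requested; must be <= min(n - 1, p).  Fewer
        are kept if the response covariance is exhausted earlier.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("labels contain a single class; PLS-DA needs two")
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("labels must be coded 0/1")
    max_lv = min(n - 1, p)
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}], got {n_lv}")

    if scale:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd == 0.0, 1.0, sd)  # constant columns carry no information
        Xs = (X - mu) / sd
    else:
        mu = np.zeros(p)
        sd = np.ones(p)
        Xs = X - X.mean(axis=0)
        mu = X.mean(axis=0)

    y = np.where(labels == 1, 1.0, -1.0)
    y_mean = y.mean()
    yc = y - y_mean

    W, T, P, q = _nipals_pls1(Xs, yc, n_lv)
    a = W.shape[1]
    if a == 0:
        raise ValueError("response has no covariance with X; model degenerate")

    # b = W (P'W)^-1 q reconstructs predictions from the undeflated X
    coef = W @ np.linalg.solve(P.T @ W, q)

    ssx = float((Xs**2).sum())
    ssy = float((yc**2).sum())
    tt = (T**2).sum(axis=0)
    explained_x = 100.0 * tt * (P**2).sum(axis=0) / ssx if ssx > 0 else np.zeros(a)
    ssy_a = q**2 * tt
    explained_y = 100.0 * ssy_a / ssy if ssy > 0 else np.zeros(a)

    vip = _vip(W, ssy_a)

    return PLSDAModel(
        n_lv=a,
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=q,
        coefficients=coef,
        vip=vip,
        explained_x_pct=explained_x,
        explained_y_pct=explained_y,
        column_means=mu,
        column_sds=sd,
        y_mean=y_mean,
    )


def _vip(W: np.ndarray, ssy_a: np.ndarray) -> np.ndarray:
    total = ssy_a.sum()
    if total < _EPS:
        raise ValueError("zero explained class-membership variance; VIP undefined")
    p = W.shape[0]
    return np.sqrt(p * (W**2 @ ssy_a) / total)


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection, one nonnegative score per variable."""
    ssy_a = model.y_loadings**2 * (model.x_scores**2).sum(axis=0)
    return _vip(model.x_weights, ssy_a)


def plsda_predict(model: PLSDAModel, new_matrix: np.ndarray, scaled: bool = False):
    """Predict class labels and decision values for new samples.

    ``scaled=False`` (default) applies the training scaling to raw
    input.  The decision value is the predicted (centered-coded) class
    indicator; class_b (1) is called at positive values, class_a (0)
    otherwise — an exact tie at 0 goes to class_a and is flagged.

    Returns ``(labels, decision, ties)``.
    """
    X = np.asarray(new_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coefficients.shape[0]:
        raise ValueError(
            f"expected {model.coefficients.shape[0]} columns, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    Xs = X if scaled else (X - model.column_means) / model.column_sds
    decision = Xs @ model.coefficients + model.y_mean
    labels = (decision > 0).astype(int)
    ties = decision == 0
    return labels, decision, ties


def coefficient_report(model: PLSDAModel, variable_ids) -> pd.DataFrame:
    """Sign-based direction calls from the regression coefficients.

    Positive coefficient -> more abundant in class_b (e.g. upregulated
    with aging when class_b is the later timepoint); negative ->
    downregulated.  Exact zeros are reported as "none".
    """
    coef = model.coefficients
    call = np.where(coef > 0, "up_in_class_b", np.where(coef < 0, "down_in_class_b", "none"))
    return pd.DataFrame(
        {"coefficient": coef, "vip": model.vip, "direction": call},
        index=pd.Index(variable_ids, name="variable"),
    )
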