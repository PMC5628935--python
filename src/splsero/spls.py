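"""Sparse partial least-squares discriminant analysis (sPLS-DA).

NIPALS-style PLS on auto-scaled predictors against a centered/scaled
dummy-coded class response, with per-component soft-thresholding of the
predictor weight vector to at most ``keepX`` nonzero entries, and
regression-mode deflation of both blocks.  Variable importance in the
projection (VIP) summarises each predictor's weighted contribution across
components; the mean of squared VIPs over predictors is 1 by construction.

The prediction rule is the maximum predicted dummy-response value
("max.dist"): ties resolve to the first class in level order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SPLSModel", "soft_threshold", "fit_splsda", "predict", "vip_scores", "pca_scores"]


def soft_threshold(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``w`` to at most ``keep`` nonzeros, renormalized to unit norm.

    The threshold is the (keep+1)-th largest absolute entry (0 when
    ``keep`` equals the length), and each surviving entry is shrunk toward
    zero by it.  Ties at the threshold are resolved in stable index order,
    dropping later indices; a complete tie among the selected entries keeps
    their original values so the result is never the zero vector (unless
    ``w`` is).
    """
    w = np.asarray(w, dtype=float)
    if keep <= 0:
        raise ValueError("keep must be positive")
    if keep > w.size:
        raise ValueError(f"keep={keep} exceeds vector length {w.size}")
    aw = np.abs(w)
    if keep == w.size:
        lam = 0.0
        sel = np.arange(w.size)
    else:
        order = np.argsort(-aw, kind="mergesort")
        sel = order[:keep]
        lam = aw[order[keep]]
    out = np.zeros_like(w)
    shrunk = np.maximum(aw[sel] - lam, 0.0)
    out[sel] = np.sign(w[sel]) * shrunk
    if not out.any() and aw[sel].any():
        out[sel] = w[sel]  # complete tie at the threshold
    peak = np.max(np.abs(out))
    if peak == 0.0:
        return out
    out = out / peak  # guard against denormal underflow in the norm
    return out / np.linalg.norm(out)


@dataclass
class SPLSModel:
    """Fitted sparse PLS-DA model (regression-mode deflation)."""

    classes_: np.ndarray
    features: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    W: np.ndarray          # p x H sparse unit-norm predictor weights
    C: np.ndarray          # c x H response weights
    P: np.ndarray          # p x H predictor loadings
    Q: np.ndarray          # c x H response loadings
    T: np.ndarray          # n x H training scores
    keepX: list[int]
    ssy: np.ndarray        # response sum of squares explained per component
    B: np.ndarray          # p x c coefficients, standardized X -> standardized Y
    converged: list[bool] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    def to_dict(self) -> dict:
        """Plain-text-serializable representation."""
        return {
            "classes": [str(c) for c in self.classes_],
            "features": list(self.features),
            "keepX": list(map(int, self.keepX)),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_scale": self.y_scale.tolist(),
            "W": self.W.tolist(),
            "C": self.C.tolist(),
            "P": self.P.tolist(),
            "Q": self.Q.tolist(),
            "ssy": self.ssy.tolist(),
            "B": self.B.tolist(),
        }


def _dummy_code(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (labels[:, None] == classes[None, :]).astype(float)


def _spls_core(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    keepx: list[int],
    tol: float = 1e-6,
    max_iter: int = 500,
):
    """NIPALS loop on pre-standardized blocks; returns weights/loadings/scores."""
    n, p = X.shape
    c = Y.shape[1]
    Xh = X.copy()
    Yh = Y.copy()
    W = np.zeros((p, n_components))
    C = np.zeros((c, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((c, n_components))
    T = np.zeros((n, n_components))
    ssy = np.zeros(n_components)
    converged: list[bool] = []
    h_fit = 0
    for h in range(n_components):
        M = Xh.T @ Yh
        if not np.any(M):
            break
        # init v: leading eigenvector of M'M (c x c, tiny)
        evals, evecs = np.linalg.eigh(M.T @ M)
        v = evecs[:, -1]
        u = np.zeros(p)
        ok = False
        for _ in range(max_iter):
            u_new = soft_threshold(M @ v, keepx[h])
            v_new = M.T @ u_new
            nv = np.linalg.norm(v_new)
            if nv == 0:
                break
            v_new /= nv
            if np.linalg.norm(u_new - u) < tol:
                u, v = u_new, v_new
                ok = True
                break
            u, v = u_new, v_new
        if not ok:
            warnings.warn(f"component {h + 1}: weight iteration did not converge")
        # deterministic sign: largest-magnitude weight entry positive
        imax = int(np.argmax(np.abs(u)))
        if u[imax] < 0:
            u, v = -u, -v
        t = Xh @ u
        tt = float(t @ t)
        if tt == 0.0:
            break
        p_load = Xh.T @ t / tt
        q_load = Yh.T @ t / tt
        Xh = Xh - np.outer(t, p_load)
        Yh = Yh - np.outer(t, q_load)
        W[:, h] = u
        C[:, h] = v
        P[:, h] = p_load
        Q[:, h] = q_load
        T[:, h] = t
        ssy[h] = float(q_load @ q_load) * tt
        converged.append(ok)
        h_fit = h + 1
    sl = slice(0, h_fit)
    return W[:, sl], C[:, sl], P[:, sl], Q[:, sl], T[:, sl], ssy[sl], converged


def _coefficients(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros((W.shape[0], Q.shape[0]))
    ptw = P.T @ W
    return W @ np.linalg.solve(ptw, Q.T)


def fit_splsda(
    X,
    labels,
    n_components: int = 2,
    keepX: int | list[int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    drop_constant: bool = True,
) -> SPLSModel:
    """Fit a sparse PLS-DA model.

    Parameters
    ----------
    X:
        samples x proteins matrix (DataFrame or ndarray); auto-scaled
        internally (column centering, unit variance).
    labels:
        class label per sample (>= 2 classes); dummy-coded one column per
        class, centered and scaled.
    n_components:
        number of latent components (0 allowed: majority-class model).
    keepX:
        nonzero weights allowed per component; ``None`` keeps all
        (dense PLS-DA limit).
    """
    if isinstance(X, pd.DataFrame):
        features = [str(f) for f in X.columns]
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        features = [f"x{i}" for i in range(Xa.shape[1])]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    if Xa.shape[0] != labels.size:
        raise ValueError("X rows and labels length differ")

    x_scale_raw = Xa.std(axis=0, ddof=1)
    const = x_scale_raw == 0.0
    if const.any():
        if drop_constant:
            warnings.warn(f"dropping {int(const.sum())} constant column(s) before fit")
            keep_cols = ~const
            Xa = Xa[:, keep_cols]
            features = [f for f, k in zip(features, keep_cols) if k]
            x_scale_raw = x_scale_raw[keep_cols]
        else:
            x_scale_raw = np.where(const, 1.0, x_scale_raw)
    p = Xa.shape[1]

    if keepX is None:
        keepx = [p] * n_components
    elif np.isscalar(keepX):
        keepx = [int(keepX)] * n_components
    else:
        keepx = [int(k) for k in keepX]
        if len(keepx) != n_components:
            raise ValueError("keepX list length must equal n_components")
    for k in keepx:
        if not 1 <= k <= p:
            raise ValueError(f"keepX entries must lie in [1, {p}]")

    x_mean = Xa.mean(axis=0)
    x_scale = x_scale_raw
    Xs = (Xa - x_mean) / x_scale

    Yd = _dummy_code(labels, classes)
    y_mean = Yd.mean(axis=0)
    y_scale = Yd.std(axis=0, ddof=1)
    y_scale = np.where(y_scale == 0.0, 1.0, y_scale)
    Ys = (Yd - y_mean) / y_scale

    W, C, P, Q, T, ssy, converged = _spls_core(
        Xs, Ys, n_components, keepx, tol=tol, max_iter=max_iter
    )
    B = _coefficients(W, P, Q)
    return SPLSModel(
        classes_=classes,
        features=features,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        W=W,
        C=C,
        P=P,
        Q=Q,
        T=T,
        keepX=keepx[: W.shape[1]],
        ssy=ssy,
        B=B,
        converged=converged,
    )


def predict(model: SPLSModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Predict dummy-response scores and classes for new samples.

    Returns ``(scores, classes)`` where ``scores`` has one column per class
    level (continuous, usable for ROC) and ``classes`` is the argmax class
    per row, ties resolving to the first class in level order.
    """
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.features if f not in X_new.columns]
        if missing:
            raise ValueError(f"missing protein column(s): {missing}")
        Xa = X_new[model.features].to_numpy(dtype=float)
    else:
        Xa = np.asarray(X_new, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[None, :]
        if Xa.shape[1] != len(model.features):
            raise ValueError(
                f"expected {len(model.features)} columns, got {Xa.shape[1]}"
            )
    Xs = (Xa - model.x_mean) / model.x_scale
    scores = Xs @ model.B * model.y_scale + model.y_mean
    pred = model.classes_[np.argmax(scores, axis=1)]
    return scores, pred


def vip_scores(model: SPLSModel, n_components: int | None = None) -> np.ndarray:
    """Variable importance in the projection.

    ``VIP_j = sqrt(p * sum_h ssy_h * w_jh^2 / sum_h ssy_h)`` with unit-norm
    weight vectors; predictors zeroed by the soft threshold in every
    component score exactly 0, and ``mean(VIP^2) = 1``.
    """
    H = model.n_components if n_components is None else min(n_components, model.n_components)
    p = model.W.shape[0]
    if H == 0:
        warnings.warn("VIP undefined for a zero-component model; returning zeros")
        return np.zeros(p)
    ssy = model.ssy[:H]
    total = ssy.sum()
    if total == 0:
        return np.zeros(p)
    return np.sqrt(p * (model.W[:, :H] ** 2 @ ssy) / total)


def pca_scores(X, k: int = 2, scale: bool = True) -> np.ndarray:
    """First ``k`` principal-component scores of an auto-scaled matrix.

    Quality-control export for outlier inspection; ``k`` beyond the matrix
    rank is truncated with a warning.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0.0] = 1.0
        Xc = Xc / sd
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = rank
    return U[:, :k] * S[:k]
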