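"""Single-response partial least squares (PLS1) by NIPALS.

Deterministic throughout: the weight vector of each latent variable is
X'y of the deflated block (no random initialization), X is column-mean
centered and y mean centered, and no further scaling is applied — pixel
descriptors share one unit within a model.

Besides fitting and prediction this module provides the regression vector
``b``, variable importance in projection (VIP), leverages for Williams-plot
applicability-domain analysis, and leave-one-out component selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PLSModel",
    "fit",
    "predict",
    "predict_components",
    "scores",
    "vip",
    "leverage",
    "loo_predictions",
    "select_components",
    "cross_validation_rmse",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    """Fitted PLS1 state.

    W are the (unit-norm) weight vectors, P the x-loadings, q the y-loadings,
    T the training scores (orthogonal columns) and ``b`` the regression
    vector in centered descriptor space: yhat = (x - x_mean) b + y_mean.
    """

    A: int
    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray  # p x A
    P: np.ndarray  # p x A
    q: np.ndarray  # A
    T: np.ndarray  # n x A
    b: np.ndarray  # p
    fitted: np.ndarray  # training-set fitted values
    column_mask: np.ndarray | None = None

    @property
    def n_train(self) -> int:
        return self.T.shape[0]

    @property
    def p(self) -> int:
        return self.W.shape[0]


def fit(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    column_mask: np.ndarray | None = None,
    allow_fewer: bool = False,
) -> PLSModel:
    """Fit a PLS1 model with ``A`` latent variables by NIPALS deflation.

    With ``allow_fewer`` the extraction stops once X is fully deflated (the
    data's effective rank is exhausted) and the model keeps the components
    obtained; otherwise an exhausted X raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if n < 3:
        raise ValueError("need at least 3 training samples")
    if not 1 <= A <= n - 1:
        raise ValueError(f"A={A} outside the valid range [1, {n - 1}]")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    T = np.empty((n, A))
    a_used = A
    for a in range(A):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm <= 1e-10 * max(1.0, np.abs(Xd).max() * np.abs(yd).max()):
            if allow_fewer and a >= 1:
                a_used = a
                break
            raise ValueError(
                f"X is fully deflated after {a} components; A={A} is too large"
            )
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            raise ValueError(f"degenerate score at component {a + 1}")
        pvec = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        Xd -= np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t

    if a_used < A:
        W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    # b = W (P'W)^-1 q maps centered x directly to centered yhat
    b = W @ np.linalg.solve(P.T @ W, q)
    fitted = y_mean + (X - x_mean) @ b
    return PLSModel(a_used, x_mean, y_mean, W, P, q, T, b, fitted, column_mask)


def _apply_mask(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] == model.p:
        return X_new
    if model.column_mask is not None and X_new.shape[1] == model.column_mask.size:
        return X_new[:, model.column_mask]
    raise ValueError(
        f"column count {X_new.shape[1]} matches neither the model's retained "
        f"columns ({model.p}) nor its full mask"
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses: yhat = (x - x_mean) b + y_mean per row."""
    Xm = _apply_mask(model, X_new)
    return model.y_mean + (Xm - model.x_mean) @ model.b


def scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Project rows onto the model's latent variables (with deflation)."""
    Xd = _apply_mask(model, X_new) - model.x_mean
    T = np.empty((Xd.shape[0], model.A))
    for a in range(model.A):
        t = Xd @ model.W[:, a]
        Xd = Xd - np.outer(t, model.P[:, a])
        T[:, a] = t
    return T


def predict_components(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Cumulative predictions for every truncation 1..A (rows x A).

    Column a-1 is the prediction of the nested model with a components,
    exploiting that NIPALS models are nested.
    """
    T = scores(model, X_new)
    return model.y_mean + np.cumsum(T * model.q, axis=1)


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection; satisfies sum(VIP^2) = p."""
    ss = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)  # per-component SSY
    wnorm2 = (model.W**2).sum(axis=0)
    contrib = (model.W**2 / wnorm2) @ ss
    return np.sqrt(model.p * contrib / ss.sum())


def leverage(model: PLSModel, X_rows: np.ndarray) -> np.ndarray:
    """Williams-plot leverage h_i = 1/n + t_i' (T'T)^-1 t_i."""
    TtT = model.T.T @ model.T
    cond = np.linalg.cond(TtT)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("singular score covariance; reduce A")
    t_new = scores(model, X_rows)
    return 1.0 / model.n_train + np.einsum(
        "ij,ij->i", t_new, np.linalg.solve(TtT, t_new.T).T
    )


def loo_predictions(X: np.ndarray, y: np.ndarray, A_max: int) -> np.ndarray:
    """Leave-one-out predictions for every component count 1..A_max.

    Returns an (n, A_max) array; entry (i, a-1) is the prediction of sample i
    by the a-component model fitted without it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 4:
        raise ValueError("leave-one-out needs at least 4 samples")
    if A_max > n - 2:
        raise ValueError(f"A_max={A_max} exceeds n-2={n - 2}")
    out = np.empty((n, A_max))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        m = fit(X[keep], y[keep], A_max, allow_fewer=True)
        preds = predict_components(m, X[i : i + 1])[0]
        out[i, : m.A] = preds
        out[i, m.A :] = preds[-1]  # rank exhausted: further LVs change nothing
    return out


def cross_validation_rmse(X: np.ndarray, y: np.ndarray, A_max: int) -> np.ndarray:
    """RMSECV for each component count 1..A_max (leave-one-out)."""
    preds = loo_predictions(X, y, A_max)
    y = np.asarray(y, dtype=float).ravel()
    return np.sqrt(((preds - y[:, None]) ** 2).mean(axis=0))


def select_components(X: np.ndarray, y: np.ndarray, A_max: int) -> int:
    """Number of latent variables minimizing leave-one-out RMSECV.

    Ties break toward the smaller count; fully deterministic.
    """
    rmsecv = cross_validation_rmse(X, y, A_max)
    return int(np.argmin(rmsecv)) + 1


def save_model(model: PLSModel, prefix: str | Path) -> None:
    """Persist a model as a JSON metadata file plus an .npz matrix bundle."""
    prefix = Path(prefix)
    arrays = dict(
        x_mean=model.x_mean, W=model.W, P=model.P, q=model.q,
        T=model.T, b=model.b, fitted=model.fitted,
    )
    if model.column_mask is not None:
        arrays["column_mask"] = model.column_mask
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    meta = {"A": model.A, "y_mean": model.y_mean, "n_train": model.n_train,
            "p": model.p, "arrays": prefix.with_suffix(".npz").name}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_model(prefix: str | Path) -> PLSModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npz"))
    return PLSModel(
        A=meta["A"], x_mean=data["x_mean"], y_mean=meta["y_mean"],
        W=data["W"], P=data["P"], q=data["q"], T=data["T"], b=data["b"],
        fitted=data["fitted"],
        column_mask=data["column_mask"] if "column_mask" in data else None,
    )
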