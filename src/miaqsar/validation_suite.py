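"""Calibration, cross-validation, external-validation and chance-correlation
statistics, plus the Williams-plot applicability domain.

Conventions (dimensionless unless noted; RMSE/MAE in pIC50 units):

* r2 and r2_pred are squared Pearson correlations of observed vs predicted.
* q2 = 1 - PRESS / sum((y - ybar)^2) from leave-one-out refits.
* Q2_F1 and Q2_F2 reference the squared prediction error to the deviation of
  the test responses from the *training* mean (F1) or the *test* mean (F2).
* r2_m is Roy's modified statistic r2 * (1 - sqrt(|r2 - r0^2|)) with r0^2
  from the through-origin fit; the reverse variant swaps the axes and the
  pair is summarized by its mean and absolute difference.
* CCC is Lin's concordance correlation (1/n variances).
* c_r2p = r * sqrt(r2 - mean r2_y-rand) guards against chance correlation.
* The applicability domain flags compounds with leverage above
  h* = 3(A+1)/n or |standardized residual| above 3.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

from . import pls_engine

__all__ = [
    "MetricsReport",
    "ADReport",
    "calibration_metrics",
    "cross_validation",
    "external_metrics",
    "y_randomization_summary",
    "williams_domain",
]

RESIDUAL_CUTOFF = 3.0


@dataclass
class MetricsReport:
    """The full statistics block for one model (one descriptor property)."""

    A: int
    rmsec: float
    r2: float
    rmsecv: float
    q2: float
    rmsep: float
    r2_pred: float
    r2m_test: float
    avg_r2m: float
    delta_r2m: float
    ccc: float
    q2_f1: float
    q2_f2: float
    mae: float
    rmse_yrand: float
    r2_yrand: float
    c_r2p: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ADReport:
    """Williams-plot applicability domain for one assessment model."""

    ids: list[str]
    leverage: np.ndarray
    std_residual: np.ndarray
    h_star: float
    residual_cutoff: float
    outliers: list[str]

    @property
    def n_outliers(self) -> int:
        return len(self.outliers)

    def to_dict(self) -> dict:
        return {
            "ids": list(self.ids),
            "leverage": [float(v) for v in self.leverage],
            "std_residual": [float(v) for v in self.std_residual],
            "h_star": self.h_star,
            "residual_cutoff": self.residual_cutoff,
            "outliers": list(self.outliers),
        }


def _as_pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    return y, yhat


def _pearson2(y, yhat) -> float:
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def calibration_metrics(y, y_fit) -> tuple[float, float]:
    """(RMSEC, r2) of the calibration fit."""
    y, y_fit = _as_pair(y, y_fit)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    rmsec = float(np.sqrt(((y - y_fit) ** 2).mean()))
    return rmsec, _pearson2(y, y_fit)


def cross_validation(X, y, A) -> tuple[float, float]:
    """(RMSECV, q2) by leave-one-out at a fixed component count."""
    y = np.asarray(y, dtype=float).ravel()
    preds = pls_engine.loo_predictions(X, y, A)[:, A - 1]
    press = float(((y - preds) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    return float(np.sqrt(press / y.size)), 1.0 - press / ss


def _r2m_pair(y, yhat) -> tuple[float, float]:
    """Roy's (forward, reverse) modified r2 of observed vs predicted."""
    r2 = _pearson2(y, yhat)

    def one(obs, pred):
        # through-origin slope of obs on pred, r0^2 referenced to obs variance
        k = float(obs @ pred / (pred @ pred))
        r02 = 1.0 - float(((obs - k * pred) ** 2).sum() / ((obs - obs.mean()) ** 2).sum())
        return r2 * (1.0 - np.sqrt(abs(r2 - r02)))

    return one(y, yhat), one(yhat, y)


def concordance_correlation(y, yhat) -> float:
    """Lin's CCC with 1/n (biased) variances."""
    y, yhat = _as_pair(y, yhat)
    sy = y.var()
    syh = yhat.var()
    sxy = ((y - y.mean()) * (yhat - yhat.mean())).mean()
    return float(2 * sxy / (sy + syh + (y.mean() - yhat.mean()) ** 2))


def external_metrics(y_test, y_pred, y_train_mean: float) -> dict[str, float]:
    """All external-validation statistics for one test set.

    Returns keys rmsep, r2_pred, r2m_test, avg_r2m, delta_r2m, ccc, q2_f1,
    q2_f2, mae.
    """
    y, yhat = _as_pair(y_test, y_pred)
    if y.size < 3:
        raise ValueError("need at least 3 test samples")
    if np.ptp(y) == 0:
        raise ValueError("zero test-set variance")
    err2 = ((y - yhat) ** 2).sum()
    fwd, rev = _r2m_pair(y, yhat)
    return {
        "rmsep": float(np.sqrt(err2 / y.size)),
        "r2_pred": _pearson2(y, yhat),
        "r2m_test": float(fwd),
        "avg_r2m": float((fwd + rev) / 2.0),
        "delta_r2m": float(abs(fwd - rev)),
        "ccc": concordance_correlation(y, yhat),
        "q2_f1": float(1.0 - err2 / ((y - y_train_mean) ** 2).sum()),
        "q2_f2": float(1.0 - err2 / ((y - y.mean()) ** 2).sum()),
        "mae": float(np.abs(y - yhat).mean()),
    }


def y_randomization_summary(
    r2_cal: float,
    r2_yrand_cycles,
    rmse_yrand_cycles,
) -> tuple[float, float, float]:
    """(mean RMSE_y-rand, mean r2_y-rand, c_r2p).

    c_r2p = r * sqrt(r2 - mean r2_y-rand) with r = sqrt(r2_cal); a model
    whose randomized refits match or beat it gets 0 with a warning.
    """
    r2_yrand_cycles = np.asarray(r2_yrand_cycles, dtype=float)
    rmse_yrand_cycles = np.asarray(rmse_yrand_cycles, dtype=float)
    if r2_yrand_cycles.size < 1:
        raise ValueError("need at least one randomization cycle")
    mean_r2 = float(r2_yrand_cycles.mean())
    mean_rmse = float(rmse_yrand_cycles.mean())
    if r2_cal < mean_r2:
        warnings.warn(
            "calibration r2 below mean y-randomized r2; model is no better "
            "than chance (c_r2p reported as 0)",
            stacklevel=2,
        )
        return mean_rmse, mean_r2, 0.0
    c_r2p = float(np.sqrt(r2_cal) * np.sqrt(r2_cal - mean_r2))
    return mean_rmse, mean_r2, c_r2p


def williams_domain(model: pls_engine.PLSModel, X_all, y_all, ids=None) -> ADReport:
    """Leverage / standardized-residual screening with one assessment model.

    Standardized residuals divide by the RMSE of the assessment fit itself;
    the leverage threshold is h* = 3(A+1)/n.
    """
    y = np.asarray(y_all, dtype=float).ravel()
    if ids is None:
        ids = [str(i) for i in range(y.size)]
    h = pls_engine.leverage(model, X_all)
    resid = y - pls_engine.predict(model, X_all)
    rmse = float(np.sqrt((resid**2).mean()))
    if rmse == 0:
        std_resid = np.zeros_like(resid)
    else:
        std_resid = resid / rmse
    h_star = 3.0 * (model.A + 1) / y.size
    flagged = [
        ids[i]
        for i in range(y.size)
        if h[i] > h_star or abs(std_resid[i]) > RESIDUAL_CUTOFF
    ]
    return ADReport(list(ids), h, std_resid, float(h_star), RESIDUAL_CUTOFF, flagged)
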