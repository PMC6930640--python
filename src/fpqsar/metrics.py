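"""Validation statistics for QSAR regression models.

The statistics follow the conventions of the external-validation literature
for ligand-based QSAR:

* ``R2`` is the squared Pearson correlation between observed and predicted
  pIC50.  This is the form that feeds experimental-vs-predicted correlation
  plots and the rm2 machinery.  The alternative ``1 - SSE/SST`` form is
  exposed separately as :func:`press_q_squared` for PRESS-style
  cross-validated reporting; reports state which form they use.
* ``rm2`` / ``delta_rm2`` compare the correlation with and without forcing
  the regression through the origin.  With ``k = sum(y*yhat)/sum(yhat^2)``
  and ``r0^2 = 1 - sum((y - k*yhat)^2)/sum((y - ybar)^2)``, the forward
  metric is ``r^2 * (1 - sqrt(r^2 - r0^2))``; the reverse metric swaps the
  roles of observed and predicted.  The reported rm2 is the average of the
  two directions and delta_rm2 their absolute difference.
* A model is conventionally called acceptable when R2 > 0.6, Q2 > 0.5 and
  rm2 > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricSet",
    "r_squared",
    "press_q_squared",
    "rmse",
    "mae",
    "rm2_metrics",
    "metric_set",
    "is_acceptable",
]


@dataclass(frozen=True)
class MetricSet:
    """The five scalar statistics reported for one model on one partition."""

    R2: float
    RMSE: float
    MAE: float
    rm2: float
    delta_rm2: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R2": self.R2,
            "RMSE": self.RMSE,
            "MAE": self.MAE,
            "rm2": self.rm2,
            "delta_rm2": self.delta_rm2,
        }


def _validated_pair(observed, predicted, min_len: int = 1):
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError(
            f"length mismatch: observed has {obs.size}, predicted has {pred.size}"
        )
    if obs.size < min_len:
        raise ValueError(f"need at least {min_len} points, got {obs.size}")
    if not (np.isfinite(obs).all() and np.isfinite(pred).all()):
        raise ValueError("non-finite values in observed/predicted")
    return obs, pred


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted values.

    Raises if either vector is constant (the correlation is undefined).
    """
    obs, pred = _validated_pair(observed, predicted, min_len=2)
    so = obs.std()
    sp = pred.std()
    if so == 0.0:
        raise ValueError("observed vector is constant; R2 undefined")
    if sp == 0.0:
        raise ValueError("predicted vector is constant; R2 undefined")
    r = float(np.mean((obs - obs.mean()) * (pred - pred.mean())) / (so * sp))
    return r * r


def press_q_squared(observed, predicted) -> float:
    """``1 - SSE/SST`` coefficient of determination (PRESS form).

    Unlike :func:`r_squared` this can be negative for predictions worse
    than the mean; it is the form usually quoted for leave-out validation.
    """
    obs, pred = _validated_pair(observed, predicted, min_len=2)
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed vector is constant; Q2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def rmse(observed, predicted) -> float:
    """Root mean squared error, in response (pIC50) units."""
    obs, pred = _validated_pair(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mae(observed, predicted) -> float:
    """Mean absolute error, in response (pIC50) units."""
    obs, pred = _validated_pair(observed, predicted)
    return float(np.mean(np.abs(obs - pred)))


def _rm2_oneway(y: np.ndarray, yhat: np.ndarray) -> float:
    # slope of the least-squares fit through the origin of y on yhat
    denom = float(np.sum(yhat * yhat))
    if denom == 0.0:
        raise ValueError("all-zero vector; rm2 undefined")
    k = float(np.sum(y * yhat)) / denom
    sst = float(np.sum((y - y.mean()) ** 2))
    r0sq = 1.0 - float(np.sum((y - k * yhat) ** 2)) / sst
    rsq = r_squared(y, yhat)
    # rsq - r0sq can dip below zero by floating error on near-perfect fits
    gap = max(rsq - r0sq, 0.0)
    return rsq * (1.0 - np.sqrt(gap))


def rm2_metrics(observed, predicted) -> tuple[float, float]:
    """Average rm2 and delta_rm2 over the forward and reverse directions.

    Returns ``(rm2, delta_rm2)`` where rm2 is the mean of the forward
    (observed on predicted) and reverse (predicted on observed) metrics and
    delta_rm2 their absolute difference.
    """
    obs, pred = _validated_pair(observed, predicted, min_len=2)
    if obs.std() == 0.0 or pred.std() == 0.0:
        raise ValueError("constant vector; rm2 undefined")
    fwd = _rm2_oneway(obs, pred)
    rev = _rm2_oneway(pred, obs)
    return (fwd + rev) / 2.0, abs(fwd - rev)


def metric_set(predictions) -> MetricSet:
    """Compute all five statistics on one prediction set.

    ``predictions`` is either an object with ``observed``/``predicted``
    attributes (a PredictionSet) or an ``(observed, predicted)`` pair.
    """
    if hasattr(predictions, "observed"):
        obs, pred = predictions.observed, predictions.predicted
    else:
        obs, pred = predictions
    rm2, d_rm2 = rm2_metrics(obs, pred)
    return MetricSet(
        R2=r_squared(obs, pred),
        RMSE=rmse(obs, pred),
        MAE=mae(obs, pred),
        rm2=rm2,
        delta_rm2=d_rm2,
    )


def is_acceptable(r2: float, q2: float, rm2: float) -> bool:
    """Conventional QSAR acceptability: R2 > 0.6, Q2 > 0.5 and rm2 > 0.5."""
    return r2 > 0.6 and q2 > 0.5 and rm2 > 0.5
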