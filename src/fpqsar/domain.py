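"""Leverage-based applicability domain (Williams plot) for QSAR models.

The leverage of a compound is the diagonal element of the hat (projection)
matrix of the intercept-augmented training design,
``h_i = x_i (X'X)^-1 x_i'`` — the Mahalanobis-like distance of the
compound from the training-set centroid in descriptor space.  Predictions
are flagged unreliable beyond the warning leverage

    h* = 3 (p + 1) / n

(p descriptors, n training compounds) or when the standardized prediction
residual leaves the +/-3 band.  Both thresholds are strict: boundary
compounds are in-domain.

Leverages are computed from a QR decomposition of the augmented design —
never an explicit inverse — and a rank-deficient design raises (leverage
is undefined; filter collinear descriptors first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "ADResult",
    "warning_leverage",
    "leverages",
    "standardized_residuals",
    "williams_classify",
]

FLAGS = ("in_domain", "leverage_outlier", "residual_outlier", "both")


@dataclass
class ADResult:
    """Williams-plot data: per-compound leverage, standardized residual, flag."""

    leverages: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    p: int
    n: int
    flags: np.ndarray  # strings from FLAGS

    @property
    def counts(self) -> dict[str, int]:
        return {f: int((self.flags == f).sum()) for f in FLAGS}

    def to_dataframe(self, ids=None, partition=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "leverage": self.leverages,
                "std_residual": self.std_residuals,
                "flag": self.flags,
            }
        )
        if ids is not None:
            df.insert(0, "compound_id", list(ids))
        if partition is not None:
            part = [partition] * len(df) if isinstance(partition, str) else list(partition)
            df.insert(1 if ids is not None else 0, "partition", part)
        return df


def warning_leverage(p: int, n: int) -> float:
    """Warning leverage h* = 3 (p + 1) / n."""
    if n <= 0:
        raise ValueError(f"training-set size must be positive, got {n}")
    if p < 0:
        raise ValueError(f"descriptor count must be nonnegative, got {p}")
    return 3.0 * (p + 1) / n


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.hstack([np.ones((X.shape[0], 1)), X])


def leverages(X_train, X_query=None) -> np.ndarray:
    """Hat-matrix diagonals for query rows against a training design.

    With ``X_query=None`` the training leverages themselves are returned
    (they sum to p + 1 for a full-rank intercept-augmented design).
    """
    A = _augment(X_train)
    n, q = A.shape
    if n < q:
        raise ValueError(f"need at least p+1={q} training rows, got {n}")
    R = np.linalg.qr(A, mode="r")
    diag = np.abs(np.diag(R))
    if diag.min() <= max(n, q) * np.finfo(float).eps * diag.max():
        raise np.linalg.LinAlgError(
            "rank-deficient descriptor matrix: leverage is undefined; "
            "remove collinear/constant descriptors (correlation filter) first"
        )
    B = _augment(X_train) if X_query is None else _augment(np.asarray(X_query))
    if B.shape[1] != q:
        raise ValueError(f"query has {B.shape[1] - 1} columns, training has {q - 1}")
    # h_i = || R^-T b_i ||^2  since (A'A)^-1 = R^-1 R^-T
    W = linalg.solve_triangular(R.T, B.T, lower=True)
    return np.einsum("ij,ij->j", W, W)


def standardized_residuals(observed, predicted, scale: float | None = None) -> np.ndarray:
    """Residuals divided by the training residual standard deviation.

    ``scale`` supplies the training s when standardizing test residuals;
    left as None, s is the sample sd (ddof=1) of these residuals.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 2 and scale is None:
        raise ValueError("need at least 2 residuals to estimate their scale")
    resid = obs - pred
    s = float(np.std(resid, ddof=1)) if scale is None else float(scale)
    if s <= 0.0 or not np.isfinite(s):
        raise ValueError("residual scale is zero or non-finite; cannot standardize")
    return resid / s


def williams_classify(
    leverages_: np.ndarray,
    std_residuals_: np.ndarray,
    h_star: float,
    p: int | None = None,
    residual_band: float = 3.0,
) -> ADResult:
    """Flag each compound by its position in the Williams plot.

    Strict thresholds: ``h > h*`` and ``|residual| > residual_band``;
    compounds sitting exactly on a boundary are in-domain.
    """
    h = np.asarray(leverages_, dtype=float).ravel()
    r = np.asarray(std_residuals_, dtype=float).ravel()
    if h.shape != r.shape:
        raise ValueError("leverage and residual vectors differ in length")
    lev_out = h > h_star
    res_out = np.abs(r) > residual_band
    flags = np.where(
        lev_out & res_out,
        "both",
        np.where(lev_out, "leverage_outlier", np.where(res_out, "residual_outlier", "in_domain")),
    )
    return ADResult(
        leverages=h,
        std_residuals=r,
        h_star=float(h_star),
        p=int(p) if p is not None else -1,
        n=len(h),
        flags=flags,
    )
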