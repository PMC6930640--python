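"""Fingerprint-count descriptor tables and collinearity filtering.

Descriptors are nonnegative integer counts of predefined substructures
(SubFPC-style), one row per compound.  Tables are exchanged in the PaDEL
CSV dialect: first column ``Name`` holds the compound identifier, every
remaining column is one numeric descriptor.

Highly correlated descriptor pairs are pruned with the greedy
mean-absolute-correlation heuristic: while any pair exceeds the cutoff in
absolute Pearson correlation, the member of the worst offending pair with
the larger mean absolute correlation against all surviving columns is
dropped.  Zero-variance columns are removed up front (their correlation is
undefined).  The kept set is guaranteed, and asserted, to have all pairwise
|r| <= cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorMatrix",
    "FilterResult",
    "read_padel_csv",
    "write_padel_csv",
    "select_features",
]


@dataclass
class DescriptorMatrix:
    """Compounds x named descriptor counts.

    ids and feature_names are ordered and unique; values is an
    ``(n, p)`` array of nonnegative numbers (integer counts in normal use).
    """

    ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if n != len(self.ids):
            raise ValueError(f"{len(self.ids)} ids but {n} rows")
        if p != len(self.feature_names):
            raise ValueError(f"{len(self.feature_names)} feature names but {p} columns")
        if len(set(self.ids)) != len(self.ids):
            dup = pd.Index(self.ids)[pd.Index(self.ids).duplicated()][0]
            raise ValueError(f"duplicate compound id: {dup!r}")
        if len(set(self.feature_names)) != len(self.feature_names):
            dup = pd.Index(self.feature_names)[
                pd.Index(self.feature_names).duplicated()
            ][0]
            raise ValueError(f"duplicate feature name: {dup!r}")
        if not np.isfinite(self.values.astype(float)).all():
            raise ValueError("non-finite descriptor values")
        if (self.values.astype(float) < 0).any():
            raise ValueError("negative descriptor counts")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.ids, name="Name"), columns=self.feature_names
        )

    def subset_features(self, indices) -> "DescriptorMatrix":
        idx = list(indices)
        return DescriptorMatrix(
            ids=list(self.ids),
            feature_names=[self.feature_names[i] for i in idx],
            values=self.values[:, idx],
        )

    def subset_compounds(self, ids: list[str]) -> "DescriptorMatrix":
        pos = {cid: i for i, cid in enumerate(self.ids)}
        missing = [cid for cid in ids if cid not in pos]
        if missing:
            raise KeyError(f"ids absent from descriptor matrix: {missing[:5]}")
        rows = [pos[cid] for cid in ids]
        return DescriptorMatrix(
            ids=list(ids), feature_names=list(self.feature_names),
            values=self.values[rows, :],
        )


def read_padel_csv(path) -> DescriptorMatrix:
    """Read a PaDEL-dialect descriptor CSV (first column = compound name)."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a Name column plus at least one descriptor")
    name_col = df.columns[0]
    ids = df[name_col].astype(str).tolist()
    dup = df[name_col][df[name_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate compound name {dup.iloc[0]!r}")
    feats = df.drop(columns=[name_col])
    for col in feats.columns:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        bad = coerced.isna() & feats[col].notna()
        if bad.any():
            row = ids[int(np.flatnonzero(bad)[0])]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        if coerced.isna().any():
            row = ids[int(np.flatnonzero(coerced.isna())[0])]
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        feats[col] = coerced
    values = feats.to_numpy()
    if np.allclose(values, np.round(values)):
        values = np.round(values).astype(np.int64)
    return DescriptorMatrix(ids=ids, feature_names=list(feats.columns), values=values)


def write_padel_csv(matrix: DescriptorMatrix, path) -> None:
    """Write a descriptor matrix in the PaDEL CSV dialect."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_dataframe().to_csv(path, index=True)


@dataclass
class FilterResult:
    """Outcome of the pairwise-correlation filter.

    ``removals`` records, per dropped column, the partner it was paired
    with and the |r| of that pair at the moment of removal, so the decision
    trail can be audited or replayed.
    """

    kept: list[int]
    removed: list[int]
    cutoff: float
    zero_variance: list[int] = field(default_factory=list)
    removals: list[dict] = field(default_factory=list)

    def report(self, feature_names: list[str] | None = None) -> dict:
        name = (lambda i: feature_names[i]) if feature_names else (lambda i: i)
        return {
            "cutoff": self.cutoff,
            "n_kept": len(self.kept),
            "n_removed": len(self.removed),
            "kept": [name(i) for i in self.kept],
            "zero_variance": [name(i) for i in self.zero_variance],
            "removals": [
                {
                    "feature": name(r["column"]),
                    "partner": name(r["partner"]),
                    "abs_r": r["abs_r"],
                    "mean_abs_corr": r["mean_abs_corr"],
                }
                for r in self.removals
            ],
        }


def select_features(X, cutoff: float = 0.7) -> FilterResult:
    """Greedy removal of collinear descriptor columns.

    ``X`` is a DescriptorMatrix or an ``(n, p)`` array with n >= 3.
    Returns a partition of the column indices into kept and removed sets;
    pairs with |r| exactly equal to the cutoff are retained (the filter
    triggers on strict ``|r| > cutoff``).  Deterministic: the worst pair is
    processed first and ties remove the later column in input order.
    """
    values = X.values if isinstance(X, DescriptorMatrix) else np.asarray(X)
    values = values.astype(float)
    n, p = values.shape
    if n < 3:
        raise ValueError(f"need at least 3 rows for stable correlations, got {n}")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")

    variances = values.var(axis=0)
    zero_var = [int(i) for i in np.flatnonzero(variances == 0.0)]
    active = [i for i in range(p) if variances[i] > 0.0]
    removals: list[dict] = []

    if len(active) >= 2:
        corr = np.corrcoef(values[:, active], rowvar=False)
        abs_corr = np.abs(corr)
        np.fill_diagonal(abs_corr, 0.0)
        # positions into `active`; shrink both as columns fall
        while abs_corr.shape[0] >= 2:
            flat = int(np.argmax(abs_corr))
            i, j = divmod(flat, abs_corr.shape[0])
            worst = abs_corr[i, j]
            if worst <= cutoff:
                break
            if i > j:
                i, j = j, i
            mean_i = abs_corr[i].sum() / (abs_corr.shape[0] - 1)
            mean_j = abs_corr[j].sum() / (abs_corr.shape[0] - 1)
            # tie -> drop the later column in input order (j)
            drop, partner, m = (i, j, mean_i) if mean_i > mean_j else (j, i, mean_j)
            removals.append(
                {
                    "column": active[drop],
                    "partner": active[partner],
                    "abs_r": float(worst),
                    "mean_abs_corr": float(m),
                }
            )
            del active[drop]
            abs_corr = np.delete(np.delete(abs_corr, drop, axis=0), drop, axis=1)

    kept = sorted(active)
    removed = sorted(set(range(p)) - set(kept))

    # postcondition: surviving set has no supra-cutoff pair
    if len(kept) >= 2:
        check = np.abs(np.corrcoef(values[:, kept], rowvar=False))
        np.fill_diagonal(check, 0.0)
        assert check.max() <= cutoff + 1e-12, "correlation filter postcondition failed"

    return FilterResult(
        kept=kept,
        removed=removed,
        cutoff=cutoff,
        zero_variance=zero_var,
        removals=removals,
    )
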