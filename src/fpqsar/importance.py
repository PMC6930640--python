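"""Aggregation of per-run random-forest variable importances.

A single forest's importance ranking depends on its random seed; the
stable quantity is the mean (with sample sd) of the raw node-purity
("Gini") importance across many independently seeded protocol runs.
Features are ranked by descending mean; known SubFPC descriptor names are
annotated with their substructure descriptions from the shipped lookup
table.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["aggregate_importance", "top_features", "load_subfpc_descriptions"]


def load_subfpc_descriptions() -> dict[str, str]:
    """Name -> substructure description for the SubFPC descriptor family."""
    path = resources.files("fpqsar.data").joinpath("subfpc_descriptions.csv")
    with path.open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["fingerprint"], df["description"]))


def aggregate_importance(
    per_run_scores, feature_names: list[str]
) -> pd.DataFrame:
    """Mean +/- sd importance over runs, ranked by descending mean.

    ``per_run_scores`` is an (n_runs, p) array or list of per-feature
    vectors; at least two runs are required.  Ties in the mean are broken
    by feature-name lexicographic order.  Returns a DataFrame with columns
    feature, mean_gini, sd_gini, rank, sorted by rank.
    """
    arr = np.asarray(per_run_scores, dtype=float)
    if arr.ndim != 2:
        raise ValueError("per_run_scores must be a runs x features array")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 runs to aggregate")
    if arr.shape[1] != len(feature_names):
        raise ValueError(
            f"{arr.shape[1]} score columns but {len(feature_names)} feature names"
        )
    table = pd.DataFrame(
        {
            "feature": list(feature_names),
            "mean_gini": arr.mean(axis=0),
            "sd_gini": arr.std(axis=0, ddof=1),
        }
    )
    table = table.sort_values(
        ["mean_gini", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_features(
    table: pd.DataFrame, k: int, descriptions: dict[str, str] | None = None
) -> pd.DataFrame:
    """First k rows by rank, annotated with substructure descriptions."""
    p = len(table)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    if descriptions is None:
        descriptions = load_subfpc_descriptions()
    out = table.nsmallest(k, "rank").copy()
    out["description"] = [descriptions.get(f, "") for f in out["feature"]]
    return out.reset_index(drop=True)
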