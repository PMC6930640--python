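"""Tanimoto similarity and binning clustering for scaffold prioritization.

Compounds are grouped by binning clustering: a threshold graph is built
with an edge wherever the pairwise Tanimoto similarity reaches the cutoff
(0.8 by default), and clusters are its connected components — any compound
similar enough to one member joins that member's bin.  Singletons and
small bins carry little scaffold information and are dropped (default
retention N >= 20); surviving clusters are summarized (mean +/- sd of
pIC50, MW, ALogP) and prioritized by how far the cluster's mean potency
sits above the whole-dataset mean.

Tanimoto similarity is computed on presence/absence bits by default; a
count-based (min/max) variant is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .features import DescriptorMatrix

__all__ = [
    "ClusterSummary",
    "tanimoto",
    "pairwise_tanimoto",
    "bin_cluster",
    "summarize_clusters",
    "prioritize",
]


@dataclass
class ClusterSummary:
    cluster_id: int
    member_ids: list[str]
    N: int
    mean_pic50: float
    sd_pic50: float
    mean_mw: float | None
    sd_mw: float | None
    mean_alogp: float | None
    sd_alogp: float | None
    delta_vs_dataset: float

    def as_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "N": self.N,
            "mean_pic50": self.mean_pic50,
            "sd_pic50": self.sd_pic50,
            "mean_mw": self.mean_mw,
            "sd_mw": self.sd_mw,
            "mean_alogp": self.mean_alogp,
            "sd_alogp": self.sd_alogp,
            "delta_vs_dataset": self.delta_vs_dataset,
            "member_ids": self.member_ids,
        }


def tanimoto(fp_a, fp_b, count_based: bool = False) -> float:
    """Tanimoto similarity of two fingerprint vectors.

    Counts are binarized to presence/absence unless ``count_based``, in
    which case the min/max generalization is used.  Undefined (raises) if
    both fingerprints are empty.
    """
    a = np.asarray(fp_a, dtype=float).ravel()
    b = np.asarray(fp_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    if count_based:
        union = float(np.maximum(a, b).sum())
        if union == 0.0:
            raise ValueError("both fingerprints are all-zero; similarity undefined")
        return float(np.minimum(a, b).sum()) / union
    ab = a > 0
    bb = b > 0
    union = int(np.logical_or(ab, bb).sum())
    if union == 0:
        raise ValueError("both fingerprints are all-zero; similarity undefined")
    return float(np.logical_and(ab, bb).sum()) / union


def pairwise_tanimoto(values, count_based: bool = False) -> np.ndarray:
    """Dense pairwise Tanimoto similarity matrix.

    Pairs where either fingerprint is all-zero get similarity 0 (an empty
    fingerprint resembles nothing); the diagonal is 1.
    """
    V = np.asarray(values, dtype=float)
    if count_based:
        n = V.shape[0]
        sim = np.zeros((n, n))
        for i in range(n):
            mins = np.minimum(V[i], V[i + 1 :]).sum(axis=1)
            maxs = np.maximum(V[i], V[i + 1 :]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.where(maxs > 0, mins / maxs, 0.0)
            sim[i, i + 1 :] = s
            sim[i + 1 :, i] = s
        np.fill_diagonal(sim, 1.0)
        return sim
    B = (V > 0).astype(np.float64)
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def bin_cluster(fps, cutoff: float = 0.8, count_based: bool = False) -> np.ndarray:
    """Binning clustering: connected components of the similarity >= cutoff graph.

    ``fps`` is a DescriptorMatrix or (n, p) array.  Returns integer labels
    (singletons included as size-1 clusters); label 0 is the largest
    cluster, ties broken by smallest member index.
    """
    values = fps.values if isinstance(fps, DescriptorMatrix) else np.asarray(fps)
    n = values.shape[0]
    if n == 0:
        raise ValueError("need at least one compound")
    sim = pairwise_tanimoto(values, count_based=count_based)
    adj = csr_matrix(sim >= cutoff)
    _, raw = connected_components(adj, directed=False)
    # relabel: decreasing component size, then smallest member index
    comp_ids, sizes = np.unique(raw, return_counts=True)
    first_member = np.array([int(np.flatnonzero(raw == c)[0]) for c in comp_ids])
    order = np.lexsort((first_member, -sizes))
    remap = {int(comp_ids[c]): rank for rank, c in enumerate(order)}
    return np.array([remap[int(c)] for c in raw], dtype=int)


def summarize_clusters(
    labels,
    compounds: pd.DataFrame,
    min_size: int = 20,
    dataset_mean: float | None = None,
) -> list[ClusterSummary]:
    """Per-cluster potency/property summaries for retained clusters.

    Singletons and clusters below ``min_size`` members are dropped.
    ``compounds`` must align row-wise with ``labels`` and carry
    compound_id and pIC50 (MW / ALogP summarized when present).
    ``delta_vs_dataset`` compares the cluster's mean pIC50 to the full
    dataset mean (all compounds, including unclustered ones) unless an
    explicit ``dataset_mean`` — e.g. the curated modelling set's mean —
    is supplied.
    """
    labels = np.asarray(labels)
    if len(labels) != len(compounds):
        raise ValueError("labels and compounds are not aligned")
    if dataset_mean is None:
        dataset_mean = float(compounds["pIC50"].mean())

    def stat(series) -> tuple[float | None, float | None]:
        if series is None:
            return None, None
        vals = pd.to_numeric(series, errors="coerce").dropna()
        if not len(vals):
            return None, None
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd

    summaries = []
    for cid in np.unique(labels):
        if cid < 0:
            continue
        members = np.flatnonzero(labels == cid)
        if len(members) < max(min_size, 2):
            continue
        sub = compounds.iloc[members]
        mean_p, sd_p = stat(sub["pIC50"])
        mean_mw, sd_mw = stat(sub["MW"] if "MW" in sub else None)
        mean_lp, sd_lp = stat(sub["ALogP"] if "ALogP" in sub else None)
        summaries.append(
            ClusterSummary(
                cluster_id=int(cid),
                member_ids=sub["compound_id"].astype(str).tolist(),
                N=int(len(members)),
                mean_pic50=mean_p,
                sd_pic50=sd_p,
                mean_mw=mean_mw,
                sd_mw=sd_mw,
                mean_alogp=mean_lp,
                sd_alogp=sd_lp,
                delta_vs_dataset=float(mean_p - dataset_mean),
            )
        )
    return summaries


def prioritize(summaries: list[ClusterSummary]) -> list[ClusterSummary]:
    """Rank clusters by excess potency over the dataset mean.

    Descending delta_vs_dataset; ties by larger N, then smaller cluster id.
    """
    if not summaries:
        raise ValueError("no cluster summaries to prioritize")
    return sorted(
        summaries, key=lambda s: (-s.delta_vs_dataset, -s.N, s.cluster_id)
    )
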