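"""Synthetic inputs with known ground truth for the QSAR pipeline.

The generator emulates the shape of a kinase-inhibitor modelling study
without any chemistry: a nonnegative-integer substructure-count matrix
(optionally with planted collinear column blocks), a pIC50 response from a
sparse linear model plus Gaussian noise, a raw bioactivity table
contaminated with the defects real extracts carry (non-IC50 endpoints,
qualified values, missing values, mixed units, replicate measurements),
and sets of mutually similar binary fingerprints arranged in planted
scaffold clusters.  Every generator is bit-reproducible from its seed, and
each returns (or embeds) the ground truth a downstream recovery test needs.

Compound identifiers are synthetic placeholders ("SYN000001", ...); no
attempt is made to produce chemically valid SMILES.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import DescriptorMatrix

__all__ = [
    "SyntheticSpec",
    "generate_fingerprint_matrix",
    "generate_activity",
    "noise_sd_for_r2",
    "generate_raw_records",
    "records_for_compounds",
    "generate_properties",
    "generate_clustered_fingerprints",
    "generate_clustered_dataset",
    "write_bioactivity_csv",
    "write_ground_truth_json",
]

#: default anchor for the mean generated pIC50 — mid-range of typical
#: kinase-inhibitor cluster means; cosmetic realism only, configurable.
TARGET_MEAN_PIC50 = 6.5

RECORD_COLUMNS = ["compound_id", "smiles", "standard_type", "relation", "value", "unit"]

CONTAMINATION_KINDS = ("non_ic50", "qualifier", "missing", "micromolar", "duplicate")


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic QSAR dataset.

    collinear_blocks entries are ``(source index, duplicate count,
    correlation target)``; duplicates are appended as the trailing columns
    of the matrix, so the base (independently drawn) columns are the first
    ``n_features - sum(duplicate counts)``.
    """

    n_compounds: int
    n_features: int
    informative_idx: list[int] = field(default_factory=list)
    coefficients: list[float] = field(default_factory=list)
    noise_sd: float = 0.5
    collinear_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    cluster_plan: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0
    base_lambda: float = 2.0
    count_cap: int = 10
    target_mean_pic50: float = TARGET_MEAN_PIC50

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise ValueError(f"n_compounds must be positive, got {self.n_compounds}")
        if self.n_features <= 0:
            raise ValueError(f"n_features must be positive, got {self.n_features}")
        if len(self.informative_idx) != len(self.coefficients):
            raise ValueError("informative_idx and coefficients must have equal length")
        for i in self.informative_idx:
            if not 0 <= i < self.n_features:
                raise ValueError(f"informative index {i} outside [0, {self.n_features})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        sources = [b[0] for b in self.collinear_blocks]
        if len(set(sources)) != len(sources):
            raise ValueError("duplicate source indices in collinear_blocks")
        n_dups = sum(int(b[1]) for b in self.collinear_blocks)
        n_base = self.n_features - n_dups
        if n_base < 1:
            raise ValueError("collinear duplicates leave no base columns")
        for src, cnt, r in self.collinear_blocks:
            if not 0 <= src < n_base:
                raise ValueError(f"block source {src} outside base columns [0, {n_base})")
            if cnt < 1:
                raise ValueError("duplicate count must be >= 1")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"correlation target {r} outside [0, 1]")

    @property
    def n_base_features(self) -> int:
        return self.n_features - sum(int(b[1]) for b in self.collinear_blocks)


def _ids(n: int, prefix: str = "SYN") -> list[str]:
    return [f"{prefix}{i + 1:06d}" for i in range(n)]


def generate_fingerprint_matrix(spec: SyntheticSpec) -> DescriptorMatrix:
    """Draw a count matrix: truncated-Poisson base columns + collinear blocks.

    Base cells are Poisson(base_lambda) clipped at count_cap.  Each
    collinear block appends noisy integer copies of its source column: the
    jitter standard deviation is solved from the variance identity
    ``r = sd(x) / sqrt(sd(x)^2 + sd(e)^2)`` and then shrunk until the
    empirical correlation meets the target (rounding and clipping eat some
    correlation, so the analytic solution is only a starting point).
    """
    rng = np.random.default_rng(spec.seed)
    n, p_base = spec.n_compounds, spec.n_base_features
    base = np.minimum(rng.poisson(spec.base_lambda, size=(n, p_base)), spec.count_cap)
    columns = [base]
    names = [f"FP{i + 1:03d}" for i in range(p_base)]
    for src, cnt, r_target in spec.collinear_blocks:
        src_col = base[:, src].astype(float)
        v = src_col.var()
        for d in range(cnt):
            names.append(f"FP{src + 1:03d}dup{d + 1}")
            if r_target >= 1.0 or v == 0.0:
                columns.append(src_col.astype(np.int64)[:, None])
                continue
            sd = np.sqrt(v * (1.0 / r_target**2 - 1.0))
            dup = None
            for _ in range(12):  # shrink jitter until the target holds
                cand = np.clip(
                    np.round(src_col + rng.normal(0.0, sd, size=n)), 0, spec.count_cap
                ).astype(np.int64)
                if cand.std() > 0 and abs(np.corrcoef(src_col, cand)[0, 1]) >= r_target:
                    dup = cand
                    break
                sd *= 0.8
            if dup is None:  # degenerate column; fall back to an exact copy
                dup = src_col.astype(np.int64)
            columns.append(dup[:, None])
    values = np.hstack([c if c.ndim == 2 else c[:, None] for c in columns])
    return DescriptorMatrix(ids=_ids(n), feature_names=names, values=values)


def generate_activity(
    X: DescriptorMatrix, spec: SyntheticSpec, intercept: float | None = None
) -> np.ndarray:
    """pIC50 response: sparse linear signal over the count matrix + noise.

    ``y_i = intercept + sum_j coeff_j * X[i, informative_j] + eps_i`` with
    ``eps ~ N(0, noise_sd^2)``.  When ``intercept`` is None it is anchored
    so the mean response sits at ``spec.target_mean_pic50``.
    """
    for i in spec.informative_idx:
        if i >= X.n_features:
            raise ValueError(f"informative index {i} outside matrix with p={X.n_features}")
    signal = np.zeros(X.n_compounds)
    if spec.informative_idx:
        signal = X.values[:, spec.informative_idx].astype(float) @ np.asarray(
            spec.coefficients, dtype=float
        )
    if intercept is None:
        intercept = spec.target_mean_pic50 - float(signal.mean())
    rng = np.random.default_rng([spec.seed, 7])
    return intercept + signal + rng.normal(0.0, spec.noise_sd, size=X.n_compounds)


def noise_sd_for_r2(X: DescriptorMatrix, spec: SyntheticSpec, target_r2: float) -> float:
    """Noise level at which the oracle (noiseless-signal) R2 equals target_r2.

    From the variance decomposition ``R2 = V / (V + sd^2)`` with V the
    empirical variance of the noiseless signal.
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must lie in (0, 1)")
    signal = X.values[:, spec.informative_idx].astype(float) @ np.asarray(
        spec.coefficients, dtype=float
    )
    v = float(signal.var())
    if v == 0.0:
        raise ValueError("signal has zero variance; no noise level achieves target R2")
    return float(np.sqrt(v * (1.0 - target_r2) / target_r2))


def _planned_counts(n: int, fractions: dict[str, float]) -> dict[str, int]:
    unknown = set(fractions) - set(CONTAMINATION_KINDS)
    if unknown:
        raise ValueError(f"unknown contamination kinds: {sorted(unknown)}")
    for kind, f in fractions.items():
        if f < 0:
            raise ValueError(f"negative proportion for {kind!r}: {f}")
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ValueError("contamination fractions sum to more than 1")
    counts = {k: int(round(n * fractions.get(k, 0.0))) for k in CONTAMINATION_KINDS}
    if sum(counts.values()) > n:
        raise ValueError("planned contamination counts exceed n")
    return counts


def generate_raw_records(
    n: int, seed: int, fractions: dict[str, float] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Raw bioactivity table with planned contamination, plus ground truth.

    Fraction keys (each a proportion of n, summing to <= 1):

    * ``non_ic50`` — standard_type is Ki / EC50 / % inhibition (removed by
      the endpoint filter);
    * ``qualifier`` — relation is ">" or "<" (removed);
    * ``missing`` — value absent (removed);
    * ``micromolar`` — value expressed in uM instead of nM (kept; exercises
      unit conversion);
    * ``duplicate`` — replicate measurement of another clean compound, value
      jittered within the replicate-concordance window (kept by the filter,
      merged by aggregation).

    Returns ``(records, truth)`` where truth carries the planned number of
    filter survivors and of unique compounds after replicate aggregation.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    fractions = fractions or {}
    counts = _planned_counts(n, fractions)
    n_clean_slots = n - counts["duplicate"]
    if counts["duplicate"] > 0 and n_clean_slots - sum(
        counts[k] for k in ("non_ic50", "qualifier", "missing")
    ) < counts["duplicate"]:
        raise ValueError("not enough clean records to host the planned duplicates")

    rng = np.random.default_rng(seed)
    pic50 = rng.normal(TARGET_MEAN_PIC50, 1.0, size=n_clean_slots)
    ids = _ids(n_clean_slots)
    rows = [
        {
            "compound_id": ids[i],
            "smiles": "",
            "standard_type": "IC50",
            "relation": "=",
            "value": float(10.0 ** (9.0 - pic50[i])),  # nM
            "unit": "nM",
        }
        for i in range(n_clean_slots)
    ]

    # assign contamination kinds to disjoint record slots
    order = rng.permutation(n_clean_slots)
    pos = 0
    slots: dict[str, np.ndarray] = {}
    for kind in ("non_ic50", "qualifier", "missing", "micromolar"):
        slots[kind] = order[pos : pos + counts[kind]]
        pos += counts[kind]
    # surviving records (untouched or micromolar) can host replicates
    clean_pool = np.concatenate([order[pos:], slots["micromolar"]])

    alt_types = ["Ki", "EC50", "% inhibition"]
    for j, i in enumerate(slots["non_ic50"]):
        rows[i]["standard_type"] = alt_types[j % len(alt_types)]
    for j, i in enumerate(slots["qualifier"]):
        rows[i]["relation"] = ">" if j % 2 == 0 else "<"
    for i in slots["missing"]:
        rows[i]["value"] = None
    for i in slots["micromolar"]:
        rows[i]["value"] = rows[i]["value"] / 1000.0
        rows[i]["unit"] = "uM"

    hosts = clean_pool[: counts["duplicate"]]
    for i in hosts:
        jitter = rng.uniform(-0.3, 0.3)  # within the 1.0 log-unit concordance window
        rows.append(
            {
                "compound_id": rows[i]["compound_id"],
                "smiles": "",
                "standard_type": "IC50",
                "relation": "=",
                "value": float(rows[i]["value"] * 10.0**jitter),
                "unit": rows[i]["unit"],
            }
        )

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = records.iloc[rng.permutation(len(records))].reset_index(drop=True)
    n_removed = counts["non_ic50"] + counts["qualifier"] + counts["missing"]
    truth = {
        "n_records": int(n),
        "planned_counts": counts,
        "n_survivors": int(n - n_removed),
        "n_unique_compounds": int(n - n_removed - counts["duplicate"]),
    }
    return records, truth


def records_for_compounds(
    ids: list[str],
    pic50: np.ndarray,
    seed: int,
    fractions: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Bioactivity records for a fixed compound set with known pIC50.

    Every compound gets one clean IC50 record encoding its pIC50 in nM (or
    uM for the ``micromolar`` fraction); ``non_ic50`` / ``qualifier`` /
    ``missing`` fractions append EXTRA doomed records for the same
    compounds, and ``duplicate`` appends within-concordance replicates —
    so all listed compounds survive curation and their medians stay close
    to the planted response.
    """
    fractions = fractions or {}
    n = len(ids)
    counts = _planned_counts(n, fractions)
    rng = np.random.default_rng(seed)
    micro = set(rng.choice(n, size=counts["micromolar"], replace=False).tolist())
    rows = []
    for i, cid in enumerate(ids):
        nm = float(10.0 ** (9.0 - pic50[i]))
        if i in micro:
            rows.append(dict(compound_id=cid, smiles="", standard_type="IC50",
                             relation="=", value=nm / 1000.0, unit="uM"))
        else:
            rows.append(dict(compound_id=cid, smiles="", standard_type="IC50",
                             relation="=", value=nm, unit="nM"))
    alt_types = ["Ki", "EC50", "% inhibition"]
    for j in range(counts["non_ic50"]):
        i = int(rng.integers(n))
        rows.append(dict(compound_id=ids[i], smiles="",
                         standard_type=alt_types[j % 3], relation="=",
                         value=float(rng.uniform(1, 1e4)), unit="nM"))
    for j in range(counts["qualifier"]):
        i = int(rng.integers(n))
        rows.append(dict(compound_id=ids[i], smiles="", standard_type="IC50",
                         relation=">" if j % 2 == 0 else "<",
                         value=float(rng.uniform(1, 1e4)), unit="nM"))
    for _ in range(counts["missing"]):
        i = int(rng.integers(n))
        rows.append(dict(compound_id=ids[i], smiles="", standard_type="IC50",
                         relation="=", value=None, unit="nM"))
    for _ in range(counts["duplicate"]):
        i = int(rng.integers(n))
        jitter = rng.uniform(-0.3, 0.3)
        rows.append(dict(compound_id=ids[i], smiles="", standard_type="IC50",
                         relation="=",
                         value=float(10.0 ** (9.0 - pic50[i] + jitter)), unit="nM"))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    records = records.iloc[rng.permutation(len(records))].reset_index(drop=True)
    truth = {
        "n_records": len(records),
        "planned_counts": counts,
        "n_survivors": int(n + counts["duplicate"]),
        "n_unique_compounds": int(n),
    }
    return records, truth


def generate_properties(ids: list[str], seed: int) -> pd.DataFrame:
    """Lipinski-style property table (MW, ALogP, nHBDon, nHBAcc).

    Centred on the drug-like region typical of kinase-inhibitor sets
    (MW ~ 420 Da, ALogP ~ 3); purely cosmetic for chemical-space summaries.
    """
    rng = np.random.default_rng([seed, 11])
    n = len(ids)
    return pd.DataFrame(
        {
            "compound_id": ids,
            "MW": np.round(rng.normal(420.0, 70.0, n).clip(150, 900), 2),
            "ALogP": np.round(rng.normal(3.0, 1.2, n), 2),
            "nHBDon": rng.integers(0, 6, n),
            "nHBAcc": rng.integers(2, 11, n),
        }
    )


def generate_clustered_fingerprints(
    plan: list[tuple[int, float]],
    n_singletons: int,
    seed: int,
    bits_on: int = 120,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Binary fingerprints with planted similarity clusters.

    Each planned cluster ``(size, similarity_target)`` occupies its own
    disjoint bit region: a prototype with ``bits_on`` set bits, and members
    that clear d prototype bits and set d member-private bits, with d
    bounded so any two members' Tanimoto similarity stays >= the target
    (worst case ``(k - 2d) / (k + 2d)``).  Singletons get fully private bit
    regions, so all between-cluster and singleton similarities are 0.
    Pairwise similarities are brute-force verified before returning.

    Returns the matrix and ground-truth labels (cluster index, or -1 for
    singletons).
    """
    for size, s in plan:
        if size < 1:
            raise ValueError(f"cluster size must be >= 1, got {size}")
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"similarity target {s} outside [0, 1]")
        if s < 0.8:
            warnings.warn(
                f"similarity target {s} below the 0.8 clustering cutoff: "
                "planted cluster will not be recoverable at the default cutoff",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    k = bits_on
    regions = []  # (n_bits, kind, payload)
    for size, s in plan:
        d = int(np.floor(k * (1.0 - s) / (2.0 * (1.0 + s)))) if s < 1.0 else 0
        regions.append((k + size * d, "cluster", (size, d)))
    for _ in range(n_singletons):
        regions.append((k, "singleton", None))
    p = sum(r[0] for r in regions)
    n = sum(size for size, _ in plan) + n_singletons
    values = np.zeros((n, p), dtype=np.int64)
    labels = np.full(n, -1, dtype=int)

    row = 0
    offset = 0
    cluster_id = 0
    for width, kind, payload in regions:
        if kind == "singleton":
            values[row, offset : offset + k] = 1
            row += 1
        else:
            size, d = payload
            proto = np.zeros(width, dtype=np.int64)
            proto[:k] = 1
            private_start = k
            for m in range(size):
                fp = proto.copy()
                if d > 0:
                    off_bits = rng.choice(k, size=d, replace=False)
                    fp[off_bits] = 0
                    fp[private_start : private_start + d] = 1
                    private_start += d
                values[row, offset : offset + width] = fp
                labels[row] = cluster_id
                row += 1
            cluster_id += 1
        offset += width

    _verify_planted_similarities(values, labels, plan)
    matrix = DescriptorMatrix(
        ids=_ids(n, prefix="CLU"),
        feature_names=[f"BIT{i + 1:05d}" for i in range(p)],
        values=values,
    )
    return matrix, labels


def _verify_planted_similarities(values, labels, plan) -> None:
    from .clustering import pairwise_tanimoto

    sim = pairwise_tanimoto(values)
    for cid, (size, s_target) in enumerate(plan):
        members = np.flatnonzero(labels == cid)
        block = sim[np.ix_(members, members)]
        if size > 1 and block[~np.eye(size, dtype=bool)].min() < s_target - 1e-12:
            raise AssertionError(f"cluster {cid}: within-cluster similarity below target")
    distinct = labels[:, None] != labels[None, :]
    singleton_pair = (labels[:, None] == -1) | (labels[None, :] == -1)
    off_diag = ~np.eye(len(labels), dtype=bool)
    cross = sim[(distinct | singleton_pair) & off_diag]
    if cross.size and cross.max() >= 0.8:
        raise AssertionError("between-cluster similarity reached the 0.8 cutoff")


def generate_clustered_dataset(
    plan: list[tuple[int, float]],
    n_singletons: int,
    seed: int,
    potency_offsets: list[float] | None = None,
    base_mean: float = TARGET_MEAN_PIC50,
    within_sd: float = 0.3,
) -> tuple[DescriptorMatrix, np.ndarray, pd.DataFrame]:
    """Clustered fingerprints plus a compound table with planted potencies.

    Cluster c's members draw pIC50 from N(base_mean + potency_offsets[c],
    within_sd); singletons draw from N(base_mean, within_sd).  Properties
    come from :func:`generate_properties`.
    """
    matrix, labels = generate_clustered_fingerprints(plan, n_singletons, seed)
    if potency_offsets is None:
        potency_offsets = [1.0 + 0.5 * c for c in range(len(plan))]
    if len(potency_offsets) != len(plan):
        raise ValueError("need one potency offset per planned cluster")
    rng = np.random.default_rng([seed, 3])
    mu = np.array(
        [base_mean + (potency_offsets[l] if l >= 0 else 0.0) for l in labels]
    )
    pic50 = rng.normal(mu, within_sd)
    compounds = generate_properties(matrix.ids, seed)
    compounds.insert(1, "pIC50", np.round(pic50, 4))
    return matrix, labels, compounds


def write_bioactivity_csv(records: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False)


def write_ground_truth_json(truth: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
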