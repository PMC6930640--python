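"""Pipeline configuration.

Every default matches the full-scale study protocol: correlation cutoff
0.7, 80/20 splits repeated 100 times, 10-fold cross-validation, 100
Y-scrambling permutations, Tanimoto clustering cutoff 0.8, cluster
retention N >= 20, all four model families with 500-tree forests and
cross-validated mtry.  Scaled-down runs override via YAML or CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # data source: either file paths (real mode) or the synthetic recipe
    bioactivity_csv: str | None = None
    descriptor_csv: str | None = None
    properties_csv: str | None = None

    # synthetic recipe
    synthetic: bool = True
    n_compounds: int = 300
    n_features: int = 50
    n_informative: int = 5
    coefficient: float = 0.4
    oracle_r2: float = 0.8          # noise_sd solved from this when noise_sd is None
    noise_sd: float | None = None
    collinear_blocks: list = field(default_factory=lambda: [[0, 2, 0.9], [1, 1, 0.85]])
    contamination: dict = field(
        default_factory=lambda: {
            "non_ic50": 0.10, "qualifier": 0.05, "missing": 0.05,
            "micromolar": 0.10, "duplicate": 0.10,
        }
    )
    cluster_plan: list = field(default_factory=lambda: [[25, 0.9], [20, 0.9]])
    cluster_singletons: int = 5
    cluster_potency_offsets: list = field(default_factory=lambda: [1.5, 0.5])

    # curation
    concordance: float = 1.0
    active_min: float = 6.0
    inactive_max: float = 5.0

    # feature selection
    correlation_cutoff: float = 0.7

    # modelling protocol
    models: list = field(default_factory=lambda: ["DT", "SVM", "DNN", "RF"])
    train_fraction: float = 0.8
    n_splits: int = 100
    cv_folds: int = 10
    rf_n_trees: int = 500
    rf_mtry: str | int = "tune"
    scramble_permutations: int = 100
    scramble_cv_folds: int = 10

    # applicability domain / clustering
    ad_enabled: bool = True
    cluster_cutoff: float = 0.8
    cluster_min_size: int = 20

    seed: int = 0
    outdir: str = "fpqsar_out"

    def validate(self) -> None:
        problems = []
        if not 0.0 < self.train_fraction < 1.0:
            problems.append("train_fraction must lie in (0, 1)")
        if not 0.0 <= self.correlation_cutoff <= 1.0:
            problems.append("correlation_cutoff must lie in [0, 1]")
        if not 0.0 <= self.cluster_cutoff <= 1.0:
            problems.append("cluster_cutoff must lie in [0, 1]")
        if self.n_splits < 2:
            problems.append("n_splits must be >= 2")
        if self.cv_folds < 2:
            problems.append("cv_folds must be >= 2")
        if self.active_min <= self.inactive_max:
            problems.append("active_min must exceed inactive_max")
        unknown = set(self.models) - {"DT", "SVM", "DNN", "RF"}
        if unknown:
            problems.append(f"unknown models: {sorted(unknown)}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    def as_dict(self) -> dict:
        return asdict(self)

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
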