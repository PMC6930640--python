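"""Stage runner tying the modules into the end-to-end workflow.

Stages (each reads its upstream artifacts from the output directory and
writes its own bundle there):

  simulate -> curate -> featurize -> train -> ad -> cluster -> report

The report stage assembles one JSON summary embedding the configuration
and every seed used, so each number in it is regenerable; running the
same configuration and seed twice produces byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, curation, domain, features, harness, importance, metrics, synthetic
from .config import PipelineConfig

__all__ = [
    "MissingArtifactError",
    "stage_simulate",
    "stage_curate",
    "stage_featurize",
    "stage_train",
    "stage_ad",
    "stage_cluster",
    "stage_report",
    "run_pipeline",
]

log = logging.getLogger("fpqsar")


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output file is absent."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage '{stage}' needs missing artifact {path}; run the upstream stage first"
        )
    return path


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=synthetic._jsonable)
        fh.write("\n")


def _synthetic_spec(cfg: PipelineConfig) -> synthetic.SyntheticSpec:
    return synthetic.SyntheticSpec(
        n_compounds=cfg.n_compounds,
        n_features=cfg.n_features,
        informative_idx=list(range(cfg.n_informative)),
        coefficients=[cfg.coefficient] * cfg.n_informative,
        noise_sd=cfg.noise_sd if cfg.noise_sd is not None else 0.0,
        collinear_blocks=[tuple(b) for b in cfg.collinear_blocks],
        seed=cfg.seed,
    )


def stage_simulate(cfg: PipelineConfig) -> dict:
    """Generate the full synthetic input bundle with ground truth."""
    out = cfg.out
    spec = _synthetic_spec(cfg)
    X = synthetic.generate_fingerprint_matrix(spec)
    if cfg.noise_sd is None:
        noise = synthetic.noise_sd_for_r2(X, spec, cfg.oracle_r2)
        spec.noise_sd = noise
    y = synthetic.generate_activity(X, spec)
    records, truth = synthetic.records_for_compounds(
        X.ids, y, seed=cfg.seed, fractions=cfg.contamination
    )
    props = synthetic.generate_properties(X.ids, cfg.seed)

    features.write_padel_csv(X, out / "descriptors.csv")
    synthetic.write_bioactivity_csv(records, out / "bioactivity.csv")
    props.to_csv(out / "properties.csv", index=False)

    cmatrix, clabels, ccompounds = synthetic.generate_clustered_dataset(
        [tuple(p) for p in cfg.cluster_plan],
        cfg.cluster_singletons,
        seed=cfg.seed,
        potency_offsets=list(cfg.cluster_potency_offsets),
    )
    features.write_padel_csv(cmatrix, out / "cluster_fingerprints.csv")
    ccompounds.assign(true_label=clabels).to_csv(out / "cluster_compounds.csv", index=False)

    truth = dict(
        truth,
        informative_features=[X.feature_names[i] for i in spec.informative_idx],
        coefficients=list(spec.coefficients),
        noise_sd=float(spec.noise_sd),
        true_pic50={cid: float(v) for cid, v in zip(X.ids, y)},
        cluster_labels=clabels.tolist(),
        seed=cfg.seed,
    )
    synthetic.write_ground_truth_json(truth, out / "ground_truth.json")
    log.info("simulate: %d compounds, %d descriptors, %d raw records",
             X.n_compounds, X.n_features, len(records))
    return {"n_compounds": X.n_compounds, "n_features": X.n_features,
            "n_records": len(records), "noise_sd": float(spec.noise_sd)}


def stage_curate(cfg: PipelineConfig) -> dict:
    out = cfg.out
    bio_path = Path(cfg.bioactivity_csv) if cfg.bioactivity_csv else out / "bioactivity.csv"
    _require(bio_path, "curate")
    records = curation.read_bioactivity_csv(bio_path)
    props = None
    prop_path = Path(cfg.properties_csv) if cfg.properties_csv else out / "properties.csv"
    if prop_path.exists():
        props = pd.read_csv(prop_path)
    curated, clog = curation.curate(
        records, properties=props, concordance=cfg.concordance,
        thresholds=(cfg.active_min, cfg.inactive_max),
    )
    curation.write_curated_csv(curated, out / "curated.csv")
    _write_json(clog, out / "curation_log.json")
    space = curation.chemical_space_summary(curated)
    space.to_csv(out / "chemical_space.csv", index=False)
    log.info("curate: %d records in, %d compounds out",
             clog["filter"].get("input", 0), len(curated))
    return {"log": clog, "n_compounds": len(curated)}


def stage_featurize(cfg: PipelineConfig) -> dict:
    out = cfg.out
    desc_path = Path(cfg.descriptor_csv) if cfg.descriptor_csv else out / "descriptors.csv"
    _require(desc_path, "featurize")
    _require(out / "curated.csv", "featurize")
    X = features.read_padel_csv(desc_path)
    curated = pd.read_csv(out / "curated.csv")
    X = X.subset_compounds(curated["compound_id"].astype(str).tolist())
    result = features.select_features(X, cutoff=cfg.correlation_cutoff)
    kept = X.subset_features(result.kept)
    features.write_padel_csv(kept, out / "descriptors_filtered.csv")
    _write_json(result.report(X.feature_names), out / "filter_report.json")
    log.info("featurize: %d -> %d descriptors at cutoff %.2f",
             X.n_features, kept.n_features, cfg.correlation_cutoff)
    return {"n_kept": len(result.kept), "n_removed": len(result.removed)}


def _model_specs(cfg: PipelineConfig) -> list[harness.ModelSpec]:
    specs = []
    for m in cfg.models:
        hp: dict = {}
        if m == "RF":
            hp = {"n_trees": cfg.rf_n_trees, "mtry": cfg.rf_mtry}
        specs.append(harness.ModelSpec(m, hp, seed=cfg.seed))
    return specs


def _load_modelling_data(cfg: PipelineConfig, stage: str):
    out = cfg.out
    _require(out / "descriptors_filtered.csv", stage)
    _require(out / "curated.csv", stage)
    X = features.read_padel_csv(out / "descriptors_filtered.csv")
    curated = pd.read_csv(out / "curated.csv")
    aligned = X.subset_compounds(curated["compound_id"].astype(str).tolist())
    y = curated["pIC50"].to_numpy(dtype=float)
    return aligned, y


def stage_train(cfg: PipelineConfig) -> dict:
    out = cfg.out
    X, y = _load_modelling_data(cfg, "train")
    report = harness.run_protocol(
        X.values, y, _model_specs(cfg),
        n_splits=cfg.n_splits, base_seed=cfg.seed,
        train_fraction=cfg.train_fraction, cv_folds=cfg.cv_folds,
        collect_predictions=True,
    )
    summary = report.summary()
    _write_json(
        {"summary": summary, "acceptable": report.acceptability(),
         "n_splits": report.n_splits, "base_seed": report.base_seed,
         "rf_mtry_per_split": report.rf_mtry},
        out / "model_report.json",
    )
    rows = []
    for m in report.methods:
        for part in report.partitions:
            for metric, stats in summary[m][part].items():
                rows.append([m, part, metric, stats["mean"], stats["sd"]])
    pd.DataFrame(rows, columns=["model", "partition", "metric", "mean", "sd"]).to_csv(
        out / "model_metrics.csv", index=False
    )
    pred_rows = []
    for rec in getattr(report, "predictions", []):
        for o, p in zip(rec["observed"], rec["predicted"]):
            pred_rows.append([rec["split"], rec["method"], rec["partition"], o, p])
    pd.DataFrame(
        pred_rows, columns=["split", "method", "partition", "observed", "predicted"]
    ).to_csv(out / "predictions.csv", index=False)

    if report.rf_importances is not None:
        np.savetxt(out / "rf_importances_per_split.csv",
                   report.rf_importances, delimiter=",",
                   header=",".join(X.feature_names), comments="")
        table = importance.aggregate_importance(report.rf_importances, X.feature_names)
        annotated = importance.top_features(table, k=len(table))
        annotated.to_csv(out / "importance.csv", index=False)

    if cfg.scramble_permutations > 0 and "RF" in cfg.models:
        rf_spec = next(s for s in _model_specs(cfg) if s.method == "RF")
        if rf_spec.hyperparams.get("mtry") == "tune":
            rf_spec = harness.ModelSpec(
                "RF", dict(rf_spec.hyperparams, mtry="sqrt"), seed=rf_spec.seed
            )
        scr = harness.y_scramble(
            rf_spec, X.values, y, n_permutations=cfg.scramble_permutations,
            seed=cfg.seed + 17, k=cfg.scramble_cv_folds,
        )
        rows = [[scr.real_point[0], scr.real_point[1], True]] + [
            [r2, q2, False] for r2, q2 in scr.permuted_points
        ]
        pd.DataFrame(rows, columns=["R2", "Q2", "is_real"]).to_csv(
            out / "scramble.csv", index=False
        )
    log.info("train: %d splits x %d models done", cfg.n_splits, len(cfg.models))
    return {"summary": summary}


def stage_ad(cfg: PipelineConfig) -> dict:
    """Williams-plot applicability domain on one representative split."""
    out = cfg.out
    X, y = _load_modelling_data(cfg, "ad")
    idx = harness.split_data(len(y), cfg.train_fraction, seed=cfg.seed + 1)
    Xtr, ytr = X.values[idx.train_idx], y[idx.train_idx]
    Xte, yte = X.values[idx.test_idx], y[idx.test_idx]

    rf = harness.ModelSpec("RF", {"n_trees": cfg.rf_n_trees, "mtry": "sqrt"}, seed=cfg.seed)
    model = harness.fit_model(rf, Xtr, ytr)
    pred_tr = model.predict(Xtr)
    pred_te = model.predict(Xte)

    p = X.n_features
    h_star = domain.warning_leverage(p, len(ytr))
    h_tr = domain.leverages(Xtr)
    h_te = domain.leverages(Xtr, Xte)
    res_tr = ytr - pred_tr
    s = float(np.std(res_tr, ddof=1))
    r_tr = domain.standardized_residuals(ytr, pred_tr)
    r_te = domain.standardized_residuals(yte, pred_te, scale=s)

    ad_tr = domain.williams_classify(h_tr, r_tr, h_star, p=p)
    ad_te = domain.williams_classify(h_te, r_te, h_star, p=p)

    ids = np.asarray(X.ids)
    df = pd.concat(
        [
            ad_tr.to_dataframe(ids[idx.train_idx], "train"),
            ad_te.to_dataframe(ids[idx.test_idx], "test"),
        ],
        ignore_index=True,
    )
    df.to_csv(out / "williams.csv", index=False)
    summary = {
        "h_star": h_star,
        "p": p,
        "n_train": len(ytr),
        "train_counts": ad_tr.counts,
        "test_counts": ad_te.counts,
    }
    _write_json(summary, out / "ad_summary.json")
    log.info("ad: h*=%.4f, train in-domain %d/%d", h_star,
             ad_tr.counts["in_domain"], len(ytr))
    return summary


def stage_cluster(cfg: PipelineConfig) -> dict:
    out = cfg.out
    _require(out / "cluster_fingerprints.csv", "cluster")
    _require(out / "cluster_compounds.csv", "cluster")
    fps = features.read_padel_csv(out / "cluster_fingerprints.csv")
    compounds = pd.read_csv(out / "cluster_compounds.csv")
    labels = clustering.bin_cluster(fps, cutoff=cfg.cluster_cutoff)
    summaries = clustering.summarize_clusters(
        labels, compounds, min_size=cfg.cluster_min_size
    )
    ranked = clustering.prioritize(summaries) if summaries else []
    table = pd.DataFrame([s.as_dict() for s in ranked])
    if len(table):
        table["member_ids"] = table["member_ids"].map(";".join)
    table.to_csv(out / "clusters.csv", index=False)
    log.info("cluster: %d clusters retained of %d compounds",
             len(ranked), len(compounds))
    return {"n_retained": len(ranked),
            "clusters": [s.as_dict() for s in ranked]}


def stage_report(cfg: PipelineConfig) -> dict:
    """Assemble the single JSON summary of a full run."""
    out = cfg.out
    cfg_dict = cfg.as_dict()
    cfg_dict.pop("outdir")  # location-independent: identical runs give identical reports
    report: dict = {"config": cfg_dict, "seed": cfg.seed}
    bundles = [
        ("curation", out / "curation_log.json"),
        ("feature_filter", out / "filter_report.json"),
        ("models", out / "model_report.json"),
    ]
    if cfg.ad_enabled:
        bundles.append(("applicability_domain", out / "ad_summary.json"))
    for name, path in bundles:
        _require(path, "report")
        with open(path) as fh:
            report[name] = json.load(fh)
    _require(out / "clusters.csv", "report")
    clusters = pd.read_csv(out / "clusters.csv")
    report["clusters"] = clusters.drop(columns=["member_ids"], errors="ignore").to_dict(
        orient="records"
    )
    if (out / "scramble.csv").exists():
        scr = pd.read_csv(out / "scramble.csv")
        real = scr[scr["is_real"]].iloc[0]
        perm = scr[~scr["is_real"]]
        report["y_scrambling"] = {
            "real_R2": float(real["R2"]),
            "real_Q2": float(real["Q2"]),
            "max_permuted_R2": float(perm["R2"].max()) if len(perm) else None,
            "max_permuted_Q2": float(perm["Q2"].max()) if len(perm) else None,
            "separated": bool(
                len(perm)
                and real["R2"] > perm["R2"].max()
                and real["Q2"] > perm["Q2"].max()
            ),
        }
    _write_json(report, out / "report.json")
    return report


STAGES = {
    "simulate": stage_simulate,
    "curate": stage_curate,
    "featurize": stage_featurize,
    "train": stage_train,
    "ad": stage_ad,
    "cluster": stage_cluster,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the assembled report."""
    cfg.validate()
    cfg.out.mkdir(parents=True, exist_ok=True)
    if cfg.synthetic:
        stage_simulate(cfg)
    stage_curate(cfg)
    stage_featurize(cfg)
    stage_train(cfg)
    if cfg.ad_enabled:
        stage_ad(cfg)
    stage_cluster(cfg)
    return stage_report(cfg)
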