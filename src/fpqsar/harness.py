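"""Repeated-split modelling protocol for fingerprint QSAR regression.

The protocol: split the curated set 80/20 at random, fit each model family
on the training portion, evaluate on the training set, on pooled 10-fold
cross-validation of the training set, and on the held-out test set; repeat
over many independent splits (100 at full scale) and report every
statistic as mean +/- sample sd across splits.  Random-forest variable
importances are retained per split so they can be aggregated downstream.

Model families (adapter over scikit-learn estimators):

* ``DT``  — CART regression tree with cost-complexity pruning, the pruning
  strength chosen by internal cross-validation under the 1-SE rule;
* ``SVM`` — epsilon-SVR with a Gaussian RBF kernel (cost 1, gamma 1/p,
  epsilon 0.1 by default);
* ``DNN`` — multilayer perceptron, two hidden layers (64, 32), ReLU,
  squared-error objective, early stopping on 10% of the training data;
* ``RF``  — random forest (500 trees at full scale); ``mtry`` (features
  tried per split) either fixed or tuned by k-fold cross-validation over
  a small grid.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from . import metrics
from .metrics import MetricSet

__all__ = [
    "ModelSpec",
    "SplitIndices",
    "PredictionSet",
    "ScrambleResult",
    "ModelReport",
    "split_data",
    "fit_model",
    "fit_predict",
    "cross_validate",
    "tune_rf_mtry",
    "run_protocol",
    "y_scramble",
    "raw_gini_importance",
]

METHODS = ("DT", "SVM", "DNN", "RF")

_SEED_MOD = 2**31 - 1


def _subseed(seed: int, *offsets: int) -> int:
    """Derive a bounded child seed deterministically."""
    h = int(seed) % _SEED_MOD
    for o in offsets:
        h = (h * 1_000_003 + int(o) + 1) % _SEED_MOD
    return h


@dataclass(frozen=True)
class ModelSpec:
    """One model family plus its hyperparameters and seed."""

    method: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")


@dataclass(frozen=True)
class SplitIndices:
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        tr, te = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if tr & te:
            raise ValueError("train and test indices overlap")


@dataclass(frozen=True)
class PredictionSet:
    observed: np.ndarray
    predicted: np.ndarray
    partition: str  # train | cv | test

    def __post_init__(self) -> None:
        if len(self.observed) != len(self.predicted):
            raise ValueError("observed/predicted length mismatch")
        if len(self.observed) < 2:
            raise ValueError("a prediction set needs at least 2 points")


@dataclass(frozen=True)
class ScrambleResult:
    real_point: tuple[float, float]  # (train R2, pooled CV Q2)
    permuted_points: list[tuple[float, float]]
    n_permutations: int


def split_data(n: int, train_fraction: float = 0.8, seed: int = 0) -> SplitIndices:
    """Uniform random partition; |train| = round(train_fraction * n)."""
    if n < 10:
        raise ValueError(f"need at least 10 samples to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.rint(train_fraction * n))
    return SplitIndices(
        train_idx=np.sort(perm[:n_train]), test_idx=np.sort(perm[n_train:]), seed=seed
    )


def _build_estimator(spec: ModelSpec, p: int):
    hp = dict(spec.hyperparams)
    seed = _subseed(spec.seed)
    if spec.method == "DT":
        return DecisionTreeRegressor(
            random_state=seed,
            min_samples_leaf=hp.get("min_samples_leaf", 5),
        )
    if spec.method == "SVM":
        return SVR(
            kernel="rbf",
            C=hp.get("cost", 1.0),
            gamma=hp.get("gamma", 1.0 / max(p, 1)),
            epsilon=hp.get("epsilon", 0.1),
        )
    if spec.method == "DNN":
        mlp = MLPRegressor(
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (64, 32))),
            activation=hp.get("activation", "relu"),
            solver="adam",
            learning_rate_init=hp.get("learning_rate", 1e-3),
            max_iter=hp.get("epochs", 300),
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=hp.get("patience", 15),
            random_state=seed,
        )
        # networks need standardized inputs and a centred target to train
        # on raw count features and pIC50-scale responses
        return TransformedTargetRegressor(
            regressor=make_pipeline(StandardScaler(), mlp),
            transformer=StandardScaler(),
        )
    if spec.method == "RF":
        mtry = hp.get("mtry", "sqrt")
        if mtry == "sqrt":
            max_features = "sqrt"
        else:
            max_features = int(mtry)
        return RandomForestRegressor(
            n_estimators=hp.get("n_trees", 500),
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(spec.method)


def _fit_dt_pruned(tree: DecisionTreeRegressor, X, y, seed: int, cv: int = 5):
    """Cost-complexity pruning with the 1-SE rule.

    Candidate alphas come from the pruning path on the full training data
    (subsampled to at most 20); each is scored by k-fold CV MSE and the
    largest alpha whose mean error is within one standard error of the
    minimum is kept — the sparsest tree statistically tied with the best.
    """
    path = tree.cost_complexity_pruning_path(X, y)
    alphas = np.unique(path.ccp_alphas)
    alphas = alphas[alphas >= 0]
    if len(alphas) > 20:
        alphas = np.quantile(alphas, np.linspace(0, 1, 20))
    if len(alphas) <= 1:
        tree.fit(X, y)
        return tree
    kf = KFold(n_splits=min(cv, len(y)), shuffle=True, random_state=_subseed(seed, 101))
    mse = np.zeros((len(alphas), kf.get_n_splits()))
    for f, (tr, te) in enumerate(kf.split(X)):
        for a, alpha in enumerate(alphas):
            t = DecisionTreeRegressor(
                random_state=_subseed(seed, f, a),
                min_samples_leaf=tree.min_samples_leaf,
                ccp_alpha=float(alpha),
            ).fit(X[tr], y[tr])
            mse[a, f] = np.mean((t.predict(X[te]) - y[te]) ** 2)
    mean = mse.mean(axis=1)
    se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
    best = int(np.argmin(mean))
    limit = mean[best] + se[best]
    chosen = float(alphas[np.flatnonzero(mean <= limit)[-1]])
    final = DecisionTreeRegressor(
        random_state=_subseed(seed, 999),
        min_samples_leaf=tree.min_samples_leaf,
        ccp_alpha=chosen,
    )
    return final.fit(X, y)


def fit_model(spec: ModelSpec, X_train, y_train):
    """Fit one model family; returns the fitted estimator."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X_train and y_train row counts differ")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    est = _build_estimator(spec, X.shape[1])
    if spec.method == "DT" and spec.hyperparams.get("prune", True):
        return _fit_dt_pruned(est, X, y, spec.seed)
    return est.fit(X, y)


def fit_predict(spec: ModelSpec, X_train, y_train, X_eval) -> np.ndarray:
    """Fit on the training data and predict every evaluation row."""
    X_eval = np.asarray(X_eval, dtype=float)
    model = fit_model(spec, X_train, y_train)
    return np.asarray(model.predict(X_eval), dtype=float)


def cross_validate(spec: ModelSpec, X, y, k: int = 10, seed: int = 0) -> PredictionSet:
    """Pooled out-of-fold predictions from a random k-fold partition."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n={n}], got {k}")
    kf = KFold(n_splits=k, shuffle=True, random_state=_subseed(seed, 77))
    pred = np.empty(n)
    for tr, te in kf.split(X):
        pred[te] = fit_predict(spec, X[tr], y[tr], X[te])
    return PredictionSet(observed=y, predicted=pred, partition="cv")


def tune_rf_mtry(
    X, y, grid: list[int] | None = None, k: int = 10, seed: int = 0,
    n_trees: int | None = None,
) -> int:
    """Pick the RF mtry maximizing pooled cross-validated Q2.

    Default grid: {floor(sqrt p), floor(p/3), floor(p/2), p}, deduplicated.
    Ties go to the smaller mtry.  Q2 here is the squared Pearson
    correlation of the pooled out-of-fold predictions.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if grid is None:
        grid = [int(np.sqrt(p)), p // 3, p // 2, p]
    grid = sorted({int(g) for g in grid if g >= 1})
    if not grid:
        raise ValueError("empty mtry grid")
    for g in grid:
        if g > p:
            raise ValueError(f"mtry {g} exceeds p={p}")
    if len(grid) == 1:
        return grid[0]
    best_mtry, best_q2 = grid[0], -np.inf
    for mtry in grid:
        hp = {"mtry": mtry}
        if n_trees is not None:
            hp["n_trees"] = n_trees
        spec = ModelSpec("RF", hp, seed=_subseed(seed, mtry))
        preds = cross_validate(spec, X, y, k=k, seed=seed)
        q2 = metrics.r_squared(preds.observed, preds.predicted)
        if q2 > best_q2:  # strict: ties keep the smaller mtry
            best_mtry, best_q2 = mtry, q2
    return best_mtry


def raw_gini_importance(rf: RandomForestRegressor, n_train: int) -> np.ndarray:
    """Per-feature total impurity (variance) decrease, averaged over trees.

    The regression analogue of the classification Gini index: for each
    tree, the sample-weighted sum of the node variance decreases credited
    to each splitting feature, rescaled by the training-set size so the
    score is the tree's total residual-sum-of-squares reduction; the
    forest score is the per-tree average.  Deliberately NOT normalized —
    magnitudes are comparable to node-purity importances from classical RF
    implementations.
    """
    totals = np.zeros(rf.n_features_in_)
    for est in rf.estimators_:
        totals += est.tree_.compute_feature_importances(normalize=False) * n_train
    return totals / len(rf.estimators_)


@dataclass
class ModelReport:
    """Per-split metric sets and their mean +/- sd aggregation.

    ``per_split[method][partition]`` is the list of MetricSet over splits;
    ``rf_importances`` stacks the per-split raw Gini importances (RF only).
    """

    methods: list[str]
    partitions: tuple[str, ...]
    per_split: dict
    n_splits: int
    base_seed: int
    rf_importances: np.ndarray | None = None
    rf_mtry: list[int] | None = None

    def summary(self) -> dict:
        """mean and sample sd (ddof=1) of each metric over the splits."""
        out: dict = {}
        for m in self.methods:
            out[m] = {}
            for part in self.partitions:
                sets = self.per_split[m][part]
                vals = {k: np.array([s.as_dict()[k] for s in sets]) for k in sets[0].as_dict()}
                out[m][part] = {
                    k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
                    for k, v in vals.items()
                }
        return out

    def acceptability(self) -> dict:
        """Conventional threshold verdicts (R2 > 0.6, Q2 > 0.5, rm2 > 0.5)
        applied to the mean statistics of each model."""
        if "cv" not in self.partitions:
            raise ValueError("acceptability needs the cross-validation partition")
        s = self.summary()
        return {
            m: metrics.is_acceptable(
                s[m]["train"]["R2"]["mean"],
                s[m]["cv"]["R2"]["mean"],
                s[m]["test"]["rm2"]["mean"],
            )
            for m in self.methods
        }


def run_protocol(
    X,
    y,
    models: list[ModelSpec],
    n_splits: int = 100,
    base_seed: int = 0,
    train_fraction: float = 0.8,
    cv_folds: int | None = 10,
    mtry_grid: list[int] | None = None,
    collect_predictions: bool = False,
) -> ModelReport:
    """The repeated-split protocol: the machine behind the summary tables.

    For each split s in 1..n_splits (seeded base_seed + s): partition
    80/20, fit every model on the training portion, evaluate train /
    pooled k-fold CV on train / test, and record the full metric set per
    partition.  RF specs with ``mtry="tune"`` are tuned per split on the
    training portion only.  Per-split RF importances are retained.
    ``cv_folds=None`` skips the cross-validation partition (train/test
    metrics only), which large recovery simulations use to avoid paying
    for fold fits they never read.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y are not aligned")
    if n_splits < 2:
        raise ValueError("need at least 2 splits for a standard deviation")

    partitions = ("train", "cv", "test") if cv_folds else ("train", "test")
    per_split: dict = {m.method: {p: [] for p in partitions} for m in models}
    rf_imps: list[np.ndarray] = []
    rf_mtry: list[int] = []
    predictions: list[dict] = []

    for s in range(1, n_splits + 1):
        split_seed = base_seed + s
        idx = split_data(len(y), train_fraction, seed=split_seed)
        assert len(set(idx.train_idx) | set(idx.test_idx)) == len(y)
        Xtr, ytr = X[idx.train_idx], y[idx.train_idx]
        Xte, yte = X[idx.test_idx], y[idx.test_idx]

        for spec in models:
            spec_s = replace(spec, seed=_subseed(spec.seed, split_seed))
            if spec.method == "RF" and spec.hyperparams.get("mtry") == "tune":
                chosen = tune_rf_mtry(
                    Xtr, ytr, grid=mtry_grid, k=cv_folds or 10, seed=split_seed,
                    n_trees=spec.hyperparams.get("n_trees"),
                )
                rf_mtry.append(chosen)
                hp = dict(spec.hyperparams, mtry=chosen)
                spec_s = replace(spec_s, hyperparams=hp)

            model = fit_model(spec_s, Xtr, ytr)
            pred_tr = np.asarray(model.predict(Xtr), dtype=float)
            pred_te = np.asarray(model.predict(Xte), dtype=float)
            per_split[spec.method]["train"].append(
                metrics.metric_set((ytr, pred_tr))
            )
            per_split[spec.method]["test"].append(metrics.metric_set((yte, pred_te)))
            cv_preds = None
            if cv_folds:
                cv_preds = cross_validate(spec_s, Xtr, ytr, k=cv_folds, seed=split_seed)
                per_split[spec.method]["cv"].append(metrics.metric_set(cv_preds))

            if spec.method == "RF":
                rf_imps.append(raw_gini_importance(model, len(ytr)))
            if collect_predictions:
                pairs = [("train", ytr, pred_tr), ("test", yte, pred_te)]
                if cv_preds is not None:
                    pairs.insert(1, ("cv", cv_preds.observed, cv_preds.predicted))
                for part, obs, pr in pairs:
                    predictions.append(
                        {"split": s, "method": spec.method, "partition": part,
                         "observed": obs, "predicted": pr}
                    )

    report = ModelReport(
        methods=[m.method for m in models],
        partitions=partitions,
        per_split=per_split,
        n_splits=n_splits,
        base_seed=base_seed,
        rf_importances=np.vstack(rf_imps) if rf_imps else None,
        rf_mtry=rf_mtry or None,
    )
    if collect_predictions:
        report.predictions = predictions  # type: ignore[attr-defined]
    return report


def y_scramble(
    spec: ModelSpec, X, y, n_permutations: int = 100, seed: int = 0, k: int = 10
) -> ScrambleResult:
    """Chance-correlation check: refit after random shuffles of the response.

    The real point is (training R2, pooled k-fold Q2) on the intact data;
    each permuted point repeats the computation after an independent
    uniform shuffle of y with the descriptor matrix untouched.  A genuine
    structure-activity relationship shows the real point clearly separated
    from the permuted cloud.

    For random forests the training R2 is computed from out-of-bag
    predictions (the convention of classical RF implementations, whose
    resubstitution predictions are OOB): a forest interpolates the
    training data it has seen, so its literal resubstitution R2 stays
    near 1 even on a permuted response and would carry no information.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    def point(y_use: np.ndarray, sub: int) -> tuple[float, float]:
        spec_p = replace(spec, seed=_subseed(spec.seed, sub))
        if spec.method == "RF":
            est = _build_estimator(spec_p, X.shape[1])
            est.set_params(oob_score=True)
            est.fit(X, y_use)
            train_pred = est.oob_prediction_
            if not np.isfinite(train_pred).all():
                raise ValueError(
                    "some samples never out-of-bag; increase n_trees for scrambling"
                )
        else:
            model = fit_model(spec_p, X, y_use)
            train_pred = model.predict(X)
        r2 = metrics.r_squared(y_use, train_pred)
        cv = cross_validate(spec_p, X, y_use, k=k, seed=_subseed(seed, sub))
        q2 = metrics.r_squared(cv.observed, cv.predicted)
        return (r2, q2)

    real = point(y, 0)
    rng = np.random.default_rng(seed)
    permuted = []
    for i in range(1, n_permutations + 1):
        permuted.append(point(rng.permutation(y), i))
    return ScrambleResult(real_point=real, permuted_points=permuted, n_permutations=n_permutations)
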