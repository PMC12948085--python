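"""The per-cell six-classifier response benchmark on the cell x DEG matrix.

Covers stratified splitting (cell- or patient-level), train-fitted feature
standardization, randomized hyperparameter search with stratified 5-fold
cross-validation scored by ROC-AUC, the 1-D CNN, tree-importance
extraction, importance-rank concordance gene selection, and the repeated
random-split stability study.

The default split unit is the cell (matching the original analysis); a
patient-level split is offered as the leakage-safe alternative, since cells
of one patient are not independent. Scaling is fitted on the training
partition only by default; a pooled mode is available behind a flag and is
logged loudly when used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .containers import RESPONDER
from .errors import ValidationError
from . import nn

logger = logging.getLogger(__name__)

MODEL_NAMES = ("xgboost", "random_forest", "logistic_regression", "svm", "fnn", "cnn1d")
TREE_MODELS = ("xgboost", "random_forest")


@dataclass
class SplitSpec:
    """How to partition cells into train/test."""

    unit: str = "cell"  # 'cell' or 'patient'
    test_fraction: float = 0.2
    seed: int = 42
    stratify_by: str = "response"

    def validate(self) -> None:
        if self.unit not in ("cell", "patient"):
            raise ValidationError(f"split unit must be 'cell' or 'patient', got {self.unit!r}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValidationError(f"test_fraction must be in (0, 1), got {self.test_fraction!r}")


def stratified_split(meta: pd.DataFrame, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Train/test positional indices, stratified by response.

    Cell unit: |test| = round(test_fraction * n) with per-class proportions
    preserved. Patient unit: whole patients are assigned to one partition,
    per class, approximating the requested cell fraction.
    """
    spec.validate()
    labels = meta[spec.stratify_by].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present before splitting")
    n = len(labels)
    if spec.unit == "cell":
        if counts.min() < 2:
            raise ValidationError("each class needs at least 2 cells to stratify")
        n_test = int(round(spec.test_fraction * n))
        train_idx, test_idx = train_test_split(
            np.arange(n),
            test_size=n_test,
            stratify=labels,
            random_state=spec.seed,
        )
        return np.sort(train_idx), np.sort(test_idx)

    patients = meta["patient_id"].to_numpy()
    rng = np.random.default_rng(spec.seed)
    test_mask = np.zeros(n, dtype=bool)
    for cls in classes:
        cls_mask = labels == cls
        cls_patients = pd.unique(patients[cls_mask])
        if len(cls_patients) < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 patients; cannot split by patient")
        order = rng.permutation(len(cls_patients))
        target = spec.test_fraction * cls_mask.sum()
        taken = 0
        for pi in order:
            if taken >= target:
                break
            p_mask = cls_mask & (patients == cls_patients[pi])
            # never move the whole class into test
            if taken + p_mask.sum() >= cls_mask.sum():
                continue
            test_mask |= p_mask
            taken += p_mask.sum()
        if taken == 0:  # ensure both partitions see the class
            p_mask = cls_mask & (patients == cls_patients[order[0]])
            test_mask |= p_mask
    train_idx = np.flatnonzero(~test_mask)
    test_idx = np.flatnonzero(test_mask)
    for part, name in ((train_idx, "train"), (test_idx, "test")):
        if len(np.unique(labels[part])) < 2:
            raise ValidationError(f"patient-level split left only one class in {name}")
    return train_idx, test_idx


def standardize(
    train_X: np.ndarray, apply_X: np.ndarray | None = None, *, pooled: bool = False
) -> tuple[np.ndarray, np.ndarray | None, StandardScaler]:
    """Z-score features with statistics from the training partition.

    Zero-variance features map to 0. ``pooled=True`` fits on train and apply
    jointly (the leakage-prone variant some published protocols use); it is
    logged loudly.
    """
    if train_X.shape[0] < 2:
        raise ValidationError("standardize requires at least 2 training rows")
    scaler = StandardScaler()
    if pooled and apply_X is not None:
        logger.warning("standardize: pooled scaling fits on train+apply jointly (leakage-prone)")
        scaler.fit(np.vstack([train_X, apply_X]))
        return scaler.transform(train_X), scaler.transform(apply_X), scaler
    scaler.fit(train_X)
    applied = scaler.transform(apply_X) if apply_X is not None else None
    return scaler.transform(train_X), applied, scaler


def response_to_binary(labels) -> np.ndarray:
    """responder -> 1, non-responder -> 0."""
    arr = np.asarray(labels)
    return (arr == RESPONDER).astype(int)


# ------------------------------------------------------------------ models
def default_estimator(name: str, seed: int = 42):
    if name == "xgboost":
        return XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            subsample=0.9,
            tree_method="hist",
            eval_metric="logloss",
            n_jobs=1,
            random_state=seed,
        )
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=300, n_jobs=1, random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if name == "fnn":
        return MLPClassifier(
            hidden_layer_sizes=(64, 32),
            alpha=1e-3,
            max_iter=300,
            early_stopping=True,
            random_state=seed,
        )
    raise ValidationError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")


def default_search_space(name: str) -> dict:
    """Randomized-search distributions; the analysis text prints none, so
    these are package defaults covering the usual ranges."""
    if name == "xgboost":
        return {
            "n_estimators": [100, 200, 300],
            "max_depth": [3, 4, 5, 6],
            "learning_rate": [0.03, 0.1, 0.2],
            "subsample": [0.7, 0.9, 1.0],
            "colsample_bytree": [0.7, 1.0],
        }
    if name == "random_forest":
        return {
            "n_estimators": [100, 200, 300, 500],
            "max_depth": [None, 6, 12],
            "max_features": ["sqrt", 0.3],
            "min_samples_leaf": [1, 2, 5],
        }
    if name == "svm":
        return {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]}
    if name == "fnn":
        return {
            "hidden_layer_sizes": [(64, 32), (128, 64), (32, 16)],
            "alpha": [1e-4, 1e-3, 1e-2],
            "learning_rate_init": [1e-3, 1e-2],
        }
    return {}


def tune_and_train(
    model_name: str,
    train_X: np.ndarray,
    train_y: np.ndarray,
    *,
    cv_folds: int = 5,
    n_iter: int = 10,
    seed: int = 42,
    search_space: dict | None = None,
):
    """Randomized search (stratified CV, ROC-AUC) then refit on all of train.

    Logistic regression fits with defaults; the other sklearn-family models
    search ``search_space`` (package defaults when omitted). Returns
    (fitted estimator, chosen settings).
    """
    train_y = np.asarray(train_y).reshape(-1)
    class_counts = np.bincount(train_y.astype(int))
    if (class_counts[class_counts > 0] < cv_folds).any():
        raise ValidationError(
            f"stratified {cv_folds}-fold CV impossible: class counts {class_counts.tolist()}"
        )
    est = default_estimator(model_name, seed=seed)
    if model_name == "logistic_regression":
        est.fit(train_X, train_y)
        return est, {}
    space = default_search_space(model_name) if search_space is None else search_space
    n_candidates = int(np.prod([len(v) for v in space.values()])) if space else 1
    search = RandomizedSearchCV(
        est,
        space,
        n_iter=min(n_iter, n_candidates),
        scoring="roc_auc",
        cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed),
        random_state=seed,
        refit=True,
        n_jobs=1,
    )
    search.fit(train_X, train_y)
    return search.best_estimator_, dict(search.best_params_)


def train_cnn1d_genes(
    train_X: np.ndarray,
    train_y: np.ndarray,
    seed: int = 42,
    *,
    epochs: int = 100,
    patience: int = 5,
    batch_size: int = 64,
    lr: float = 1e-3,
    **arch_kwargs,
) -> nn.NeuralNet:
    """Train the gene-level 1-D CNN (feature order = the recorded DEG order)."""
    net = nn.build_gene_cnn1d(train_X.shape[1], seed=seed, **arch_kwargs)
    X3 = np.asarray(train_X, dtype=float)[:, :, None]
    net.fit(
        X3,
        np.asarray(train_y, dtype=float),
        epochs=epochs,
        patience=patience,
        batch_size=batch_size,
        lr=lr,
        seed=seed,
        restore_best=None,
    )
    return net


def model_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for ROC: probability of the positive class where
    available, decision-function otherwise; CNNs score via predict_proba."""
    if isinstance(model, nn.NeuralNet):
        return model.predict_proba(np.asarray(X, dtype=float)[:, :, None])
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC; equals P(score+ > score-) + P(tie)/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).reshape(-1)
    if len(np.unique(labels)) < 2:
        raise ValidationError("roc_auc requires both classes in labels")
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), float(_trapezoid_auc(fpr, tpr))


@dataclass
class ModelReport:
    name: str
    params: dict
    roc: pd.DataFrame
    auc: float
    importances: pd.Series | None = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "params": {k: _plain(v) for k, v in self.params.items()},
            "auc": self.auc,
            "roc": {"fpr": self.roc["fpr"].tolist(), "tpr": self.roc["tpr"].tolist()},
        }
        if self.importances is not None:
            d["importances"] = {str(k): float(v) for k, v in self.importances.items()}
        return d


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, tuple):
        return list(v)
    return v


@dataclass
class ImportanceRanking:
    """Descending-importance gene ranking with average-rank tie handling."""

    importances: pd.Series  # gene -> non-negative importance
    ranks: pd.Series  # gene -> rank, 1 = most important, average ranks for ties
    ordered_genes: list[str] = field(default_factory=list)  # ties broken by symbol
    tie_rule: str = "average_rank_then_symbol"


def tree_importances(model, feature_names: Sequence[str]) -> ImportanceRanking:
    """Importances from the two tree ensembles (gain for boosting, impurity
    decrease for the forest); other models are unsupported."""
    feature_names = [str(f) for f in feature_names]
    if isinstance(model, XGBClassifier):
        score = model.get_booster().get_score(importance_type="gain")
        imp = np.array([score.get(f"f{i}", 0.0) for i in range(len(feature_names))])
    elif isinstance(model, RandomForestClassifier):
        imp = np.asarray(model.feature_importances_, dtype=float)
    else:
        raise ValidationError(
            f"tree_importances supports the tree ensembles only, got {type(model).__name__}"
        )
    if len(imp) != len(feature_names):
        raise ValidationError("feature_names length does not match the fitted model")
    importances = pd.Series(imp, index=feature_names)
    ranks = pd.Series(scipy.stats.rankdata(-imp, method="average"), index=feature_names)
    order = sorted(feature_names, key=lambda g: (-importances[g], g))
    return ImportanceRanking(importances=importances, ranks=ranks, ordered_genes=order)


def concordant_gene_selection(
    rank_a: ImportanceRanking | pd.Series,
    rank_b: ImportanceRanking | pd.Series,
    top_n: int = 50,
) -> tuple[list[str], float, float]:
    """Genes in the top-``top_n`` of both rankings, plus the Spearman
    correlation (and p-value) of the two full rank vectors.

    The selected genes are ordered by mean rank across the two rankings.
    """
    ra = rank_a.ranks if isinstance(rank_a, ImportanceRanking) else pd.Series(rank_a, dtype=float)
    rb = rank_b.ranks if isinstance(rank_b, ImportanceRanking) else pd.Series(rank_b, dtype=float)
    sym_diff = set(ra.index) ^ set(rb.index)
    if sym_diff:
        raise ValidationError(f"rankings cover different gene universes; difference: {sorted(sym_diff)[:10]}")
    rb = rb.loc[ra.index]
    rho, pval = scipy.stats.spearmanr(ra.to_numpy(), rb.to_numpy())
    top_a = set(ra.nsmallest(top_n).index)
    top_b = set(rb.nsmallest(top_n).index)
    shared = top_a & top_b
    mean_rank = (ra + rb) / 2.0
    selected = sorted(shared, key=lambda g: (mean_rank[g], g))
    return selected, float(rho), float(pval)


def resampling_stability(
    X: np.ndarray,
    y: np.ndarray,
    models: Mapping[str, object],
    *,
    n_splits: int = 100,
    test_fraction: float = 0.2,
    base_seed: int = 42,
    original_aucs: Mapping[str, float] | None = None,
    pooled_scaling: bool = False,
) -> dict:
    """Repeated random-split AUC distributions for fixed model settings.

    ``models`` maps name -> a fitted or unfitted sklearn-style estimator
    whose hyperparameters are reused (tuned once on the original split);
    each of the ``n_splits`` random stratified splits refits a clone.
    Returns per-model AUC arrays, percentile 95% CIs, and — when
    ``original_aucs`` is given — the Spearman correlation between mean
    resampled AUC and the original single-split AUCs across models.
    """
    if n_splits < 2:
        raise ValidationError("resampling_stability needs n_splits >= 2")
    y = np.asarray(y).reshape(-1)
    aucs: dict[str, list[float]] = {name: [] for name in models}
    meta = pd.DataFrame({"response": y})
    for s in range(n_splits):
        spec = SplitSpec(unit="cell", test_fraction=test_fraction, seed=base_seed + s)
        tr, te = stratified_split(meta, spec)
        Xtr, Xte, _ = standardize(X[tr], X[te], pooled=pooled_scaling)
        for name, est in models.items():
            fitted = clone(est)
            fitted.fit(Xtr, y[tr])
            _, a = roc_auc(model_scores(fitted, Xte), y[te])
            aucs[name].append(a)
    out: dict = {"aucs": {k: np.asarray(v) for k, v in aucs.items()}}
    out["ci95"] = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in out["aucs"].items()
    }
    out["mean"] = {k: float(np.mean(v)) for k, v in out["aucs"].items()}
    if original_aucs is not None and len(models) >= 3:
        names = list(models)
        rho, pval = scipy.stats.spearmanr(
            [out["mean"][n] for n in names], [original_aucs[n] for n in names]
        )
        out["correlation_with_original"] = (float(rho), float(pval))
    return out


def benchmark_gene_models(
    X: np.ndarray,
    labels,
    *,
    meta: pd.DataFrame | None = None,
    feature_names: Sequence[str] | None = None,
    models: Sequence[str] = MODEL_NAMES,
    split_spec: SplitSpec | None = None,
    cv_folds: int = 5,
    n_iter: int = 10,
    seed: int = 42,
    pooled_scaling: bool = False,
    search_spaces: Mapping[str, dict] | None = None,
    cnn_kwargs: dict | None = None,
) -> dict:
    """Run the full gene-level benchmark: split, scale, tune, train, evaluate.

    Returns a dict with the split indices, one :class:`ModelReport` per
    model (importances attached for the tree ensembles), and the fitted
    models keyed by name.
    """
    y = response_to_binary(labels)
    if meta is None:
        meta = pd.DataFrame({"response": np.asarray(labels)})
    split_spec = split_spec or SplitSpec(seed=seed)
    tr, te = stratified_split(meta, split_spec)
    Xtr, Xte, scaler = standardize(X[tr], X[te], pooled=pooled_scaling)
    reports: dict[str, ModelReport] = {}
    fitted: dict[str, object] = {}
    for name in models:
        if name == "cnn1d":
            model = train_cnn1d_genes(Xtr, y[tr], seed=seed, **(cnn_kwargs or {}))
            params: dict = {"architecture": "conv1d_x2_bn_pool_dropout"}
        else:
            space = None if search_spaces is None else search_spaces.get(name)
            model, params = tune_and_train(
                name, Xtr, y[tr], cv_folds=cv_folds, n_iter=n_iter, seed=seed, search_space=space
            )
        roc, a = roc_auc(model_scores(model, Xte), y[te])
        imp = None
        if name in TREE_MODELS and feature_names is not None:
            imp = tree_importances(model, feature_names).importances
        reports[name] = ModelReport(name=name, params=params, roc=roc, auc=a, importances=imp)
        fitted[name] = model
    return {
        "train_idx": tr,
        "test_idx": te,
        "reports": reports,
        "models": fitted,
        "scaler": scaler,
        "labels": y,
    }
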