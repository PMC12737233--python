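"""Per-phenotype faller / non-faller models.

Four families (random forest, gradient-boosted trees via XGBoost, single
decision tree, feed-forward neural network) are tuned by exhaustive grid
search under stratified 5-fold cross-validation with mean validation F1 as
the selection criterion and inverse-frequency class weighting, then refit
on all of the phenotype's subjects.  Preprocessing (imputation, scaling,
and for the network IQR clipping) is fitted on training folds only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .types import FEATURE_COLUMNS

FAMILIES = ("random_forest", "gradient_boosted_trees", "decision_tree", "feedforward_nn")

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass
class ModelSpec:
    family: str
    grid: dict
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.folds != 5:
            raise ValueError("protocol fixes 5 stratified folds")

    def combos(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, vals)) for vals in itertools.product(*(self.grid[k] for k in keys))]


@dataclass
class ModelResult:
    family: str
    best_hyperparameters: dict
    fold_confusions: list  # one 2x2 array per fold, rows true (0,1), cols pred
    metrics: dict  # name -> (mean, lo95, hi95)
    model: object = None
    preprocessor: object = None
    cv_f1: float = 0.0


def full_grids() -> dict:
    """The complete per-family hyperparameter enumerations."""
    return {
        "random_forest": {
            "n_estimators": [100, 200, 300],
            "max_depth": [None, 10, 20, 30],
            "min_samples_split": [2, 5, 10],
            "min_samples_leaf": [1, 2, 4],
            "max_features": ["sqrt", "log2", None],
            "bootstrap": [True, False],
        },
        "gradient_boosted_trees": {
            "n_estimators": [100, 200, 300],
            "max_depth": [3, 6, 9],
            "learning_rate": [0.01, 0.1, 0.2],
            "subsample": [0.8, 0.9, 1.0],
            "colsample_bytree": [0.8, 0.9, 1.0],
        },
        "decision_tree": {
            "criterion": ["gini", "entropy"],
            "max_depth": [None, 5, 10, 15, 20, 25, 30],
            "min_samples_split": [2, 5, 10, 15, 20],
            "min_samples_leaf": [1, 2, 4, 8, 10],
            "max_features": [None, "sqrt", "log2"],
            "splitter": ["best", "random"],
        },
        "feedforward_nn": {
            "hidden_layer_sizes": [
                (50,), (100,), (150,), (50, 50), (100, 100), (150, 150),
                (50, 50, 50), (100, 100, 100),
            ],
            "activation": ["relu", "tanh"],
            "alpha": [0.0001, 0.001, 0.01],
            "learning_rate_init": [0.001, 0.01, 0.1],
            "max_iter": [500, 1000, 1500],
        },
    }


def small_grids() -> dict:
    """Reduced enumerations for desk-scale synthetic cohorts (~35 subjects
    per phenotype), keeping one axis of variation per regularization knob."""
    return {
        "random_forest": {
            "n_estimators": [100],
            "max_depth": [None, 10],
            "min_samples_split": [2],
            "min_samples_leaf": [1, 4],
            "max_features": ["sqrt"],
            "bootstrap": [True],
        },
        "gradient_boosted_trees": {
            "n_estimators": [100],
            "max_depth": [3, 6],
            "learning_rate": [0.1, 0.2],
            "subsample": [0.9],
            "colsample_bytree": [0.9],
        },
        "decision_tree": {
            "criterion": ["gini"],
            "max_depth": [None, 5],
            "min_samples_split": [2, 10],
            "min_samples_leaf": [1, 4],
            "max_features": [None],
            "splitter": ["best"],
        },
        "feedforward_nn": {
            "hidden_layer_sizes": [(50,), (100,)],
            "activation": ["relu"],
            "alpha": [0.001, 0.01],
            "learning_rate_init": [0.01],
            "max_iter": [500],
        },
    }


# ------------------------------------------------------------- preprocessing


@dataclass
class Preprocessor:
    """Per-family preprocessing fitted on training data only.

    Tree families: mean imputation + z-scoring.  Network: median imputation,
    IQR clipping to [Q1 - 1.5 IQR, Q3 + 1.5 IQR], robust scaling by
    median/IQR.
    """

    family: str
    center: np.ndarray = field(default=None)
    scale: np.ndarray = field(default=None)
    fill: np.ndarray = field(default=None)
    clip_lo: np.ndarray = field(default=None)
    clip_hi: np.ndarray = field(default=None)

    def fit(self, X: np.ndarray, columns: list[str] | None = None) -> "Preprocessor":
        X = np.asarray(X, dtype=float)
        all_missing = np.all(np.isnan(X), axis=0)
        if np.any(all_missing):
            cols = columns or [str(i) for i in range(X.shape[1])]
            bad = [cols[i] for i in np.where(all_missing)[0]]
            raise ValueError(f"all-missing feature column(s): {bad}")
        if self.family == "feedforward_nn":
            self.fill = np.nanmedian(X, axis=0)
            Xi = np.where(np.isnan(X), self.fill, X)
            q1 = np.percentile(Xi, 25, axis=0)
            q3 = np.percentile(Xi, 75, axis=0)
            iqr = q3 - q1
            self.clip_lo = q1 - 1.5 * iqr
            self.clip_hi = q3 + 1.5 * iqr
            Xc = np.clip(Xi, self.clip_lo, self.clip_hi)
            self.center = np.median(Xc, axis=0)
            self.scale = np.where(iqr > 0, iqr, 1.0)
        else:
            self.fill = np.nanmean(X, axis=0)
            Xi = np.where(np.isnan(X), self.fill, X)
            self.center = Xi.mean(axis=0)
            sd = Xi.std(ddof=0, axis=0)
            self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xi = np.where(np.isnan(X), self.fill, X)
        if self.family == "feedforward_nn":
            Xi = np.clip(Xi, self.clip_lo, self.clip_hi)
        return (Xi - self.center) / self.scale


def prepare_features(
    subjects: pd.DataFrame,
    family: str,
    feature_columns: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (raw, preprocessing happens fold-wise), labels, and the
    feature-name list.  The fall label is never a feature; TUG time is."""
    cols = feature_columns or FEATURE_COLUMNS
    if "fell" in cols:
        raise ValueError("the fall label cannot be a feature")
    X = subjects[cols].to_numpy(dtype=float)
    y = subjects["fell"].to_numpy(dtype=int)
    return X, y, list(cols)


# ------------------------------------------------------------------ metrics


def confusion_metrics(cm: np.ndarray) -> dict:
    """Standard binary metrics from a 2x2 confusion matrix
    [[tn, fp], [fn, tp]]; undefined ratios are reported as nan, not zero."""
    cm = np.asarray(cm)
    if np.any(cm < 0):
        raise ValueError("confusion counts must be nonnegative")
    tn, fp, fn, tp = int(cm[0, 0]), int(cm[0, 1]), int(cm[1, 0]), int(cm[1, 1])
    total = tn + fp + fn + tp

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    return {
        "accuracy": ratio(tp + tn, total),
        "precision": precision,
        "recall": recall,
        "specificity": ratio(tn, tn + fp),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }


def _fit_model(family: str, params: dict, X: np.ndarray, y: np.ndarray, seed: int,
               final: bool = False):
    classes, counts = np.unique(y, return_counts=True)
    if family == "random_forest":
        model = RandomForestClassifier(
            class_weight="balanced", random_state=seed, n_jobs=1, **params
        )
        model.fit(X, y)
    elif family == "gradient_boosted_trees":
        n_pos = counts[classes == 1].sum()
        n_neg = counts[classes == 0].sum()
        model = XGBClassifier(
            objective="binary:logistic",
            scale_pos_weight=(n_neg / n_pos) if n_pos > 0 else 1.0,
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="logloss", **params,
        )
        model.fit(X, y)
    elif family == "decision_tree":
        model = DecisionTreeClassifier(class_weight="balanced", random_state=seed, **params)
        model.fit(X, y)
    else:  # feedforward_nn
        p = dict(params)
        if final:
            p["max_iter"] = max(int(p.get("max_iter", 500)) * 3, 2000)
        model = MLPClassifier(
            solver="adam", early_stopping=True, validation_fraction=0.1,
            n_iter_no_change=10, random_state=seed, **p,
        )
        Xb, yb = _balance_by_duplication(X, y)
        model.fit(Xb, yb)
    return model


def _balance_by_duplication(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic minority-class row duplication approximating
    inverse-frequency class weights (the MLP accepts no sample weights)."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() == counts.max():
        return X, y
    n_max = counts.max()
    parts_X, parts_y = [], []
    for cls, cnt in zip(classes, counts):
        idx = np.where(y == cls)[0]
        reps = int(np.ceil(n_max / cnt))
        take = np.tile(idx, reps)[:n_max]
        parts_X.append(X[take])
        parts_y.append(y[take])
    return np.concatenate(parts_X), np.concatenate(parts_y)


def tune_and_crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    feature_names: list[str] | None = None,
) -> ModelResult:
    """Grid search + stratified 5-fold CV, selection by mean validation F1,
    final refit on all data with the best hyperparameters.

    Per-fold confusion matrices of the winning setting are retained; each
    metric is summarized as mean with a normal-approximation 95% CI across
    folds (mean +/- 1.96 SD / sqrt(folds)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))
    for _, val_idx in folds:
        if len(np.unique(y[val_idx])) < 2:
            # a fold missing a class makes F1/specificity degenerate there;
            # it is kept but flagged via nan handling in the summary
            pass

    best = None
    for params in spec.combos():
        f1s, cms = [], []
        for train_idx, val_idx in folds:
            prep = Preprocessor(spec.family).fit(X[train_idx], feature_names)
            Xtr = prep.transform(X[train_idx])
            Xva = prep.transform(X[val_idx])
            model = _fit_model(spec.family, params, Xtr, y[train_idx], spec.seed)
            pred = model.predict(Xva)
            cm = np.zeros((2, 2), dtype=int)
            for t, p in zip(y[val_idx], pred):
                cm[t, p] += 1
            cms.append(cm)
            f1 = confusion_metrics(cm)["f1"]
            f1s.append(0.0 if np.isnan(f1) else f1)
        mean_f1 = float(np.mean(f1s))
        if best is None or mean_f1 > best[0] + 1e-12:
            best = (mean_f1, params, cms)

    mean_f1, params, cms = best
    metrics = {}
    for name in METRIC_NAMES:
        vals = np.array([confusion_metrics(cm)[name] for cm in cms])
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            metrics[name] = (float("nan"), float("nan"), float("nan"))
            continue
        m = float(vals.mean())
        half = 1.96 * float(vals.std(ddof=1 if len(vals) > 1 else 0)) / np.sqrt(len(vals))
        metrics[name] = (m, max(m - half, 0.0), min(m + half, 1.0))

    prep = Preprocessor(spec.family).fit(X, feature_names)
    model = _fit_model(spec.family, params, prep.transform(X), y, spec.seed, final=True)
    return ModelResult(
        family=spec.family, best_hyperparameters=params, fold_confusions=cms,
        metrics=metrics, model=model, preprocessor=prep, cv_f1=mean_f1,
    )


def metrics_table(results: dict[str, dict[str, ModelResult]]) -> pd.DataFrame:
    """Per-phenotype, per-family metric summary (mean and 95% CI)."""
    rows = []
    for pheno, fam_results in results.items():
        for family, res in fam_results.items():
            row = {"phenotype": pheno, "family": family}
            for name, (m, lo, hi) in res.metrics.items():
                row[name] = m
                row[f"{name}_ci"] = f"({lo:.2f}, {hi:.2f})"
            rows.append(row)
    return pd.DataFrame(rows)
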