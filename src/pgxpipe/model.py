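"""Class-imbalance-aware training and comparison of tree-ensemble
classifiers for pharmacogenetic variant prediction.

Workflow: stratified 70/30 partition; repeated stratified k-fold cross
validation (default 5 folds x 10 repeats = 50 resamples) with SMOTE applied
inside each analysis fold only; hyperparameters chosen to maximise the mean
of a selection metric (sensitivity by default) across resamples; held-out
confusion matrices at a fixed probability threshold; gain-based variable
importance rescaled so the top variable scores 100; prediction of new
(not-yet-annotated) pharmacogenetic variants.

The positive class throughout is "annotated pharmacovariant".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .balance import SmoteConfig, smote_sample

LEARNER_NAMES = ("random_forest", "logit_boost", "gradient_boosted_trees")

#: Documented default hyperparameter grids (the original analysis used
#: framework defaults it never listed).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100], "max_features": ["sqrt", "third"]},
    "logit_boost": {"n_estimators": [100, 300], "learning_rate": [0.1, 0.3]},
    "gradient_boosted_trees": {
        "n_estimators": [100, 300],
        "max_depth": [2, 4, 6],
        "learning_rate": [0.1, 0.3],
    },
}

#: Single-configuration grids for budgeted runs (tests, acceptance, CLI
#: --fast): one sensible point from each default grid.
FAST_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100], "max_features": ["sqrt"]},
    "logit_boost": {"n_estimators": [100], "learning_rate": [0.3]},
    "gradient_boosted_trees": {
        "n_estimators": [60],
        "max_depth": [3],
        "learning_rate": [0.3],
    },
}


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. one-class AUC)."""


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_table(self) -> pd.DataFrame:
        """Held-out counts: rows = predicted neutral/PGx, columns =
        not-annotated/annotated."""
        return pd.DataFrame(
            {"not_annotated": [self.tn, self.fp], "annotated": [self.fn, self.tp]},
            index=pd.Index(["neutral", "PGx"], name="prediction"),
        )


@dataclass
class MethodMetrics:
    method_name: str
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float = float("nan")


@dataclass
class CVResult:
    learner_name: str
    resample_metrics: pd.DataFrame
    chosen_hyperparameters: dict
    summary: pd.DataFrame
    #: per resample: {'assessment': original row indices of the assessment
    #: fold, 'smote_sources': original row indices that influenced SMOTE}
    provenance: list[dict] = field(default_factory=list)


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # columns: variable, importance; descending

    def top_variable(self) -> str:
        return str(self.table.iloc[0]["variable"])


def make_learner(name: str, params: Mapping, seed: int):
    """Instantiate a probabilistic binary classifier backend."""
    params = dict(params)
    if name == "random_forest":
        max_features = params.pop("max_features", "sqrt")
        if max_features == "third":
            max_features = 1.0 / 3.0
        return RandomForestClassifier(
            n_estimators=int(params.pop("n_estimators", 100)),
            max_features=max_features,
            random_state=seed,
            n_jobs=1,
            **params,
        )
    if name == "logit_boost":
        # boosted depth-1 stumps under logistic loss: the LogitBoost shape
        return GradientBoostingClassifier(
            n_estimators=int(params.pop("n_estimators", 100)),
            learning_rate=float(params.pop("learning_rate", 0.3)),
            max_depth=1,
            random_state=seed,
            **params,
        )
    if name == "gradient_boosted_trees":
        return GradientBoostingClassifier(
            n_estimators=int(params.pop("n_estimators", 100)),
            learning_rate=float(params.pop("learning_rate", 0.3)),
            max_depth=int(params.pop("max_depth", 4)),
            random_state=seed,
            **params,
        )
    raise ValueError(f"unknown learner {name!r}; expected one of {LEARNER_NAMES}")


def _positive_proba(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    pos_col = list(model.classes_).index(True)
    return proba[:, pos_col]


def stratified_partition(
    labels: Sequence, train_fraction: float = 0.70, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test split; per-class train counts are
    round(class_count * train_fraction)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or (counts == 0).any():
        raise ValueError("both classes must be present with at least one member")
    rng = np.random.default_rng(seed)
    train_parts = []
    test_parts = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = round(count * train_fraction)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Probability a random positive outscores a random negative; ties
    count one half (rank / Mann-Whitney formulation)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(cm: ConfusionMatrix, method_name: str = "", auc_value: float = float("nan")) -> MethodMetrics:
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise UndefinedMetricError("sensitivity/specificity need both classes")
    return MethodMetrics(
        method_name=method_name,
        sensitivity=cm.tp / (cm.tp + cm.fn),
        specificity=cm.tn / (cm.tn + cm.fp),
        accuracy=(cm.tp + cm.tn) / cm.total,
        auc=auc_value,
    )


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionMatrix:
    pred = scores >= threshold
    y = np.asarray(labels, dtype=bool)
    return ConfusionMatrix(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


def summarize_resamples(resample_metrics: pd.DataFrame) -> pd.DataFrame:
    """Six-number summary per metric column (linear-interpolation quantiles,
    the type-7 convention)."""
    if len(resample_metrics) == 0:
        raise ValueError("no resample metrics to summarize")
    rows = {}
    for col in resample_metrics.columns:
        v = resample_metrics[col].to_numpy(dtype=float)
        rows[col] = {
            "Minimum": float(v.min()),
            "1st Quartile": float(np.quantile(v, 0.25)),
            "Median": float(np.quantile(v, 0.5)),
            "Mean": float(v.mean()),
            "3rd Quartile": float(np.quantile(v, 0.75)),
            "Maximum": float(v.max()),
        }
    return pd.DataFrame(rows).T[
        ["Minimum", "1st Quartile", "Median", "Mean", "3rd Quartile", "Maximum"]
    ]


def _expand_grid(grid: Mapping[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def repeated_cv_train(
    learner_name: str,
    X: pd.DataFrame | np.ndarray,
    y: Sequence,
    folds: int = 5,
    repeats: int = 10,
    selection_metric: str = "sensitivity",
    smote_config: SmoteConfig | None = None,
    seed: int = 0,
    param_grid: Mapping[str, list] | None = None,
    threshold: float = 0.5,
):
    """Repeated stratified CV with within-fold SMOTE and metric-weighted
    hyperparameter selection.

    Returns ``(CVResult, fitted_model)``; the fitted model is refit on the
    full input (SMOTE-balanced) with the chosen hyperparameters. One master
    seed expands deterministically into fold, SMOTE, and learner seeds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if selection_metric not in ("sensitivity", "roc_auc"):
        raise ValueError("selection_metric must be 'sensitivity' or 'roc_auc'")
    if learner_name not in LEARNER_NAMES:
        raise ValueError(f"unknown learner {learner_name!r}")
    smote_config = smote_config or SmoteConfig()

    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=bool)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} members; cannot stratify into "
            f"{folds} folds with both classes in every fold"
        )

    ss = np.random.SeedSequence(seed)
    cv_seed, smote_seed, learner_seed, final_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    )
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=cv_seed
    )

    # SMOTE is hyperparameter-independent: balance each analysis fold once.
    balanced = []
    provenance = []
    smote_rng = np.random.default_rng(smote_seed)
    for train_idx, assess_idx in splitter.split(Xa, ya):
        res = smote_sample(Xa[train_idx], ya[train_idx], smote_config, seed=smote_rng)
        provenance.append(
            {
                "assessment": assess_idx.copy(),
                "smote_sources": train_idx[res.source_rows],
            }
        )
        balanced.append((res.X, res.y.astype(bool), assess_idx))

    grid = _expand_grid(dict(param_grid) if param_grid is not None else DEFAULT_GRIDS[learner_name])
    results_per_param: list[pd.DataFrame] = []
    for params in grid:
        rows = []
        for r, (Xb, yb, assess_idx) in enumerate(balanced):
            model = make_learner(learner_name, params, seed=learner_seed)
            model.fit(Xb, yb)
            scores = _positive_proba(model, Xa[assess_idx])
            y_assess = ya[assess_idx]
            cm = confusion_at_threshold(scores, y_assess, threshold)
            rows.append(
                {
                    "resample": f"Rep{r // folds + 1}.Fold{r % folds + 1}",
                    "roc_auc": auc(scores, y_assess),
                    "sensitivity": cm.tp / (cm.tp + cm.fn),
                    "specificity": cm.tn / (cm.tn + cm.fp),
                }
            )
        results_per_param.append(pd.DataFrame(rows).set_index("resample"))

    means = [df[selection_metric].mean() for df in results_per_param]
    best = int(np.argmax(means))
    metrics = results_per_param[best]

    final_balance = smote_sample(Xa, ya, smote_config, seed=final_seed)
    fitted = make_learner(learner_name, grid[best], seed=learner_seed)
    fitted.fit(final_balance.X, final_balance.y.astype(bool))
    if feature_names is not None:
        fitted.feature_names_ = feature_names

    cv_result = CVResult(
        learner_name=learner_name,
        resample_metrics=metrics,
        chosen_hyperparameters=grid[best],
        summary=summarize_resamples(metrics),
        provenance=provenance,
    )
    return cv_result, fitted


def evaluate_test(
    model, test_matrix, test_labels: Sequence, threshold: float = 0.5
) -> ConfusionMatrix:
    """Confusion matrix on held-out data at the given probability threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    Xa = np.asarray(test_matrix, dtype=float)
    ya = np.asarray(test_labels, dtype=bool)
    if len(Xa) != len(ya):
        raise ValueError("test matrix and labels differ in length")
    scores = _positive_proba(model, Xa)
    return confusion_at_threshold(scores, ya, threshold)


def variable_importance(model, feature_names: Sequence[str] | None = None) -> ImportanceTable:
    """Gain-based importance, rescaled so the top variable scores 100."""
    importances = np.asarray(model.feature_importances_, dtype=float)
    if feature_names is None:
        feature_names = getattr(model, "feature_names_", None) or [
            f"x{i}" for i in range(len(importances))
        ]
    if len(feature_names) != len(importances):
        raise ValueError("feature_names length mismatch")
    scaled = importances * (100.0 / importances.max()) if importances.max() > 0 else importances
    table = (
        pd.DataFrame({"variable": list(feature_names), "importance": scaled})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return ImportanceTable(table)


def predict_scores(model, matrix, ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Two-column frame: variant_id, predicted probability of being PGx."""
    if isinstance(matrix, pd.DataFrame) and ids is None:
        ids = list(matrix.index)
    scores = _positive_proba(model, np.asarray(matrix, dtype=float))
    if ids is None:
        ids = [str(i) for i in range(len(scores))]
    return pd.DataFrame({"variant_id": list(ids), "probability": scores})


def predict_new(
    model,
    unlabeled_matrix,
    annotated_id_set: Iterable[str],
    threshold: float = 0.5,
    ids: Sequence[str] | None = None,
) -> set[str]:
    """Ids predicted PGx (probability >= threshold) that are not already
    annotated."""
    annotated = frozenset(annotated_id_set)
    frame = predict_scores(model, unlabeled_matrix, ids)
    hits = frame.loc[frame["probability"] >= threshold, "variant_id"]
    return {vid for vid in hits if vid not in annotated}


def comparator_metrics(
    score_table: pd.DataFrame,
    labels: Sequence,
    thresholds: Mapping[str, tuple[float, str]],
    *,
    method_names: Sequence[str] | None = None,
) -> tuple[list[MethodMetrics], pd.DataFrame]:
    """Per-method confusion metrics + AUC from raw comparator scores.

    ``thresholds`` maps method (column) name to ``(threshold, direction)``
    where direction is 'higher' (score >= threshold calls PGx) or 'lower'
    (score <= threshold calls PGx). Rows with a missing score are excluded
    for that method and logged.
    """
    ya = np.asarray(labels, dtype=bool)
    if len(score_table) != len(ya):
        raise ValueError("score table and labels differ in length")
    out = []
    log_rows = []
    for method in method_names or list(thresholds):
        thr, direction = thresholds[method]
        if direction not in ("higher", "lower"):
            raise ValueError(f"direction for {method!r} must be 'higher' or 'lower'")
        s = score_table[method].to_numpy(dtype=float)
        ok = ~np.isnan(s)
        n_dropped = int((~ok).sum())
        if n_dropped:
            log_rows.append({"method": method, "excluded_rows": n_dropped})
        s_ok, y_ok = s[ok], ya[ok]
        oriented = s_ok if direction == "higher" else -s_ok
        pred = s_ok >= thr if direction == "higher" else s_ok <= thr
        cm = ConfusionMatrix(
            tp=int((pred & y_ok).sum()),
            fp=int((pred & ~y_ok).sum()),
            tn=int((~pred & ~y_ok).sum()),
            fn=int((~pred & y_ok).sum()),
        )
        out.append(compute_metrics(cm, method_name=method, auc_value=auc(oriented, y_ok)))
    return out, pd.DataFrame(log_rows, columns=["method", "excluded_rows"])


def metrics_to_frame(metrics: list[MethodMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [m.method_name for m in metrics],
            "sensitivity": [m.sensitivity for m in metrics],
            "specificity": [m.specificity for m in metrics],
            "accuracy": [m.accuracy for m in metrics],
            "auc": [m.auc for m in metrics],
        }
    )
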