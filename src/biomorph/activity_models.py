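"""Random-forest activity classifiers with nested-CV and held-out protocols.

Two evaluation protocols are provided, both stratified on the binary
activity label:

* ``nested_cv_evaluate`` — four outer folds repeated five times (20 test
  sets).  Inside each outer training split, hyperparameters are tuned by a
  successive-halving random search (resource = number of trees) with
  stratified five-fold inner CV, the tuned forest is refit on the full outer
  training split, and the operating threshold is chosen from inner
  cross-validation predictions by maximizing Youden's J = TPR − FPR.
* ``train_heldout`` — a single stratified 75/25 split with the same tuning
  and thresholding on the 75%, metrics on the untouched 25%.

Reported per test set: ROC AUC (threshold-free), balanced accuracy and
Matthews correlation at the chosen threshold, plus the confusion counts they
derive from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.experimental import enable_halving_search_cv  # noqa: F401
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import (
    HalvingRandomSearchCV,
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_predict,
    train_test_split,
)

from .profiles_io import MorphProfileTable

__all__ = [
    "CVConfig",
    "ThresholdResult",
    "EvalReport",
    "DEFAULT_PARAM_GRID",
    "youden_threshold",
    "nested_cv_evaluate",
    "train_heldout",
]

logger = logging.getLogger("biomorph.models")

# Declared stand-in hyperparameter space: tree count is the halving resource
# (25 .. 500); the searched dimensions are depth, feature subsampling and
# leaf size.
DEFAULT_PARAM_GRID: dict[str, list] = {
    "max_depth": [5, 10, 20, None],
    "max_features": ["sqrt", "log2", 0.3],
    "min_samples_leaf": [1, 3, 5],
}


@dataclass
class CVConfig:
    n_repeats: int = 5
    n_outer_folds: int = 4
    inner_folds: int = 5
    n_candidates: int = 8
    min_resources: int = 25
    max_resources: int = 500
    param_grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_PARAM_GRID))
    threshold_rule: str = "youden"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ThresholdResult:
    threshold: float
    j_value: float


@dataclass
class EvalReport:
    """Per-test-set metric records (one per outer test set)."""

    records: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def summary(self) -> dict:
        df = self.to_frame()
        return {
            "n_test_sets": len(df),
            "mean_auc": float(df["auc"].mean()),
            "mean_balanced_accuracy": float(df["balanced_accuracy"].mean()),
            "mean_mcc": float(df["mcc"].mean()),
        }

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.to_frame().to_csv(prefix.with_suffix(".csv"), index=False)
        prefix.with_suffix(".json").write_text(
            json.dumps(self.summary(), indent=2, sort_keys=True) + "\n"
        )


def youden_threshold(
    y_true: np.ndarray | pd.Series, scores: np.ndarray | pd.Series
) -> ThresholdResult:
    """Operating point maximizing J = TPR − FPR over observed score cuts.

    Every distinct score is a candidate threshold t with the rule "predict
    positive iff score >= t"; ties in J are broken toward the smallest
    threshold (maximal sensitivity).
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have the same shape")
    pos = y == 1
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present to choose a threshold")
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    best_t, best_j = np.inf, -np.inf
    for t in np.unique(s):  # ascending, so strict improvement keeps smallest tie
        pred = s >= t
        tpr = (pred & pos).sum() / n_pos
        fpr = (pred & ~pos).sum() / n_neg
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, t
    return ThresholdResult(threshold=float(best_t), j_value=float(best_j))


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, MorphProfileTable):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _check_classes(y: np.ndarray, minimum: int = 8) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need a binary label vector (got classes {classes})")
    if counts.min() < minimum:
        raise ValueError(
            f"need >= {minimum} samples per class (got {dict(zip(classes, counts))})"
        )


def _tuned_search(config: CVConfig, seed: int) -> HalvingRandomSearchCV:
    base = RandomForestClassifier(random_state=seed, n_jobs=1)
    return HalvingRandomSearchCV(
        base,
        config.param_grid,
        resource="n_estimators",
        min_resources=config.min_resources,
        max_resources=config.max_resources,
        factor=3,
        n_candidates=config.n_candidates,
        cv=StratifiedKFold(config.inner_folds, shuffle=True, random_state=seed),
        scoring="roc_auc",
        random_state=seed,
        n_jobs=1,
    )


def _fit_tune_threshold(X_tr, y_tr, config: CVConfig, seed: int):
    """Tune on the training split, refit, and pick the Youden threshold from
    inner cross-validation predictions of the tuned model."""
    search = _tuned_search(config, seed).fit(X_tr, y_tr)
    model = search.best_estimator_
    inner = StratifiedKFold(config.inner_folds, shuffle=True, random_state=seed + 1)
    cv_proba = cross_val_predict(
        clone(model), X_tr, y_tr, cv=inner, method="predict_proba", n_jobs=1
    )[:, 1]
    thr = youden_threshold(y_tr, cv_proba)
    return model, thr, search.best_params_


def _test_record(model, thr: ThresholdResult, X_te, y_te) -> dict:
    proba = model.predict_proba(X_te)[:, list(model.classes_).index(1)]
    pred = (proba >= thr.threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y_te, pred, labels=[0, 1]).ravel()
    return {
        "auc": float(roc_auc_score(y_te, proba)),
        "balanced_accuracy": float(balanced_accuracy_score(y_te, pred)),
        "mcc": float(matthews_corrcoef(y_te, pred)),
        "chosen_threshold": thr.threshold,
        "j_value": thr.j_value,
        "tp": int(tp),
        "tn": int(tn),
        "fp": int(fp),
        "fn": int(fn),
    }


def nested_cv_evaluate(X, y, cv_config: CVConfig | None = None) -> EvalReport:
    """Repeated stratified nested CV; one record per outer test set.

    With the default configuration (4 outer folds × 5 repeats) the report
    contains exactly 20 records.  Fully deterministic under the config seed.
    """
    config = cv_config or CVConfig()
    Xm = _as_matrix(X)
    y = np.asarray(y).astype(int)
    _check_classes(y)
    outer = RepeatedStratifiedKFold(
        n_splits=config.n_outer_folds,
        n_repeats=config.n_repeats,
        random_state=config.seed,
    )
    records = []
    for split_idx, (tr, te) in enumerate(outer.split(Xm, y)):
        repeat, fold = divmod(split_idx, config.n_outer_folds)
        fit_seed = config.seed + 100 * split_idx + 1
        model, thr, params = _fit_tune_threshold(Xm[tr], y[tr], config, fit_seed)
        rec = _test_record(model, thr, Xm[te], y[te])
        rec.update({"repeat": repeat, "fold": fold, "hyperparameters": params})
        records.append(rec)
        logger.debug("outer split %d: AUC=%.3f", split_idx, rec["auc"])
    report = EvalReport(records)
    logger.info("nested CV: %s", report.summary())
    return report


def train_heldout(
    X, y, seed: int, cv_config: CVConfig | None = None
) -> tuple[RandomForestClassifier, ThresholdResult, EvalReport]:
    """Stratified 75/25 split: tune + threshold on 75%, metrics on 25%."""
    config = cv_config or CVConfig(seed=seed)
    Xm = _as_matrix(X)
    y = np.asarray(y).astype(int)
    _check_classes(y)
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xm, y, test_size=0.25, random_state=seed, stratify=y
    )
    model, thr, params = _fit_tune_threshold(X_tr, y_tr, config, seed)
    rec = _test_record(model, thr, X_te, y_te)
    rec.update({"repeat": 0, "fold": 0, "hyperparameters": params})
    report = EvalReport([rec])
    logger.info("held-out: %s", report.summary())
    return model, thr, report
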