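"""Classifier evaluation protocols for segment-level pain detection.

The learners themselves come from scikit-learn; this module owns what is
actually protocol-sensitive in subject-level physiological data:

* the hyperparameter grids for the eight classifier families
  (linear / 3rd-order polynomial / RBF SVM, decision tree, random forest,
  MLP, logistic regression, KNN),
* *subject-wise* splitting everywhere — all segments of a subject stay on
  one side of any split, otherwise within-subject correlation leaks labels,
* three evaluation protocols: (1) pooled leave-one-subject-out (LOSO) with a
  nested subject-wise 5-fold grid search inside each training fold,
  (2) train on one dataset / test on the other, and (3) the reverse,
* standardization fitted on training data only (skipped for tree families),
* accuracy / sensitivity / specificity from the pooled confusion counts of
  each test fold, averaged across folds for LOSO.

Grid-search scoring is mean validation accuracy, except the MLP which is
scored by cross-entropy loss (minimized); ties go to the first-listed grid
point, so results are deterministic given the seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .records import ValidationError
from .segments import FEATURE_COLUMNS

_SVM_C = [1, 10, 100, 1000]
_SVM_GAMMA = [0.0001, 0.001, 0.1]

#: Hyperparameter grids per classifier family.
GRIDS: dict[str, list[dict]] = {
    "L-SVM": [{"C": c} for c in _SVM_C],
    "P-SVM": [{"C": c, "gamma": g} for c, g in itertools.product(_SVM_C, _SVM_GAMMA)],
    "R-SVM": [{"C": c, "gamma": g} for c, g in itertools.product(_SVM_C, _SVM_GAMMA)],
    "DecisionTree": [{"criterion": c} for c in ("gini", "entropy")],
    "RandomForest": [{"criterion": c} for c in ("gini", "entropy")],
    "MLP": [
        {"hidden_layers": h, "activation": a, "solver": s, "learning_rate_init": lr}
        for h, a, s, lr in itertools.product(
            (1, 2, 3), ("logistic", "tanh", "relu"), ("sgd", "adam", "lbfgs"), (0.0001, 0.001, 0.01)
        )
    ],
    "LogisticRegression": [
        {"solver": s} for s in ("newton-cg", "lbfgs", "liblinear", "sag", "saga")
    ],
    "KNN": [{"n_neighbors": k} for k in (3, 5, 7, 9)],
}

#: Families that skip feature standardization.
TREE_FAMILIES = {"DecisionTree", "RandomForest"}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid."""

    family: str
    grid: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family not in GRIDS:
            raise ValidationError(f"unknown classifier family {self.family!r}")
        if not self.grid:
            object.__setattr__(self, "grid", GRIDS[self.family])

    @property
    def standardize(self) -> bool:
        return self.family not in TREE_FAMILIES

    @property
    def loss_scored(self) -> bool:
        return self.family == "MLP"


def build_classifier(spec: ClassifierSpec, params: dict, seed: int = 0):
    """Instantiate a (possibly standardized) sklearn pipeline for one grid point."""
    fam = spec.family
    if fam == "L-SVM":
        est = SVC(kernel="linear", C=params["C"], random_state=seed)
    elif fam == "P-SVM":
        est = SVC(kernel="poly", degree=3, C=params["C"], gamma=params["gamma"], random_state=seed)
    elif fam == "R-SVM":
        est = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"], random_state=seed)
    elif fam == "DecisionTree":
        est = DecisionTreeClassifier(criterion=params["criterion"], random_state=seed)
    elif fam == "RandomForest":
        est = RandomForestClassifier(criterion=params["criterion"], random_state=seed)
    elif fam == "MLP":
        est = MLPClassifier(
            hidden_layer_sizes=(100,) * params["hidden_layers"],
            activation=params["activation"],
            solver=params["solver"],
            learning_rate_init=params["learning_rate_init"],
            # with SGD: divide the rate by 5 whenever two consecutive epochs
            # fail to improve (sklearn's "adaptive" schedule)
            learning_rate="adaptive" if params["solver"] == "sgd" else "constant",
            max_iter=100,
            random_state=seed,
        )
    elif fam == "LogisticRegression":
        est = LogisticRegression(solver=params["solver"], max_iter=1000, random_state=seed)
    elif fam == "KNN":
        est = KNeighborsClassifier(n_neighbors=params["n_neighbors"])
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValidationError(fam)
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return Pipeline([("clf", est)])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(accuracy, sensitivity, specificity); ``None`` where a denominator is zero."""
    total = c.tp + c.tn + c.fp + c.fn
    acc = (c.tp + c.tn) / total if total else None
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    return acc, sens, spec


def _subject_folds(subject_ids: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic subject-wise folds: seeded shuffle, then round-robin."""
    uniq = sorted(set(subject_ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    folds: list[list] = [[] for _ in range(n_folds)]
    for i, j in enumerate(order):
        folds[i % n_folds].append(uniq[j])
    return [np.asarray(f) for f in folds]


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        table[FEATURE_COLUMNS].to_numpy(dtype=float),
        table["label"].to_numpy(dtype=int),
        table["subject_id"].to_numpy(),
    )


def grid_search_subjectwise(
    train_table: pd.DataFrame,
    spec: ClassifierSpec,
    seed: int = 0,
    n_folds: int = 5,
    audit=None,
) -> dict:
    """Pick the best grid point by subject-wise cross-validation.

    Subjects are shuffled (seeded) and dealt round-robin into ``n_folds``
    groups; with fewer than ``n_folds`` subjects this degrades to
    leave-one-subject-out with a warning.  Each grid point is scored by the
    mean validation accuracy (or mean cross-entropy loss, minimized, for
    loss-scored families) across folds; ties keep the first-listed point.
    """
    X, y, subj = _xy(train_table)
    n_subjects = len(set(subj))
    if n_subjects < n_folds:
        import logging

        logging.getLogger(__name__).warning(
            "only %d training subjects; falling back to leave-one-subject-out", n_subjects
        )
        n_folds = n_subjects
    if n_folds < 2:
        return spec.grid[0]
    folds = _subject_folds(subj, n_folds, seed)

    best_params = None
    best_score = None
    for params in spec.grid:
        scores = []
        for fold in folds:
            val_mask = np.isin(subj, fold)
            if val_mask.all() or not val_mask.any():
                continue
            if len(set(y[~val_mask])) < 2:
                continue
            if audit is not None:
                audit(set(subj[~val_mask]))
            clf = build_classifier(spec, params, seed)
            clf.fit(X[~val_mask], y[~val_mask])
            if spec.loss_scored:
                proba = clf.predict_proba(X[val_mask])
                scores.append(log_loss(y[val_mask], proba, labels=[0, 1]))
            else:
                scores.append(float(np.mean(clf.predict(X[val_mask]) == y[val_mask])))
        if not scores:
            continue
        score = float(np.mean(scores))
        better = (
            best_score is None
            or (spec.loss_scored and score < best_score - 1e-12)
            or (not spec.loss_scored and score > best_score + 1e-12)
        )
        if better:
            best_score, best_params = score, params
    return best_params if best_params is not None else spec.grid[0]


@dataclass
class EvalResult:
    """Outcome of one evaluation protocol."""

    protocol: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ci_accuracy: tuple[float, float] | None
    ci_sensitivity: tuple[float, float] | None
    ci_specificity: tuple[float, float] | None
    fold_metrics: list[tuple[float | None, float | None, float | None]]
    chosen_params: list[dict]


def _normal_ci(values: list[float]) -> tuple[float, float] | None:
    vals = [v for v in values if v is not None and not math.isnan(v)]
    if len(vals) < 2:
        return None
    mean = float(np.mean(vals))
    half = 1.96 * float(np.std(vals, ddof=1)) / math.sqrt(len(vals))
    return (mean - half, mean + half)


def evaluate_protocol1(
    pooled: pd.DataFrame, spec: ClassifierSpec, seed: int = 0, audit=None
) -> EvalResult:
    """Pooled leave-one-subject-out evaluation with nested grid search.

    For every held-out subject: grid search runs on the remaining subjects
    only (subject-wise 5-fold), the chosen model is refit on all remaining
    segments, and the held-out subject's segments are scored.  Metrics are
    averaged across folds; the CI is the 95% normal approximation over fold
    metrics.

    ``audit``, if given, is called as ``audit(held_subject, training_subjects)``
    before every model fit (grid-search and final) of the corresponding fold —
    instrumentation to verify the held-out subject never enters any fit.
    """
    X, y, subj = _xy(pooled)
    uniq = sorted(set(subj))
    if len(uniq) < 6:
        raise ValidationError("protocol 1 needs at least 6 subjects")
    fold_metrics = []
    chosen = []
    for held in uniq:
        test_mask = subj == held
        train_tab = pooled[~test_mask]
        inner_audit = (lambda tr, h=held: audit(h, tr)) if audit is not None else None
        params = grid_search_subjectwise(train_tab, spec, seed, audit=inner_audit)
        chosen.append(params)
        if audit is not None:
            audit(held, set(subj[~test_mask]))
        clf = build_classifier(spec, params, seed)
        clf.fit(X[~test_mask], y[~test_mask])
        c = ConfusionCounts.from_predictions(y[test_mask], clf.predict(X[test_mask]))
        fold_metrics.append(metrics(c))
    accs, senss, specs = zip(*fold_metrics)

    def _mean(vs):
        vals = [v for v in vs if v is not None]
        return float(np.mean(vals)) if vals else None

    return EvalResult(
        protocol=1,
        accuracy=_mean(accs),
        sensitivity=_mean(senss),
        specificity=_mean(specs),
        ci_accuracy=_normal_ci(list(accs)),
        ci_sensitivity=_normal_ci(list(senss)),
        ci_specificity=_normal_ci(list(specs)),
        fold_metrics=fold_metrics,
        chosen_params=chosen,
    )


def evaluate_cross_dataset(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    spec: ClassifierSpec,
    seed: int = 0,
    protocol: int = 2,
    n_boot: int = 2000,
) -> EvalResult:
    """Train on one dataset, test once on the other (protocols 2 and 3).

    Grid search is subject-wise within the training table; the CI is a
    bootstrap over test segments (``n_boot`` resamples).
    """
    if not len(test_table):
        raise ValidationError("empty test table")
    overlap = set(train_table["subject_id"]) & set(test_table["subject_id"])
    if overlap:
        raise ValidationError(f"overlapping subjects between train and test: {sorted(overlap)}")
    Xtr, ytr, _ = _xy(train_table)
    Xte, yte, _ = _xy(test_table)
    params = grid_search_subjectwise(train_table, spec, seed)
    clf = build_classifier(spec, params, seed)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    c = ConfusionCounts.from_predictions(yte, pred)
    acc, sens, spc = metrics(c)

    rng = np.random.default_rng(seed)
    n = yte.size
    boots = {"acc": [], "sens": [], "spec": []}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        cb = ConfusionCounts.from_predictions(yte[idx], pred[idx])
        a, s, p = metrics(cb)
        if a is not None:
            boots["acc"].append(a)
        if s is not None:
            boots["sens"].append(s)
        if p is not None:
            boots["spec"].append(p)

    def _ci(vals):
        if len(vals) < 2:
            return None
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return (float(lo), float(hi))

    return EvalResult(
        protocol=protocol,
        accuracy=acc,
        sensitivity=sens,
        specificity=spc,
        ci_accuracy=_ci(boots["acc"]),
        ci_sensitivity=_ci(boots["sens"]),
        ci_specificity=_ci(boots["spec"]),
        fold_metrics=[(acc, sens, spc)],
        chosen_params=[params],
    )
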