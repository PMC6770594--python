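"""Evaluation harness: leakage-free split, CV-tuned classifiers, multiclass AUC.

The protocol mirrors the standard supervised evaluation for panel-score
features: the samples are split 80/20 (stratified by group); gene panels
are derived from the *training* samples only; every sample is then
represented by one cell-centered score per group panel; five standard
classifiers (random forest, linear SVM, radial SVM, nearest-shrunken-
centroids — the learner ML tuning frameworks label "pam" — and linear
discriminant analysis) are tuned by stratified k-fold cross-validation on
the training scores, refit, and evaluated on the held-out scores with the
one-vs-one (Hand-and-Till-style) multiclass AUC. The whole procedure is
repeated over seeds and summarized by the per-algorithm median AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import EmptyPanelError, PipelineError
from .features import (
    GenePanel,
    MODE_SCORE_KIND,
    build_group_panels,
    build_score_matrix,
    check_labels,
)
from .preprocessing import ExpressionMatrix, mrn_normalize

__all__ = [
    "ALGORITHMS",
    "SplitPlan",
    "AlgorithmResult",
    "ClassificationReport",
    "RepeatSummary",
    "split_train_test",
    "multiclass_auc",
    "run_pipeline",
    "repeat_evaluation",
    "wilcoxon_focus_vs_rest",
]

#: The five supported learners.
ALGORITHMS = ("rf", "svm_linear", "svm_radial", "pam", "lda")


@dataclass(frozen=True)
class SplitPlan:
    """A stratified train/test split of sample ids (deterministic per seed)."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass(frozen=True, eq=False)
class AlgorithmResult:
    """Outcome for one algorithm in one repeat."""

    algorithm: str
    auc: float
    best_params: dict
    confusion: pd.DataFrame  # true groups x predicted groups
    seed: int


@dataclass(frozen=True, eq=False)
class ClassificationReport:
    """One end-to-end run: panels, per-algorithm results, provenance."""

    mode: str
    seed: int
    plan: SplitPlan
    panels: dict[str, GenePanel]
    results: dict[str, AlgorithmResult]
    models: dict[str, object] = field(repr=False, default_factory=dict)


@dataclass(frozen=True, eq=False)
class RepeatSummary:
    """Aggregate over repeats: per-algorithm AUCs, median and IQR."""

    mode: str
    base_seed: int
    aucs: pd.DataFrame  # repeats x algorithms
    reports: tuple[ClassificationReport, ...] = field(repr=False, default=())

    @property
    def median_auc(self) -> pd.Series:
        return self.aucs.median(axis=0)

    @property
    def iqr_auc(self) -> pd.Series:
        return self.aucs.quantile(0.75) - self.aucs.quantile(0.25)


def split_train_test(labels: pd.Series, fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Stratified random split: about ``fraction`` of each group trains.

    Per-group train counts are ``round(fraction * n_g)`` clamped so both
    sides keep at least one sample; groups of size 1 are rejected.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = check_labels(labels)
    sizes = labels.value_counts()
    too_small = sizes[sizes < 2]
    if len(too_small):
        raise ValueError(
            f"groups need >= 2 samples to split: {too_small.index.tolist()}"
        )
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for group in sorted(labels.unique()):
        ids = sorted(labels.index[labels == group])
        n = len(ids)
        n_train = int(np.clip(round(fraction * n), 1, n - 1))
        perm = rng.permutation(n)
        train += [ids[i] for i in perm[:n_train]]
        test += [ids[i] for i in perm[n_train:]]
    return SplitPlan(
        train_ids=tuple(train), test_ids=tuple(test), fraction=fraction, seed=seed
    )


def multiclass_auc(probabilities: pd.DataFrame, truth: pd.Series) -> float:
    """One-vs-one multiclass AUC (Hand-and-Till-style pairwise average).

    For every unordered class pair (i, j) the two directed AUCs — class-i
    probability column ranking i against j, and vice versa — are averaged;
    the result is the mean over pairs. Equals the ordinary AUC for two
    classes; 0.5 is chance.

    ``probabilities`` must have one column per class (rows summing to 1)
    and cover every class present in ``truth``.
    """
    truth = truth.reindex(probabilities.index)
    if truth.isna().any():
        raise ValueError("truth labels missing for some probability rows")
    classes = sorted(truth.unique())
    if len(classes) < 2:
        raise ValueError("multiclass AUC needs >= 2 classes in truth")
    missing = [c for c in classes if c not in probabilities.columns]
    if missing:
        raise ValueError(f"no probability column for class(es): {missing}")
    rows = probabilities.to_numpy(dtype=float).sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if len(classes) == 2:  # both directed AUCs coincide with the plain AUC
        positive = classes[1]
        return float(
            roc_auc_score(
                (truth == positive).astype(int),
                probabilities[positive].to_numpy(dtype=float),
            )
        )
    return float(
        roc_auc_score(
            truth.to_numpy(),
            probabilities[classes].to_numpy(dtype=float),
            multi_class="ovo",
            average="macro",
            labels=classes,
        )
    )


class NearestShrunkenCentroids(BaseEstimator, ClassifierMixin):
    """Nearest-shrunken-centroids classifier with distance-softmax scores.

    Wraps :class:`sklearn.neighbors.NearestCentroid` with a shrink
    threshold and adds ``predict_proba`` as a softmax over negative
    squared distances to the shrunken centroids — a monotone score
    sufficient for ranking-based metrics such as AUC.
    """

    def __init__(self, shrink_threshold: float = 0.0):
        self.shrink_threshold = shrink_threshold

    def fit(self, X, y):
        thr = self.shrink_threshold if self.shrink_threshold > 0 else None
        self._nc = NearestCentroid(shrink_threshold=thr)
        self._nc.fit(X, y)
        self.classes_ = self._nc.classes_
        return self

    def _distances(self, X):
        X = np.asarray(X, dtype=float)
        cents = self._nc.centroids_
        return ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)

    def predict(self, X):
        check_is_fitted(self, "_nc")
        return self.classes_[np.argmin(self._distances(X), axis=1)]

    def predict_proba(self, X):
        check_is_fitted(self, "_nc")
        d = self._distances(X)
        z = -0.5 * (d - d.min(axis=1, keepdims=True))
        w = np.exp(z)
        return w / w.sum(axis=1, keepdims=True)


def _calibrated_svc(**svc_kwargs) -> CalibratedClassifierCV:
    """SVC with Platt-calibrated probabilities (deterministic 5-fold)."""
    return CalibratedClassifierCV(SVC(**svc_kwargs), method="sigmoid", ensemble=False)


def _make_algorithms(
    names: Sequence[str], n_classes: int, seed: int, gamma_scale: float
) -> dict[str, tuple[BaseEstimator, dict]]:
    """Estimator + hyperparameter grid per requested algorithm.

    Features are standardized (train-set mean/sd, inside the CV pipeline)
    for the SVMs, LDA and the centroid classifier; the random forest uses
    raw features. Grids are small and standard: radial SVM C in
    {0.25, 1, 4, 16} x gamma in scale-heuristic x {0.5, 1, 2}; linear SVM
    C in {0.25, 1, 4}; RF 500 trees, max_features 1..n_classes; shrinkage
    threshold over 10 log-spaced values; LDA has no grid.
    """
    scaled = lambda est: Pipeline([("scale", StandardScaler()), ("model", est)])
    algos: dict[str, tuple[BaseEstimator, dict]] = {}
    for name in names:
        if name == "rf":
            est = RandomForestClassifier(
                n_estimators=500, random_state=seed, n_jobs=1
            )
            grid = {"max_features": list(range(1, n_classes + 1))}
        elif name == "svm_linear":
            est = scaled(_calibrated_svc(kernel="linear", random_state=seed))
            grid = {"model__estimator__C": [0.25, 1.0, 4.0]}
        elif name == "svm_radial":
            est = scaled(_calibrated_svc(kernel="rbf", random_state=seed))
            grid = {
                "model__estimator__C": [0.25, 1.0, 4.0, 16.0],
                "model__estimator__gamma": [
                    0.5 * gamma_scale, gamma_scale, 2.0 * gamma_scale
                ],
            }
        elif name == "pam":
            est = scaled(NearestShrunkenCentroids())
            grid = {
                "model__shrink_threshold": [0.0]
                + list(np.logspace(-2, 0.5, 9))
            }
        elif name == "lda":
            est = scaled(LinearDiscriminantAnalysis())
            grid = {}
        else:
            raise ValueError(f"unknown algorithm {name!r}; pick from {ALGORITHMS}")
        algos[name] = (est, grid)
    return algos


def run_pipeline(
    m: ExpressionMatrix,
    labels: pd.Series,
    plan: SplitPlan,
    mode: str = "high_mae",
    k: int = 200,
    algorithms: Sequence[str] = ("svm_radial",),
    cv_folds: int = 10,
    alpha: float = 0.05,
    min_nonzero: int = 10,
) -> ClassificationReport:
    """One leakage-free evaluation run.

    Panels are derived from the training samples only; train and test
    score matrices are built per sample from those fixed panels (a
    sample's scores never depend on other samples); hyperparameters are
    tuned by stratified ``cv_folds``-fold CV on the training scores; the
    best model is refit on the full training set and scored on the test
    set with the one-vs-one multiclass AUC. Raw-count input is MRN-
    normalized up front.
    """
    labels = check_labels(labels, m.sample_ids)
    if m.value_kind == "raw_count":
        m = mrn_normalize(m)
    train_cols = list(plan.train_ids)
    test_cols = list(plan.test_ids)
    train_matrix = ExpressionMatrix(m.values[train_cols], value_kind=m.value_kind)
    try:
        panels = build_group_panels(
            train_matrix, labels[train_cols], mode, k=k,
            alpha=alpha, min_nonzero=min_nonzero,
        )
    except EmptyPanelError as err:
        raise PipelineError(f"panel derivation failed (mode={mode}): {err}") from err

    scores = build_score_matrix(m, panels, MODE_SCORE_KIND[mode])
    X_train = scores.loc[train_cols]
    X_test = scores.loc[test_cols]
    y_train = labels[train_cols]
    y_test = labels[test_cols]
    classes = sorted(labels.unique())

    # Radial-SVM gamma "scale" heuristic on the standardized training scores.
    std = X_train.to_numpy(dtype=float)
    std = (std - std.mean(axis=0)) / np.where(std.std(axis=0) == 0, 1, std.std(axis=0))
    gamma_scale = 1.0 / (X_train.shape[1] * max(std.var(), 1e-12))

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=plan.seed)
    results: dict[str, AlgorithmResult] = {}
    models: dict[str, object] = {}
    for name, (est, grid) in _make_algorithms(
        algorithms, len(classes), plan.seed, gamma_scale
    ).items():
        search = GridSearchCV(est, grid, scoring="roc_auc_ovo", cv=cv, n_jobs=1)
        search.fit(X_train.to_numpy(dtype=float), y_train.to_numpy())
        model = search.best_estimator_
        proba = pd.DataFrame(
            model.predict_proba(X_test.to_numpy(dtype=float)),
            index=X_test.index,
            columns=list(model.classes_),
        )
        auc = multiclass_auc(proba, y_test)
        pred = model.predict(X_test.to_numpy(dtype=float))
        conf = pd.DataFrame(
            confusion_matrix(y_test.to_numpy(), pred, labels=classes),
            index=classes,
            columns=classes,
        )
        results[name] = AlgorithmResult(
            algorithm=name,
            auc=auc,
            best_params=dict(search.best_params_),
            confusion=conf,
            seed=plan.seed,
        )
        models[name] = model
    return ClassificationReport(
        mode=mode, seed=plan.seed, plan=plan, panels=panels,
        results=results, models=models,
    )


def repeat_evaluation(
    m: ExpressionMatrix,
    labels: pd.Series,
    n_repeats: int = 10,
    base_seed: int = 0,
    fraction: float = 0.8,
    keep_reports: bool = False,
    **pipeline_kwargs,
) -> RepeatSummary:
    """Repeat the 80/20 evaluation with seeds base_seed..base_seed+n-1."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if m.value_kind == "raw_count":
        m = mrn_normalize(m)  # normalize once, not per repeat
    rows = []
    reports = []
    for r in range(n_repeats):
        seed = base_seed + r
        plan = split_train_test(labels, fraction=fraction, seed=seed)
        report = run_pipeline(m, labels, plan, **pipeline_kwargs)
        rows.append({name: res.auc for name, res in report.results.items()})
        if keep_reports:
            reports.append(report)
    aucs = pd.DataFrame(rows, index=pd.RangeIndex(n_repeats, name="repeat"))
    return RepeatSummary(
        mode=pipeline_kwargs.get("mode", "high_mae"),
        base_seed=base_seed,
        aucs=aucs,
        reports=tuple(reports),
    )


def wilcoxon_focus_vs_rest(scores: pd.Series, labels: pd.Series, group: str) -> float:
    """Two-sided Wilcoxon rank-sum p-value, focus group vs all others.

    Exact enumeration when both sides have <= 25 untied observations;
    normal approximation with tie correction otherwise.
    """
    labels = check_labels(labels, scores.index)
    focus = scores[labels == group].to_numpy(dtype=float)
    rest = scores[labels != group].to_numpy(dtype=float)
    if focus.size == 0 or rest.size == 0:
        raise ValueError(f"focus group {group!r} or its complement is empty")
    pooled = np.concatenate([focus, rest])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (focus.size <= 25 and rest.size <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(focus, rest, alternative="two-sided", method=method)
    return float(res.pvalue)
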