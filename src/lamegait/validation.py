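"""Leave-one-out validation and confusion-matrix performance statistics.

Validation is leave-one-epoch-out: for each epoch the discriminant model is
refitted on all remaining epochs and the held-out epoch is predicted; the
tallies form a confusion matrix with predicted behaviours as rows and
observed behaviours as columns.  Per class c, in one-vs-rest terms,

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / total     precision   = TP / (TP + FP)

with TP the diagonal count, FN the rest of c's observed column, FP the rest
of c's predicted row, and TN the remainder.  The per-observed-class
"prediction accuracy" (diagonal over observed-column total) is identical to
sensitivity; both are reported.  Metrics whose denominator is zero are
reported as missing, not as 0.  Percentages are rounded half-up to whole
numbers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ANALYSIS_CLASSES, FEATURE_NAMES, build_feature_matrix
from .qda import GaussianQDA
from .ranking import RankingConfig, rank_features, top_k
from .synthetic import StudyConfig, generate_study
from .io import segment_epochs


def pct(fraction: float | None) -> int | None:
    """Fraction -> whole percent, rounded half-up (0.815 -> 82)."""
    if fraction is None:
        return None
    # tiny epsilon so exact halves survive binary representation (0.345 -> 35)
    return int(math.floor(fraction * 100.0 + 0.5 + 1e-9))


@dataclass
class ConfusionMatrix:
    """Observed-by-predicted epoch counts (rows predicted, columns observed)."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.classes)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be square over the class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, observed, predicted, classes=None) -> "ConfusionMatrix":
        observed = np.asarray(observed)
        predicted = np.asarray(predicted)
        if classes is None:
            classes = sorted(set(observed) | set(predicted))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for o, p in zip(observed, predicted):
            counts[index[p], index[o]] += 1
        return cls(classes=list(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def observed_total(self, c: str) -> int:
        return int(self.counts[:, self.classes.index(c)].sum())

    def predicted_total(self, c: str) -> int:
        return int(self.counts[self.classes.index(c), :].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "predicted\\observed"
        df.to_csv(path)


def prediction_accuracy(cm: ConfusionMatrix, observed_class: str) -> float | None:
    """Diagonal count over observed-column total; None for an empty column."""
    if observed_class not in cm.classes:
        raise ValueError(f"unknown class {observed_class!r}")
    i = cm.classes.index(observed_class)
    col = cm.counts[:, i].sum()
    if col == 0:
        return None
    return float(cm.counts[i, i]) / float(col)


@dataclass
class ClassPerformance:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    precision: float | None
    prediction_accuracy: float | None


@dataclass
class PerformanceReport:
    """One-vs-rest counts and metrics per class."""

    classes: list[str]
    per_class: dict[str, ClassPerformance]
    total: int
    notes: tuple[str, ...] = (
        "specificity = TN/(TN+FP), the standard one-vs-rest definition",
    )

    def to_frame(self, as_percent: bool = False) -> pd.DataFrame:
        rows = {}
        for c in self.classes:
            p = self.per_class[c]
            metrics = {
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "accuracy": p.accuracy,
                "precision": p.precision,
                "prediction_accuracy": p.prediction_accuracy,
            }
            if as_percent:
                metrics = {k: pct(v) for k, v in metrics.items()}
            rows[c] = {"TP": p.tp, "FP": p.fp, "FN": p.fn, "TN": p.tn, **metrics}
        return pd.DataFrame(rows).T

    def to_json(self) -> str:
        doc = {"total": self.total, "notes": list(self.notes), "classes": {}}
        for c in self.classes:
            p = self.per_class[c]
            doc["classes"][c] = {
                "TP": p.tp, "FP": p.fp, "FN": p.fn, "TN": p.tn,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "accuracy": p.accuracy,
                "precision": p.precision,
                "prediction_accuracy": p.prediction_accuracy,
                "sensitivity_pct": pct(p.sensitivity),
                "specificity_pct": pct(p.specificity),
                "accuracy_pct": pct(p.accuracy),
                "precision_pct": pct(p.precision),
                "prediction_accuracy_pct": pct(p.prediction_accuracy),
            }
        return json.dumps(doc, indent=2, sort_keys=True)


def performance(cm: ConfusionMatrix) -> PerformanceReport:
    """One-vs-rest performance statistics for every class of a matrix."""
    total = cm.total
    if total == 0:
        raise ValueError("all-zero confusion matrix")

    def ratio(num, den):
        return float(num) / float(den) if den > 0 else None

    per_class = {}
    for i, c in enumerate(cm.classes):
        tp = int(cm.counts[i, i])
        fn = int(cm.counts[:, i].sum()) - tp
        fp = int(cm.counts[i, :].sum()) - tp
        tn = total - tp - fn - fp
        per_class[c] = ClassPerformance(
            tp=tp, fp=fp, fn=fn, tn=tn,
            sensitivity=ratio(tp, tp + fn),
            specificity=ratio(tn, tn + fp),
            accuracy=ratio(tp + tn, total),
            precision=ratio(tp, tp + fp),
            prediction_accuracy=prediction_accuracy(cm, c),
        )
    return PerformanceReport(classes=list(cm.classes), per_class=per_class, total=total)


def loocv(matrix: pd.DataFrame, feature_subset: list[str],
          shrinkage: float = 1e-6, priors: str = "empirical",
          classes: list[str] | None = None) -> ConfusionMatrix:
    """Leave-one-epoch-out cross-validation of the QDA classifier.

    For each row the model is refitted on all other rows and the held-out
    row predicted.  Every class must have >= 3 rows so each fold retains at
    least 2 rows per class; otherwise the run aborts reporting the number
    of untrainable folds.
    """
    missing = [f for f in feature_subset if f not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns {missing}")
    X = matrix.loc[:, feature_subset].to_numpy(dtype=float)
    y = matrix["behaviour"].to_numpy()
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("LOOCV requires at least 2 classes")
    if np.any(counts < 3):
        bad = labels[counts < 3]
        n_untrainable = int(counts[counts < 3].sum())
        raise ValueError(
            f"classes {bad} have < 3 epochs; {n_untrainable} folds would be "
            "untrainable (a fold would leave < 2 rows in a class)")
    n = len(y)
    predicted = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = GaussianQDA(shrinkage=shrinkage, priors=priors)
        model.fit(X[mask], y[mask])
        predicted[i] = model.predict(X[i][None, :])[0]
        mask[i] = True
    if classes is None:
        classes = list(labels)
    return ConfusionMatrix.from_predictions(y, predicted, classes=classes)


@dataclass
class AnalysisConfig:
    """End-to-end run configuration: study shape, analysis, model settings."""

    study: StudyConfig = field(default_factory=StudyConfig)
    deployment: str = "ear"
    analysis: str = "II"
    ranking: RankingConfig = field(default_factory=RankingConfig)
    n_features: int = 3
    shrinkage: float = 1e-6
    priors: str = "empirical"

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSIS_CLASSES:
            raise ValueError("analysis must be 'I' or 'II'")
        if self.deployment not in self.study.deployments:
            raise ValueError(
                f"deployment {self.deployment!r} not generated by the study "
                f"config (has {self.study.deployments})")


@dataclass
class AnalysisReport:
    """Everything one end-to-end analysis produces."""

    config: AnalysisConfig
    feature_matrix: pd.DataFrame
    ranking: "object"
    selected_features: list[str]
    confusion: ConfusionMatrix
    performance: PerformanceReport
    dropped_classes: list[str]

    def to_json(self) -> str:
        doc = {
            "analysis": self.config.analysis,
            "deployment": self.config.deployment,
            "seed": self.config.study.seed,
            "selected_features": self.selected_features,
            "ranking_order": list(self.ranking.order),
            "importance": self.ranking.importance,
            "dropped_classes": self.dropped_classes,
            "classes": self.confusion.classes,
            "confusion_predicted_rows_observed_cols": self.confusion.counts.tolist(),
            "performance": json.loads(self.performance.to_json()),
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run one full analysis: simulate -> segment -> features -> rank ->
    select top features -> LOOCV -> confusion matrix -> performance report.

    Classes requested by the analysis but absent from the generated data
    (e.g. no lying epochs in an ear-style study) are dropped with a warning.
    """
    study = generate_study(config.study)
    epochs = []
    for (animal_id, deployment), (series, annotations) in sorted(study.items()):
        if deployment != config.deployment:
            continue
        epochs.extend(segment_epochs(series, annotations, config.study.epoch_s))
    matrix = build_feature_matrix(epochs, analysis=config.analysis)
    present = set(matrix["behaviour"])
    requested = ANALYSIS_CLASSES[config.analysis]
    dropped = [c for c in requested if c not in present]
    if dropped:
        warnings.warn(
            f"classes absent from the data and dropped: {dropped}",
            RuntimeWarning, stacklevel=2)
    ranking = rank_features(matrix, config.ranking)
    selected = top_k(ranking, config.n_features)
    classes = [c for c in requested if c in present]
    cm = loocv(matrix, selected, shrinkage=config.shrinkage,
               priors=config.priors, classes=classes)
    report = performance(cm)
    return AnalysisReport(
        config=config, feature_matrix=matrix, ranking=ranking,
        selected_features=selected, confusion=cm, performance=report,
        dropped_classes=dropped)
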