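"""Nested leave-one-out cross-validation, ROC analysis, and diagnostic metrics.

The LOOCV harness is strictly nested: for every fold the held-out subject is
excluded from voxelwise discrimination, watershed partitioning, region
growing, feature selection, standardization, and SVM training — the entire
adaptive feature-extraction-and-training procedure re-runs on the remaining
subjects, and only then scores the held-out map.  Pooled held-out scores are
standardized to Z scores and evaluated by ROC/AUC and 2x2 contingency
metrics.  Feature-frequency maps record, per voxel, the fraction of folds
whose selected elements covered it (a 0-1 stability scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import isnan

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cohort import Cohort
from .compare import (
    PipelineConfig,
    RegionalElement,
    element_feature,
    extract_elements,
    select_features,
    train_svm,
)

__all__ = [
    "ConfusionMatrix",
    "DiagnosticReport",
    "RocCurve",
    "FeatureFrequencyMap",
    "LoocvResult",
    "loocv",
    "confusion",
    "diagnostic_metrics",
    "roc_curve",
    "auc",
    "best_threshold",
    "feature_frequency",
    "round_pct",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 contingency counts for a binary diagnostic comparison."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class DiagnosticReport:
    """Diagnostic-performance summary: percentages, AUC, and threshold.

    Undefined ratios (zero denominator) are reported as NaN — explicitly
    not-available rather than silently 0.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float = float("nan")
    threshold: float = float("nan")
    n_features: int | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "ppv_pct": self.ppv,
            "npv_pct": self.npv,
            "auc": self.auc,
            "threshold": self.threshold,
            "n_features": self.n_features,
        }


@dataclass
class RocCurve:
    """ROC staircase: (false-positive rate, true-positive rate) per threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass
class FeatureFrequencyMap:
    """Per-voxel fraction of LOOCV folds whose selected elements covered it."""

    frequency: dict[str, np.ndarray]  # compartment -> 3D grid in [0, 1]
    n_folds: int


@dataclass
class LoocvResult:
    """Pooled held-out outputs of one nested LOOCV experiment."""

    subject_ids: list[str]
    truth: np.ndarray  # 1 = positive group
    scores: np.ndarray  # Z-standardized held-out decision values
    raw_scores: np.ndarray
    predictions: np.ndarray  # 1 = predicted positive (decision > 0)
    features_per_fold: list[int]
    frequency_map: FeatureFrequencyMap
    positive_group: str
    negative_group: str

    @property
    def accuracy(self) -> float:
        return float((self.predictions == self.truth).mean())


def round_pct(x: float, decimals: int = 1) -> float:
    """Round a percentage half away from zero (table convention)."""
    if isnan(x):
        return x
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def loocv(
    cohort: Cohort,
    positive_group: str,
    negative_group: str,
    config: PipelineConfig | None = None,
) -> LoocvResult:
    """Run strictly nested leave-one-out cross-validation on a cohort.

    Every stage — discrimination mapping, watershed, region growing,
    SVM-criteria feature selection, standardization, training — is refit per
    fold on the training subjects only.  Returns one held-out prediction per
    subject plus the feature-frequency map and per-fold selected counts.
    """
    cfg = config or PipelineConfig()
    subjects = [s for s in cohort.subjects if s.group in (positive_group, negative_group)]
    if positive_group == negative_group:
        raise ValueError("positive and negative groups must differ")
    y = np.array([1 if s.group == positive_group else 0 for s in subjects])
    for cls, name in ((1, positive_group), (0, negative_group)):
        if (y == cls).sum() < 3:
            raise ValueError(
                f"group {name!r} has fewer than 3 subjects; LOOCV needs >= 3"
            )

    stacks = {
        comp: np.stack(
            [cohort.maps[s.id].compartments()[comp].data for s in subjects]
        )
        for comp in cfg.compartments
    }
    n = len(subjects)
    shape = next(iter(stacks.values())).shape[1:]
    coverage = {comp: np.zeros(shape) for comp in cfg.compartments}

    raw_scores = np.empty(n)
    predictions = np.empty(n, dtype=int)
    features_per_fold: list[int] = []

    for i in range(n):
        train_idx = np.array([j for j in range(n) if j != i])
        y_train = y[train_idx]
        candidates: list[RegionalElement] = []
        for comp in cfg.compartments:
            candidates.extend(
                extract_elements(
                    stacks[comp][train_idx], y_train, cfg, compartment=comp
                )
            )
        if not candidates:
            # nothing discriminative in this fold: score 0, majority vote
            raw_scores[i] = 0.0
            predictions[i] = int(y_train.mean() >= 0.5)
            features_per_fold.append(0)
            continue
        candidates.sort(
            key=lambda e: (-e.discriminative_power, -e.consistency, e.compartment,
                           e.seed_voxel)
        )
        candidates = candidates[: cfg.max_candidates]
        fset = select_features(candidates, y_train, cfg)
        selected = fset.selected
        model = train_svm(fset.matrix(), y_train, cfg)

        x_test = np.array(
            [
                element_feature(e, stacks[e.compartment][i])
                for e in selected
            ]
        )
        score = float(model.decision(x_test.reshape(1, -1))[0])
        raw_scores[i] = score
        predictions[i] = int(score > 0)
        features_per_fold.append(len(selected))
        for e in selected:
            v = e.voxels
            coverage[e.compartment][v[:, 0], v[:, 1], v[:, 2]] += 1.0

    sd = raw_scores.std()
    z = (raw_scores - raw_scores.mean()) / sd if sd > 0 else raw_scores - raw_scores.mean()
    freq = FeatureFrequencyMap(
        frequency={c: g / n for c, g in coverage.items()}, n_folds=n
    )
    return LoocvResult(
        subject_ids=[s.id for s in subjects],
        truth=y,
        scores=z,
        raw_scores=raw_scores,
        predictions=predictions,
        features_per_fold=features_per_fold,
        frequency_map=freq,
        positive_group=positive_group,
        negative_group=negative_group,
    )


def confusion(predictions, truth, positive_class=1) -> ConfusionMatrix:
    """Build the 2x2 contingency table of predictions against truth."""
    p = np.asarray(predictions)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("predictions and truth must have equal length")
    known = np.unique(np.concatenate([p, t]))
    if positive_class not in known and len(known) > 0:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    pos_p = p == positive_class
    pos_t = t == positive_class
    return ConfusionMatrix(
        tp=int((pos_p & pos_t).sum()),
        fn=int((~pos_p & pos_t).sum()),
        fp=int((pos_p & ~pos_t).sum()),
        tn=int((~pos_p & ~pos_t).sum()),
    )


def _ratio_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def diagnostic_metrics(cm: ConfusionMatrix, n_features: int | None = None) -> DiagnosticReport:
    """Diagnostic accuracy, sensitivity, specificity, PPV, and NPV (percent).

    DA = (tp + tn) / n; sensitivity = tp / (tp + fn);
    specificity = tn / (tn + fp); PPV = tp / (tp + fp);
    NPV = tn / (tn + fn).  Zero-denominator ratios are NaN (not available).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return DiagnosticReport(
        accuracy=_ratio_pct(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio_pct(cm.tp, cm.tp + cm.fn),
        specificity=_ratio_pct(cm.tn, cm.tn + cm.fp),
        ppv=_ratio_pct(cm.tp, cm.tp + cm.fp),
        npv=_ratio_pct(cm.tn, cm.tn + cm.fn),
        n_features=n_features,
    )


def _binary_truth(truth, positive_class) -> np.ndarray:
    t = np.asarray(truth)
    pos = t == positive_class
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    return pos.astype(int)


def roc_curve(scores, truth, positive_class=1) -> RocCurve:
    """ROC staircase over all distinct score thresholds.

    True-positive rate (sensitivity) against false-positive rate
    (1 - specificity), one point per threshold, beginning at (0, 0) and
    ending at (1, 1).
    """
    s = np.asarray(scores, dtype=np.float64)
    t = _binary_truth(truth, positive_class)
    if np.ptp(s) == 0:
        warnings.warn("constant scores: degenerate two-point ROC", stacklevel=2)
    fpr, tpr, thr = _sk_roc_curve(t, s, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def auc(scores, truth, positive_class=1) -> float:
    """Area under the ROC curve as the concordant-pair probability.

    Equals the probability that a randomly chosen truly positive subject
    outscores a randomly chosen negative one, ties counting one half —
    identical to trapezoidal integration of the ROC staircase.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = _binary_truth(truth, positive_class)
    pos = s[t == 1]
    neg = s[t == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def best_threshold(scores, truth, positive_class=1) -> tuple[float, DiagnosticReport]:
    """Score cut maximizing overall accuracy; ties favor higher specificity.

    A subject is called positive when its score is >= the threshold.
    Thresholds swept are midpoints between consecutive distinct scores plus
    sentinels below and above the score range.  Returns the chosen threshold
    and the full diagnostic report at that cut (AUC included).
    """
    s = np.asarray(scores, dtype=np.float64)
    t = _binary_truth(truth, positive_class)
    uniq = np.unique(s)
    cuts = [uniq[0] - 1.0]
    cuts.extend((uniq[:-1] + uniq[1:]) / 2.0)
    cuts.append(uniq[-1] + 1.0)

    best_cut, best_key = None, None
    for cut in cuts:
        pred = (s >= cut).astype(int)
        cm = confusion(pred, t, positive_class=1)
        acc = (cm.tp + cm.tn) / cm.total
        spec = cm.tn / cm.n_negative if cm.n_negative else 0.0
        key = (acc, spec, cut)  # ties -> higher specificity -> higher cut
        if best_key is None or key > best_key:
            best_key, best_cut = key, cut
    pred = (s >= best_cut).astype(int)
    report = diagnostic_metrics(confusion(pred, t, positive_class=1))
    report.auc = auc(s, t, positive_class=1)
    report.threshold = float(best_cut)
    return float(best_cut), report


def feature_frequency(
    fold_selections: list[list[RegionalElement]],
    shape: tuple[int, int, int],
    compartments: tuple[str, ...] = ("GM", "WM", "VENT"),
) -> FeatureFrequencyMap:
    """Fraction of folds in which each voxel belonged to a selected element."""
    if not fold_selections:
        raise ValueError("need at least one fold")
    n = len(fold_selections)
    grids = {c: np.zeros(shape) for c in compartments}
    for elements in fold_selections:
        seen = {c: np.zeros(shape, dtype=bool) for c in compartments}
        for e in elements:
            v = e.voxels
            seen[e.compartment][v[:, 0], v[:, 1], v[:, 2]] = True
        for c in compartments:
            grids[c] += seen[c]
    return FeatureFrequencyMap(
        frequency={c: g / n for c, g in grids.items()}, n_folds=n
    )
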