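"""Cross-validated evaluation: folds, per-beat voting, AAMI-style metrics.

The evaluation protocol is 10-fold stratified cross-validation over beats.
When a reducer produces several rows per beat (one per time window), the
per-window classifier decisions are aggregated into one beat label by
majority vote, confidences breaking ties.  Confusion counts accumulate over
the folds, so every beat contributes exactly one prediction.

Metrics follow the AAMI reporting practice: per-class positive predictive
value (PPV), sensitivity (SEN) and specificity (SPEC) from the 4x4
confusion matrix, plus a binary normal-vs-abnormal collapse where the
abnormal classes (S, V, F) are pooled as positives.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import fit_classifier
from .dataset import CLASS_ORDER
from .reduction import (expand_window_rows, per_node_pc1, select_window,
                        select_window_subset)
from .scattering import ScatteringConfig, transform_batch

logger = logging.getLogger("scatterbeat")


@dataclass
class FoldSplit:
    assignments: np.ndarray    # fold id (0..n_folds-1) per beat
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_folds(labels, n_folds: int = 10, seed: int = 0,
               groups=None) -> FoldSplit:
    """Stratified random partition into folds of near-equal size.

    With ``groups`` (one key per beat), beats sharing a key — e.g. noisy
    copies of the same source beat — are kept in the same fold, at the cost
    of slightly less even fold sizes.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    counts = Counter(labels.tolist())
    small = [c for c, n in counts.items() if n < n_folds]
    if small:
        raise ValueError(f"classes smaller than n_folds: {small}")
    if groups is None:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros(len(labels)), labels)
    else:
        from sklearn.model_selection import StratifiedGroupKFold
        sgk = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
        splits = sgk.split(np.zeros(len(labels)), labels, groups=groups)
    assignments = np.empty(len(labels), dtype=int)
    for fold, (_, test) in enumerate(splits):
        assignments[test] = fold
    return FoldSplit(assignments, n_folds, seed)


def majority_vote(window_labels, window_confidences=None) -> str:
    """Aggregate per-window predictions for one beat into a single label.

    The most frequent label wins; ties are broken by the largest summed
    confidence among the tied classes, then by AAMI class order.
    """
    window_labels = [str(l) for l in window_labels]
    if not window_labels:
        raise ValueError("need at least one window prediction")
    counts = Counter(window_labels)
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    if window_confidences is not None:
        conf = {c: 0.0 for c in tied}
        for lab, w in zip(window_labels, window_confidences):
            if lab in conf:
                conf[lab] += float(w)
        best = max(conf.values())
        tied = [c for c in tied if conf[c] == best]
    return min(tied, key=lambda c: CLASS_ORDER.index(c)
               if c in CLASS_ORDER else 99)


@dataclass
class ConfusionMatrix:
    """True-vs-predicted counts with a fixed class order (default N,S,V,F)."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, cls: str) -> np.ndarray:
        return self.counts[self.classes.index(cls)]

    def accuracy(self) -> float:
        """Overall multiclass accuracy in percent."""
        return 100.0 * np.trace(self.counts) / self.total


def confusion_matrix(true_labels, predicted_labels,
                     classes: tuple[str, ...] = CLASS_ORDER) -> ConfusionMatrix:
    true_labels = [str(l) for l in true_labels]
    predicted_labels = [str(l) for l in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(classes)}
    bad = [l for l in set(true_labels) | set(predicted_labels) if l not in index]
    if bad:
        raise ValueError(f"labels outside {classes}: {bad}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def _ratio(num: float, den: float) -> float:
    """Percentage, or NaN when the denominator is zero (undefined, not 0)."""
    return 100.0 * num / den if den > 0 else float("nan")


@dataclass
class MetricsReport:
    """Per-class and binary-collapse metrics, all in percent."""

    per_class: dict = field(default_factory=dict)   # cls -> {ppv, sen, spec}
    binary: dict = field(default_factory=dict)      # tp/tn/fp/fn/acc/ppv/sen/spec
    accuracy: float = float("nan")                  # overall multiclass, %

    def to_dict(self) -> dict:
        return {"per_class": self.per_class, "binary": self.binary,
                "accuracy": self.accuracy}


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest PPV, SEN and SPEC per class, in percent.

    SEN(c) = cm[c,c] / row_sum(c); PPV(c) = cm[c,c] / col_sum(c);
    SPEC(c) = TN_c / (TN_c + FP_c) with FP_c the off-class column mass and
    TN_c the remainder.  Zero denominators yield NaN.
    """
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts
    report = MetricsReport(accuracy=cm.accuracy())
    for i, cls in enumerate(cm.classes):
        tp = c[i, i]
        row, col = c[i].sum(), c[:, i].sum()
        fp = col - tp
        tn = cm.total - row - fp
        report.per_class[cls] = {
            "ppv": _ratio(tp, col),
            "sen": _ratio(tp, row),
            "spec": _ratio(tn, tn + fp),
        }
    return report


def binary_collapse_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Normal-vs-abnormal collapse: N negative, {S, V, F} pooled positive.

    TP = abnormal beats predicted as any abnormal class, FN = abnormal
    predicted N, FP = N predicted abnormal, TN = N predicted N.
    """
    if cm.classes[0] != "N":
        raise ValueError("binary collapse expects class order starting at N")
    c = cm.counts
    tn = int(c[0, 0])
    fp = int(c[0, 1:].sum())
    fn = int(c[1:, 0].sum())
    tp = int(c[1:, 1:].sum())
    report = MetricsReport(accuracy=cm.accuracy())
    report.binary = {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "acc": _ratio(tp + tn, tp + tn + fp + fn),
        "ppv": _ratio(tp, tp + fp),
        "sen": _ratio(tp, tp + fn),
        "spec": _ratio(tn, tn + fp),
    }
    return report


def full_metrics(cm: ConfusionMatrix) -> MetricsReport:
    report = per_class_metrics(cm)
    report.binary = binary_collapse_metrics(cm).binary
    return report


def format_report(cm: ConfusionMatrix, report: MetricsReport) -> str:
    """Text table mirroring the per-class and summary layouts."""
    lines = ["Original  " + "".join(f"{c:>9}" for c in cm.classes)
             + f"{'PPV (%)':>10}{'SEN (%)':>10}{'SPEC (%)':>10}"]
    for i, cls in enumerate(cm.classes):
        m = report.per_class.get(cls, {})
        lines.append(
            f"{cls:<10}" + "".join(f"{cm.counts[i, j]:>9}" for j in range(len(cm.classes)))
            + "".join(f"{m.get(k, float('nan')):>10.1f}" for k in ("ppv", "sen", "spec")))
    b = report.binary
    if b:
        lines.append("")
        lines.append(f"{'TP':>9}{'TN':>9}{'FP':>9}{'FN':>9}"
                     f"{'ACC (%)':>10}{'PPV (%)':>10}{'SEN (%)':>10}{'SPEC (%)':>10}")
        lines.append(f"{b['tp']:>9}{b['tn']:>9}{b['fp']:>9}{b['fn']:>9}"
                     + "".join(f"{b[k]:>10.1f}" for k in ("acc", "ppv", "sen", "spec")))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

def _reduce(reducer: str, tensors: np.ndarray, labels: np.ndarray,
            fit_index=None):
    """Apply a reducer spec string; returns a FeatureMatrix."""
    if reducer in ("windows-all", "all"):
        return expand_window_rows(tensors, labels)
    if reducer.startswith("window:"):
        return select_window(tensors, labels, int(reducer.split(":")[1]))
    if reducer.startswith("windows:"):
        idx = [int(i) for i in reducer.split(":")[1].split(",")]
        return select_window_subset(tensors, labels, idx)
    if reducer == "pca1":
        fm, _ = per_node_pc1(tensors, labels, fit_index=fit_index)
        return fm
    raise ValueError(f"unknown reducer spec {reducer!r}")


def run_experiment(beats=None, config: ScatteringConfig | None = None,
                   reducer: str = "window:3", classifier: str = "knn",
                   n_folds: int = 10, seed: int = 0, tensors=None,
                   labels=None, classifier_params: dict | None = None,
                   pca_fit_on_all: bool = False, group_by_source: bool = False,
                   augment_train_to: int | None = None,
                   noise_variance: float = 0.05
                   ) -> tuple[MetricsReport, ConfusionMatrix]:
    """Cross-validated pipeline: scattering -> reduction -> classify -> vote.

    Either ``beats`` (Beat objects) or precomputed ``(tensors, labels)`` may
    be supplied.  Per fold, the reducer and classifier see only training
    rows (the leading-PC reducer fits on the training fold unless
    ``pca_fit_on_all``); multi-window rows of each test beat are merged by
    majority vote.  Confusion counts accumulate across folds.

    Two strict variants (both require ``beats``): ``group_by_source`` keeps
    beats sharing (record, R-index) — e.g. noisy copies of one source
    beat — in the same fold; ``augment_train_to`` defers class balancing to
    inside each fold, augmenting the training beats only, so no noisy copy
    of a test beat ever reaches training.
    """
    from .dataset import augment_to_balance
    from .scattering import build_filter_banks

    classifier_params = classifier_params or {}
    bank = None
    if beats is not None and len(beats) > 0:
        config = config or ScatteringConfig(signal_length=len(beats[0].samples))
        bank = build_filter_banks(config)
        if tensors is None:
            tensors, labels = transform_batch(beats, config, bank=bank)
    elif tensors is None:
        raise ValueError("no input beats")
    if (group_by_source or augment_train_to) and beats is None:
        raise ValueError("group_by_source / augment_train_to need Beat inputs")
    tensors = np.asarray(tensors)
    labels = np.asarray([str(l) for l in labels])

    groups = None
    if group_by_source:
        groups = np.asarray([f"{b.record_id}:{b.r_index}" for b in beats])
    folds = make_folds(labels, n_folds=n_folds, seed=seed, groups=groups)
    n = len(labels)
    predicted = np.empty(n, dtype=object)
    for fold in range(n_folds):
        train_ix, test_ix = folds.train_indices(fold), folds.test_indices(fold)
        if augment_train_to is None:
            fold_tensors, fold_labels = tensors, labels
            fit_ix, test_beats = train_ix, test_ix
            train_sel = train_ix
        else:
            balanced = augment_to_balance(
                [beats[i] for i in train_ix], target_per_class=augment_train_to,
                noise_variance=noise_variance, seed=seed + fold)
            tr_t, tr_l = transform_batch(balanced, config, bank=bank)
            fold_tensors = np.concatenate([tr_t, tensors[test_ix]])
            fold_labels = np.concatenate([tr_l, labels[test_ix]])
            fit_ix = np.arange(len(tr_l))
            train_sel = fit_ix
            test_beats = np.arange(len(tr_l), len(fold_labels))
        if reducer == "pca1" and not pca_fit_on_all:
            fm = _reduce(reducer, fold_tensors, fold_labels, fit_index=fit_ix)
        else:
            fm = _reduce(reducer, fold_tensors, fold_labels)
        train_rows = np.isin(fm.beat_index, train_sel)
        test_rows = np.isin(fm.beat_index, test_beats)
        model, predict = fit_classifier(
            classifier, fm.features[train_rows], fm.labels[train_rows],
            seed=seed + fold, **classifier_params)
        pred, conf = predict(model, fm.features[test_rows])
        row_beats = fm.beat_index[test_rows]
        for out_pos, b in zip(test_ix, test_beats):
            mask = row_beats == b
            predicted[out_pos] = majority_vote(pred[mask], conf[mask])
        logger.info("fold %d/%d: %d train rows, %d test beats",
                    fold + 1, n_folds, int(train_rows.sum()), len(test_ix))
    cm = confusion_matrix(labels, predicted)
    return full_metrics(cm), cm
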