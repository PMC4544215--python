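"""Nested contiguous 10-fold cross-validation, ROC area, per-class
misclassification, confidence-threshold sweeps, and the manual-relabeling
mitigation simulation.

Per fold the trial timeline is cut into ten contiguous slices: slice k is the
validation set, slice (k+1) mod 10 establishes the discrimination threshold,
and the remaining eight slices train the xDAWN filters and BLDA classifier.
Every slice serves as validation exactly once.  Validation scores are pooled
across folds for the headline Az; per-fold values are kept as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import blda, xdawn
from .confidence import (confidence, percentile_thresholds, select_threshold)
from .preprocess import EpochedData
from .simulate import BACKGROUND, NONTARGET, TARGET

logger = logging.getLogger(__name__)

N_FOLDS = 10

#: The three discriminations: positive class is always "target"; the value
#: lists the classes excluded before fold construction.
DISCRIMINATIONS = {
    "to_tvb": (),  # TO sessions contain no non-targets
    "tn_tvb": (NONTARGET,),  # targets vs backgrounds, non-targets omitted
    "tn_tvbnt": (),  # targets vs backgrounds + non-targets
}


@dataclass
class FoldScheme:
    """Contiguous train / threshold / validation assignment per fold."""

    n_trials: int
    slices: list  # 10 contiguous (start, stop) pairs
    n_folds: int = N_FOLDS

    def fold(self, k: int) -> tuple:
        """(train_idx, threshold_idx, validation_idx) for fold k."""
        val = k
        thr = (k + 1) % self.n_folds
        val_idx = np.arange(*self.slices[val])
        thr_idx = np.arange(*self.slices[thr])
        train_idx = np.concatenate(
            [np.arange(*self.slices[j]) for j in range(self.n_folds)
             if j not in (val, thr)]
        )
        return train_idx, thr_idx, val_idx


def make_folds(n_trials: int, n_folds: int = N_FOLDS) -> FoldScheme:
    """Balanced contiguous slices; sizes differ by at most one, deterministic."""
    if n_trials < n_folds:
        raise ValueError(f"need at least {n_folds} trials, got {n_trials}")
    bounds = [int(np.floor(i * n_trials / n_folds)) for i in range(n_folds + 1)]
    slices = [(bounds[i], bounds[i + 1]) for i in range(n_folds)]
    return FoldScheme(n_trials=n_trials, slices=slices, n_folds=n_folds)


def az(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (trapezoidal; ties count half)."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes to compute Az")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def misclassification(predicted: np.ndarray, true_class: np.ndarray) -> dict:
    """Per-class error: targets predicted non-target; others predicted target."""
    predicted = np.asarray(predicted).astype(bool)
    true_class = np.asarray(true_class, dtype=object)
    out = {}
    for cls in (TARGET, NONTARGET, BACKGROUND):
        sel = true_class == cls
        if not sel.any():
            logger.info("class %s absent; misclassification omitted", cls)
            continue
        wrong = ~predicted[sel] if cls == TARGET else predicted[sel]
        out[cls] = float(wrong.mean())
    return out


@dataclass
class SweepPoint:
    percentile: int
    threshold: float
    retained_fraction: float
    retained_fraction_by_class: dict
    az_classifier_only: float | None
    misclass_classifier_only: dict
    az_with_manual: float
    misclass_with_manual: dict


@dataclass
class EvaluationReport:
    az_per_fold: list
    az_pooled: float
    misclass_by_class: dict
    kappa_per_fold: list
    scores: np.ndarray
    confidences: np.ndarray
    predicted: np.ndarray
    labels: np.ndarray  # binary truth
    true_class: np.ndarray  # 3-level truth
    sweep: list = field(default_factory=list)  # SweepPoint per percentile


def run_fold(epochs: EpochedData, labels_binary: np.ndarray,
             fold: tuple, n_filters: int = 8,
             threshold_on: str = "threshold_slice") -> dict:
    """Train on the training slices, place kappa, score the validation slice.

    Only the training slices touch filter and classifier fitting; only the
    threshold slice (or, with ``threshold_on='train'``, the training scores)
    places kappa.  Returns scores, confidences, predictions, kappa and the
    trained model for leakage checks.
    """
    train_idx, thr_idx, val_idx = fold
    n_filters = min(n_filters, epochs.n_channels)
    train = _subset(epochs, train_idx)
    X, target_on, all_on = xdawn.stack_epochs(train)
    X = np.asarray(X)
    filters = xdawn.fit_xdawn(
        X, target_on, all_on, n1=train.n_samples, n2=train.n_samples,
        n_filters=n_filters,
    )
    feats_train = xdawn.apply_filters(train, filters)
    model = blda.fit(feats_train, labels_binary[train_idx])
    scores_train = blda.score(model, feats_train)
    score_min, score_max = float(scores_train.min()), float(scores_train.max())

    if threshold_on == "train":
        kappa = select_threshold(scores_train, labels_binary[train_idx])
    else:
        scores_thr = blda.score(model, xdawn.apply_filters(
            _subset(epochs, thr_idx), filters))
        thr_labels = labels_binary[thr_idx]
        if thr_labels.all() or not thr_labels.any():
            logger.warning(
                "threshold slice is single-class; falling back to training "
                "scores for kappa"
            )
            kappa = select_threshold(scores_train, labels_binary[train_idx])
        else:
            kappa = select_threshold(scores_thr, thr_labels)
    # Eq. 6 needs score_min < kappa < score_max; a kappa placed on the
    # threshold slice can stray outside the training extrema, so clip inward.
    span = score_max - score_min
    kappa = float(np.clip(kappa, score_min + 1e-9 * span,
                          score_max - 1e-9 * span))

    scores_val = blda.score(model, xdawn.apply_filters(
        _subset(epochs, val_idx), filters))
    return {
        "scores": scores_val,
        "confidences": confidence(scores_val, kappa, score_min, score_max),
        "predicted": scores_val > kappa,
        "kappa": kappa,
        "score_min": score_min,
        "score_max": score_max,
        "model": model,
        "filters": filters,
    }


def _subset(epochs: EpochedData, idx: np.ndarray) -> EpochedData:
    return EpochedData(
        data=epochs.data[idx],
        sampling_rate_hz=epochs.sampling_rate_hz,
        window_ms=epochs.window_ms,
        labels=epochs.labels[idx],
        channel_labels=list(epochs.channel_labels),
        onsets_s=epochs.onsets_s[idx],
    )


def run_pipeline(epochs: EpochedData, discrimination: str = "to_tvb",
                 n_filters: int = 8, threshold_on: str = "threshold_slice",
                 sweep: bool = False) -> EvaluationReport:
    """Full nested-CV evaluation of one session for one discrimination."""
    if discrimination not in DISCRIMINATIONS:
        raise ValueError(
            f"unknown discrimination {discrimination!r}; "
            f"choose from {sorted(DISCRIMINATIONS)}"
        )
    excluded = DISCRIMINATIONS[discrimination]
    if excluded:
        keep = ~np.isin(epochs.labels, excluded)
        epochs = _subset(epochs, np.flatnonzero(keep))
    labels_binary = (epochs.labels == TARGET).astype(bool)
    if not labels_binary.any() or labels_binary.all():
        raise ValueError("discrimination requires both classes present")

    scheme = make_folds(epochs.n_trials)
    az_per_fold, kappa_per_fold = [], []
    pooled = {"scores": [], "confidences": [], "predicted": [],
              "labels": [], "true_class": []}
    for k in range(scheme.n_folds):
        fold = scheme.fold(k)
        res = run_fold(epochs, labels_binary, fold, n_filters=n_filters,
                       threshold_on=threshold_on)
        val_idx = fold[2]
        val_labels = labels_binary[val_idx]
        az_per_fold.append(
            az(res["scores"], val_labels)
            if val_labels.any() and not val_labels.all() else None
        )
        kappa_per_fold.append(res["kappa"])
        pooled["scores"].append(res["scores"])
        pooled["confidences"].append(res["confidences"])
        pooled["predicted"].append(res["predicted"])
        pooled["labels"].append(val_labels)
        pooled["true_class"].append(epochs.labels[val_idx])

    scores = np.concatenate(pooled["scores"])
    labels = np.concatenate(pooled["labels"])
    predicted = np.concatenate(pooled["predicted"])
    confidences = np.concatenate(pooled["confidences"])
    true_class = np.concatenate(pooled["true_class"])
    report = EvaluationReport(
        az_per_fold=az_per_fold,
        az_pooled=az(scores, labels),
        misclass_by_class=misclassification(predicted, true_class),
        kappa_per_fold=kappa_per_fold,
        scores=scores,
        confidences=confidences,
        predicted=predicted,
        labels=labels,
        true_class=true_class,
    )
    if sweep:
        report.sweep = sweep_confidence(report)
    return report


def sweep_confidence(report: EvaluationReport,
                     percentiles: np.ndarray | None = None) -> list:
    """Classifier-only and mitigated metrics per confidence percentile.

    At percentile p the lowest p% of trials (by confidence, pooled across
    folds) form the low-confidence subset; classifier-only metrics are
    computed on the retained high-confidence subset, mitigated metrics over
    all trials with the low-confidence subset manually relabeled.
    """
    if percentiles is None:
        percentiles = np.arange(0, 100, 10)
    thresholds = percentile_thresholds(report.confidences, percentiles)
    points = []
    for p in sorted(thresholds):
        t = thresholds[p]
        retained = report.confidences >= t
        by_class = {}
        for cls in (TARGET, NONTARGET, BACKGROUND):
            sel = report.true_class == cls
            if sel.any():
                by_class[cls] = float(retained[sel].mean())
        ret_labels = report.labels[retained]
        if ret_labels.any() and not ret_labels.all():
            az_only = az(report.scores[retained], ret_labels)
        else:
            logger.info("percentile %d retains a single class; Az omitted", p)
            az_only = None
        mis_only = misclassification(report.predicted[retained],
                                     report.true_class[retained])
        az_man, mis_man = simulate_mitigation(report, t)
        points.append(SweepPoint(
            percentile=int(p),
            threshold=float(t),
            retained_fraction=float(retained.mean()),
            retained_fraction_by_class=by_class,
            az_classifier_only=az_only,
            misclass_classifier_only=mis_only,
            az_with_manual=az_man,
            misclass_with_manual=mis_man,
        ))
    return points


def simulate_mitigation(report: EvaluationReport,
                        threshold: float) -> tuple:
    """Manually relabel trials below the confidence threshold.

    Manual labels are the true labels (the manual labeler is assumed perfectly
    accurate); metrics are recomputed over ALL trials.  For Az, manual trials
    take maximal-certainty scores (max+eps for true targets, min-eps for true
    non-targets) so they sort outside the retained trials without disturbing
    their ordering.
    """
    manual = report.confidences < threshold
    predicted = report.predicted.copy()
    predicted[manual] = report.labels[manual]
    scores = report.scores.copy()
    eps = (scores.max() - scores.min()) * 1e-3 + 1e-12
    scores[manual & report.labels] = scores.max() + eps
    scores[manual & ~report.labels] = scores.min() - eps
    return (
        az(scores, report.labels),
        misclassification(predicted, report.true_class),
    )


def labeling_time_overhead(manual_fraction: float,
                           seconds_per_manual: float = 1.0,
                           seconds_per_rsvp_image: float = 0.5) -> float:
    """Extra labeling time, as a percentage of the RSVP viewing time.

    With 30% of trials manually labeled at 1 s each against 0.5 s of RSVP
    presentation per image, the overhead is 60%.
    """
    if manual_fraction < 0 or seconds_per_manual < 0:
        raise ValueError("inputs must be non-negative")
    if seconds_per_rsvp_image <= 0:
        raise ValueError("RSVP presentation time must be positive")
    return 100.0 * (manual_fraction * seconds_per_manual) / seconds_per_rsvp_image


def report_frames(report: EvaluationReport) -> dict:
    """CSV-ready tables: one row per fold and one per sweep percentile."""
    import pandas as pd

    folds = pd.DataFrame({
        "fold": np.arange(len(report.az_per_fold)),
        "az": report.az_per_fold,
        "kappa": report.kappa_per_fold,
    })
    rows = []
    for pt in report.sweep:
        row = {
            "percentile": pt.percentile,
            "threshold": pt.threshold,
            "retained_fraction": pt.retained_fraction,
            "az_classifier_only": pt.az_classifier_only,
            "az_with_manual": pt.az_with_manual,
        }
        for cls, v in pt.misclass_classifier_only.items():
            row[f"misclass_{cls}"] = v
        for cls, v in pt.misclass_with_manual.items():
            row[f"misclass_manual_{cls}"] = v
        for cls, v in pt.retained_fraction_by_class.items():
            row[f"retained_{cls}"] = v
        rows.append(row)
    return {"folds": folds, "sweep": pd.DataFrame(rows)}
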