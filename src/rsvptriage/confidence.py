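"""Discrimination threshold and the distance-to-boundary confidence measure.

The threshold kappa maximizes TPR - FPR (Youden's J) over cut points placed
midway between adjacent distinct scores.  Confidence rescales a trial's
distance from kappa by the training-set score extrema,

    Conf = (Score - kappa) / (max(Score) - kappa)   if Score >  kappa
         = (Score - kappa) / (min(Score) - kappa)   if Score <= kappa,

so it lies in [0, 1] on the training range; validation scores beyond the
training extrema clip to 1.  Percentile thresholds split trials into low
(strictly below) and high (at or above) confidence subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScoredTrials:
    """Per-trial classification record for one validation set."""

    scores: np.ndarray
    kappa: float
    score_min: float
    score_max: float
    confidences: np.ndarray
    predicted: np.ndarray  # bool: score > kappa
    true_class: np.ndarray  # 3-level labels
    labels: np.ndarray  # bool: binary ground truth of the discrimination


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cut point maximizing TPR - FPR; J ties break toward higher kappa.

    The higher-kappa tie rule predicts fewer positives — the conservative
    choice for triage.  Invariant under dataset replication.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes to place a threshold")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("all scores identical; no cut point exists")
    cuts = 0.5 * (distinct[:-1] + distinct[1:])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    best_kappa, best_j = None, None
    for kappa in cuts:
        pred = scores > kappa
        # integer-exact J * (n_pos * n_neg): ties must compare exactly
        j = int((pred & labels).sum()) * n_neg - int(
            (pred & ~labels).sum()) * n_pos
        if best_j is None or j >= best_j:  # >= : later (higher) cut wins ties
            best_j, best_kappa = j, kappa
    return float(best_kappa)


def confidence(scores: np.ndarray, kappa: float, score_min: float,
               score_max: float) -> np.ndarray:
    """Normalized distance from the boundary, clipped to [0, 1]."""
    if not (score_min < kappa < score_max):
        raise ValueError(
            "kappa must lie strictly between the training score extrema"
        )
    scores = np.asarray(scores, dtype=float)
    upper = (scores - kappa) / (score_max - kappa)
    lower = (scores - kappa) / (score_min - kappa)
    conf = np.where(scores > kappa, upper, lower)
    return np.clip(conf, 0.0, 1.0)


def score_trials(scores: np.ndarray, kappa: float, score_min: float,
                 score_max: float, true_class: np.ndarray,
                 labels: np.ndarray) -> ScoredTrials:
    scores = np.asarray(scores, dtype=float)
    return ScoredTrials(
        scores=scores,
        kappa=float(kappa),
        score_min=float(score_min),
        score_max=float(score_max),
        confidences=confidence(scores, kappa, score_min, score_max),
        predicted=scores > kappa,
        true_class=np.asarray(true_class, dtype=object),
        labels=np.asarray(labels).astype(bool),
    )


def percentile_thresholds(confidences: np.ndarray,
                          percentiles: np.ndarray | None = None) -> dict:
    """Empirical thresholds t_p with p% of trials strictly below t_p.

    t_p is the order statistic at rank floor(p*n/100); at p = 0 every trial is
    high-confidence.  Ties at the boundary land in the high-confidence subset
    (the split uses ``confidence >= t_p``), so the retained fraction can exceed
    1 - p/100 when values repeat.
    """
    confidences = np.asarray(confidences, dtype=float)
    if confidences.size == 0:
        raise ValueError("empty confidence list")
    if percentiles is None:
        percentiles = np.arange(0, 100, 10)
    ordered = np.sort(confidences)
    n = ordered.size
    out = {}
    for p in percentiles:
        rank = int(np.floor(p * n / 100.0))
        out[int(p)] = float(ordered[min(rank, n - 1)])
    return out


def trials_to_frame(st: ScoredTrials):
    """Per-trial CSV-ready table: score, confidence, prediction, true class."""
    import pandas as pd

    return pd.DataFrame(
        {
            "score": st.scores,
            "confidence": st.confidences,
            "predicted_target": st.predicted,
            "true_class": st.true_class,
        }
    )
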