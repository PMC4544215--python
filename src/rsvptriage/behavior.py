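"""Button-press scoring and signal-detection metrics.

A press within (onset + 200 ms, onset + 1000 ms] of a rare stimulus is
attributed to that stimulus: a hit if it was a target, a false positive if it
was a non-target.  Presses attributable to no rare stimulus count as
background false positives.  Hit rate, false-positive rate and the
sensitivity index

    d' = Z(HR) - Z(FPR)

follow, with Z the probit (inverse standard-normal CDF) and half-count edge
correction when a rate hits 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BACKGROUND, NONTARGET, TARGET, EventSequence

ATTRIBUTION_WINDOW_MS = (200.0, 1000.0)


@dataclass
class BehavioralCounts:
    hits: int
    misses: int
    correct_rejects_by_class: dict
    false_positives_by_class: dict
    reaction_times_ms: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )


@dataclass
class DetectionMetrics:
    HR: float
    FPR: float
    d_prime: float
    reaction_times_ms: np.ndarray


def attribute_presses(seq: EventSequence,
                      window_ms: tuple = ATTRIBUTION_WINDOW_MS) -> BehavioralCounts:
    """Assign each press to at most one stimulus.

    A press eligible for several rare stimuli (impossible under the >=2
    background gap at 2 Hz, but possible for arbitrary inputs) goes to the most
    recent not-yet-credited one — the reaction-time-plausible reading.  Presses
    left over are charged to the background class.
    """
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    rare_idx = np.flatnonzero(seq.mask(TARGET, NONTARGET))
    credited = np.zeros(rare_idx.size, dtype=bool)

    hits = 0
    rts = []
    fp = {NONTARGET: 0, BACKGROUND: 0}
    for press in np.sort(seq.presses_s):
        eligible = np.flatnonzero(
            (press > seq.onsets_s[rare_idx] + lo)
            & (press <= seq.onsets_s[rare_idx] + hi)
            & ~credited
        )
        if eligible.size == 0:
            fp[BACKGROUND] += 1
            continue
        j = eligible[-1]  # most recent eligible stimulus
        credited[j] = True
        stim = rare_idx[j]
        if seq.classes[stim] == TARGET:
            hits += 1
            rts.append((press - seq.onsets_s[stim]) * 1000.0)
        else:
            fp[NONTARGET] += 1

    n_target = int(seq.mask(TARGET).sum())
    n_nontarget = int(seq.mask(NONTARGET).sum())
    n_background = int(seq.mask(BACKGROUND).sum())
    return BehavioralCounts(
        hits=hits,
        misses=n_target - hits,
        correct_rejects_by_class={
            NONTARGET: n_nontarget - fp[NONTARGET],
            BACKGROUND: n_background - fp[BACKGROUND],
        },
        false_positives_by_class=dict(fp),
        reaction_times_ms=np.asarray(sorted(rts)),
    )


def _edge_correct(k: int, n: int) -> float:
    """k/n with the half-count correction pulling 0 and 1 into (0, 1)."""
    if n <= 0:
        raise ValueError("rate denominator must be positive")
    if k == 0:
        return 1.0 / (2 * n)
    if k == n:
        return 1.0 - 1.0 / (2 * n)
    return k / n


def rates(counts: BehavioralCounts,
          fp_classes: tuple = (NONTARGET, BACKGROUND)) -> tuple:
    """(HR, FPR): HR = Hit/(Hit+Miss), FPR pooled over ``fp_classes``."""
    n_t = counts.hits + counts.misses
    hr = _edge_correct(counts.hits, n_t)
    fp = sum(counts.false_positives_by_class.get(c, 0) for c in fp_classes)
    cr = sum(counts.correct_rejects_by_class.get(c, 0) for c in fp_classes)
    if fp + cr == 0:
        raise ValueError(f"no stimuli in false-positive classes {fp_classes}")
    fpr = _edge_correct(fp, fp + cr)
    return hr, fpr


def d_prime(hr: float, fpr: float) -> float:
    """Z(HR) - Z(FPR); inputs must already be edge-corrected into (0, 1)."""
    if not (0.0 < hr < 1.0 and 0.0 < fpr < 1.0):
        raise ValueError("HR and FPR must lie strictly in (0, 1); edge-correct first")
    return float(stats.norm.ppf(hr) - stats.norm.ppf(fpr))


def detection_metrics(seq: EventSequence,
                      fp_classes: tuple = (NONTARGET, BACKGROUND),
                      window_ms: tuple = ATTRIBUTION_WINDOW_MS) -> DetectionMetrics:
    counts = attribute_presses(seq, window_ms)
    hr, fpr = rates(counts, fp_classes=tuple(
        c for c in fp_classes
        if counts.correct_rejects_by_class.get(c, 0)
        + counts.false_positives_by_class.get(c, 0) > 0
    ))
    return DetectionMetrics(
        HR=hr, FPR=fpr, d_prime=d_prime(hr, fpr),
        reaction_times_ms=counts.reaction_times_ms,
    )


def behavioral_table(seq: EventSequence) -> pd.DataFrame:
    """One-row summary: counts, per-class and pooled rates, d', RT summary."""
    counts = attribute_presses(seq)
    row = {
        "hits": counts.hits,
        "misses": counts.misses,
        "fp_nontarget": counts.false_positives_by_class[NONTARGET],
        "fp_background": counts.false_positives_by_class[BACKGROUND],
        "cr_nontarget": counts.correct_rejects_by_class[NONTARGET],
        "cr_background": counts.correct_rejects_by_class[BACKGROUND],
    }
    hr, fpr = rates(counts, fp_classes=tuple(
        c for c in (NONTARGET, BACKGROUND)
        if counts.correct_rejects_by_class[c]
        + counts.false_positives_by_class[c] > 0
    ))
    row["HR"] = hr
    row["FPR_pooled"] = fpr
    row["d_prime"] = d_prime(hr, fpr)
    for cls in (NONTARGET, BACKGROUND):
        n = counts.correct_rejects_by_class[cls] + counts.false_positives_by_class[cls]
        row[f"FPR_{cls}"] = (
            _edge_correct(counts.false_positives_by_class[cls], n) if n else np.nan
        )
    rt = counts.reaction_times_ms
    row["rt_median_ms"] = float(np.median(rt)) if rt.size else np.nan
    row["rt_iqr_ms"] = (
        float(np.subtract(*np.percentile(rt, [75, 25]))) if rt.size else np.nan
    )
    return pd.DataFrame([row])
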