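"""Class-conditional average waveforms, windowed mean amplitudes, difference
waves, and confidence-based ERP splits."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedData, window_to_samples

logger = logging.getLogger(__name__)


@dataclass
class ERPSet:
    waveforms: dict  # class -> channels x samples, uV
    n_trials: dict  # class -> count
    window_ms: tuple
    sampling_rate_hz: float
    channel_labels: list


def grand_average(epochs: EpochedData) -> ERPSet:
    """Arithmetic mean over trials, per class; empty classes are skipped.

    When press data exist, filter the epochs to hits and correct rejections
    upstream before averaging.
    """
    waveforms, n_trials = {}, {}
    for cls in np.unique(epochs.labels):
        sel = epochs.labels == cls
        if not sel.any():  # pragma: no cover - unique() guarantees presence
            logger.warning("class %s has no trials; excluded", cls)
            continue
        waveforms[str(cls)] = epochs.data[sel].mean(axis=0)
        n_trials[str(cls)] = int(sel.sum())
    return ERPSet(
        waveforms=waveforms,
        n_trials=n_trials,
        window_ms=epochs.window_ms,
        sampling_rate_hz=epochs.sampling_rate_hz,
        channel_labels=list(epochs.channel_labels),
    )


def mean_amplitude(erps: ERPSet, channel: str = "Pz",
                   window_ms: tuple = (400.0, 800.0)) -> dict:
    """Mean waveform amplitude over the window at one channel, per class."""
    if channel not in erps.channel_labels:
        raise ValueError(f"unknown channel {channel!r}")
    ch = erps.channel_labels.index(channel)
    lo_w, hi_w = window_to_samples(erps.window_ms, erps.sampling_rate_hz)
    lo, hi = window_to_samples(window_ms, erps.sampling_rate_hz)
    if lo < lo_w or hi > hi_w or hi <= lo:
        raise ValueError("analysis window outside the epoch window")
    sl = slice(lo - lo_w, hi - lo_w)
    return {cls: float(wf[ch, sl].mean()) for cls, wf in erps.waveforms.items()}


def difference_wave(erps: ERPSet, minuend: str, subtrahend: str) -> np.ndarray:
    """Pointwise ``minuend - subtrahend`` waveform (channels x samples)."""
    for cls in (minuend, subtrahend):
        if cls not in erps.waveforms:
            raise ValueError(f"class {cls!r} not present in ERP set")
    return erps.waveforms[minuend] - erps.waveforms[subtrahend]


def _take(epochs: EpochedData, idx: np.ndarray) -> EpochedData:
    return EpochedData(
        data=epochs.data[idx],
        sampling_rate_hz=epochs.sampling_rate_hz,
        window_ms=epochs.window_ms,
        labels=epochs.labels[idx],
        channel_labels=list(epochs.channel_labels),
        onsets_s=epochs.onsets_s[idx],
    )


def confidence_split_erps(epochs: EpochedData, confidences: np.ndarray,
                          top_frac: float = 0.25, bottom_frac: float = 0.25,
                          per_class: bool = True) -> tuple:
    """(high-confidence ERPs, low-confidence ERPs).

    By default the top/bottom fractions are taken within each class, matching
    per-class high/low-confidence traces; ``per_class=False`` splits the pooled
    trial set instead.  Ties are broken by a stable sort on (confidence, trial
    index), so equal confidences split deterministically.
    """
    confidences = np.asarray(confidences, dtype=float)
    if confidences.shape[0] != epochs.n_trials:
        raise ValueError("need one confidence per trial")

    def split(idx: np.ndarray) -> tuple:
        order = idx[np.argsort(confidences[idx], kind="stable")]
        n_top = int(np.floor(top_frac * idx.size))
        if abs(top_frac + bottom_frac - 1.0) < 1e-12:
            n_bot = idx.size - n_top  # complementary fractions partition exactly
        else:
            n_bot = int(np.floor(bottom_frac * idx.size))
        return order[idx.size - n_top :], order[:n_bot]

    top_idx, bot_idx = [], []
    groups = (
        [np.flatnonzero(epochs.labels == c) for c in np.unique(epochs.labels)]
        if per_class else [np.arange(epochs.n_trials)]
    )
    for idx in groups:
        t, b = split(idx)
        if t.size == 0 or b.size == 0:
            logger.warning(
                "confidence split leaves an empty subset for a group of "
                "%d trial(s); group excluded", idx.size,
            )
            continue
        top_idx.append(t)
        bot_idx.append(b)
    if not top_idx:
        raise ValueError("confidence split produced no usable trials")
    top = grand_average(_take(epochs, np.sort(np.concatenate(top_idx))))
    bottom = grand_average(_take(epochs, np.sort(np.concatenate(bot_idx))))
    return top, bottom
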