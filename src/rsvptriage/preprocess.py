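"""Continuous EEG -> classifier-ready epochs.

Classification stream: order-4 Butterworth band-pass 1-10.66 Hz (zero-phase by
default), decimation to 32 Hz, epoching to [0, 1000) ms.  ERP stream: epoching
to [-500, 1000) ms with [-500, 0) ms baseline subtraction at the acquisition
rate.  Sample conventions are half-open, ``[ceil(start*fs/1000),
ceil(end*fs/1000))`` relative to the onset sample, so a [0, 1000) ms window at
32 Hz is exactly 32 samples; onset times map to samples by rounding down.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .simulate import ContinuousEEG, EventSequence

logger = logging.getLogger(__name__)


@dataclass
class EpochedData:
    """Stimulus-locked trials, time-ordered, sharing one window and rate."""

    data: np.ndarray  # trials x channels x samples, uV
    sampling_rate_hz: float
    window_ms: tuple  # (start, end), half-open in samples
    labels: np.ndarray  # class per trial
    channel_labels: list
    onsets_s: np.ndarray  # per-trial stimulus onset, seconds

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def window_to_samples(window_ms: tuple, rate_hz: float) -> tuple:
    """Half-open sample offsets relative to the onset sample."""
    lo = int(math.ceil(window_ms[0] * rate_hz / 1000.0))
    hi = int(math.ceil(window_ms[1] * rate_hz / 1000.0))
    return lo, hi


def bandpass(data: ContinuousEEG, low_hz: float = 1.0, high_hz: float = 10.66,
             order: int = 4, zero_phase: bool = True) -> ContinuousEEG:
    """Butterworth band-pass; DC gain is (numerically) zero.

    ``zero_phase`` applies the filter forward and backward, preserving ERP
    latencies at the cost of squaring the magnitude response; set it False for
    a causal single pass.
    """
    nyq = data.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low < high")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=data.sampling_rate_hz, output="sos")
    if zero_phase:
        out = signal.sosfiltfilt(sos, data.data, axis=1)
    else:
        out = signal.sosfilt(sos, data.data, axis=1)
    return ContinuousEEG(out, data.sampling_rate_hz, list(data.channel_labels))


def downsample(data: ContinuousEEG, target_rate_hz: float = 32.0) -> ContinuousEEG:
    """Reduce the sampling rate, assuming the band-pass already anti-aliased.

    Integer factors decimate by slicing (sample-exact for signals band-limited
    below the new Nyquist); non-integer rational factors use polyphase
    resampling.
    """
    rate = data.sampling_rate_hz
    if target_rate_hz > rate:
        raise ValueError("target rate exceeds current rate")
    if target_rate_hz == rate:
        return data
    ratio = Fraction(target_rate_hz / rate).limit_denominator(10_000)
    if ratio.numerator == 1:
        out = data.data[:, :: ratio.denominator]
    else:
        out = signal.resample_poly(data.data, ratio.numerator,
                                   ratio.denominator, axis=1)
    return ContinuousEEG(np.ascontiguousarray(out), target_rate_hz,
                         list(data.channel_labels))


def epoch(data: ContinuousEEG, seq: EventSequence,
          window_ms: tuple = (0.0, 1000.0),
          classes: tuple | None = None) -> EpochedData:
    """Cut one trial per selected onset; onset sample maps to time 0.

    Trials whose window extends past the recording are dropped and counted in
    the log, never padded.
    """
    if classes is None:
        keep = np.ones(seq.n_events, dtype=bool)
    else:
        keep = seq.mask(*classes)
    if not keep.any():
        raise ValueError("no events of the requested classes")
    rate = data.sampling_rate_hz
    lo, hi = window_to_samples(window_ms, rate)
    onset_idx = np.floor(seq.onsets_s[keep] * rate).astype(int)
    labels = seq.classes[keep]
    onsets = seq.onsets_s[keep]

    inside = (onset_idx + lo >= 0) & (onset_idx + hi <= data.n_samples)
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning("dropped %d trial(s) extending past the recording",
                       n_dropped)
    onset_idx, labels, onsets = onset_idx[inside], labels[inside], onsets[inside]
    trials = np.stack([data.data[:, i + lo : i + hi] for i in onset_idx])
    return EpochedData(
        data=trials,
        sampling_rate_hz=rate,
        window_ms=tuple(window_ms),
        labels=labels,
        channel_labels=list(data.channel_labels),
        onsets_s=onsets,
    )


def baseline_correct(epochs: EpochedData,
                     baseline_ms: tuple = (-500.0, 0.0)) -> EpochedData:
    """Subtract each channel's mean over the baseline window, per trial."""
    lo_w, hi_w = window_to_samples(epochs.window_ms, epochs.sampling_rate_hz)
    lo_b, hi_b = window_to_samples(baseline_ms, epochs.sampling_rate_hz)
    if lo_b < lo_w or hi_b > hi_w or hi_b <= lo_b:
        raise ValueError("baseline window outside the epoch window")
    sl = slice(lo_b - lo_w, hi_b - lo_w)
    mean = epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    return EpochedData(
        data=epochs.data - mean,
        sampling_rate_hz=epochs.sampling_rate_hz,
        window_ms=epochs.window_ms,
        labels=epochs.labels,
        channel_labels=list(epochs.channel_labels),
        onsets_s=epochs.onsets_s,
    )


def classification_epochs(eeg: ContinuousEEG, seq: EventSequence,
                          low_hz: float = 1.0, high_hz: float = 10.66,
                          order: int = 4, target_rate_hz: float = 32.0,
                          window_ms: tuple = (0.0, 1000.0)) -> EpochedData:
    """The full classification preprocessing chain: band-pass, decimate, epoch."""
    return epoch(downsample(bandpass(eeg, low_hz, high_hz, order),
                            target_rate_hz), seq, window_ms)
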