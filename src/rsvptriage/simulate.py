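"""Synthetic RSVP sessions: stimulus sequences, multichannel EEG, button presses.

The generator emulates a 2 Hz rapid serial visual presentation experiment in
which rare *target* images (and, in the TN condition, rare target-like
*non-target* images) are embedded in a stream of frequent *background*
distractors.  Each stimulus evokes a class-graded P3-like deflection that is
largest at a midline-parietal ("Pz"-role) channel, superimposed on ongoing
noise; targets additionally elicit button presses with a configurable hit rate
and a right-skewed reaction-time distribution.

Everything downstream of acquisition (band-pass, decimation, epoching, xDAWN,
BLDA, confidence triage) can therefore be exercised without any recorded data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

TARGET = "target"
NONTARGET = "nontarget"
BACKGROUND = "background"
CLASSES = (TARGET, NONTARGET, BACKGROUND)

#: Mean P3 amplitude (400-800 ms, Pz) evoked by target images, in microvolts.
DEFAULT_TARGET_AMPLITUDE_UV = 13.66
#: Mean amplitude evoked by background distractors, in microvolts.
DEFAULT_BACKGROUND_AMPLITUDE_UV = -0.44
#: Non-targets sit midway between targets and backgrounds.
DEFAULT_NONTARGET_AMPLITUDE_UV = 0.5 * (
    DEFAULT_TARGET_AMPLITUDE_UV + DEFAULT_BACKGROUND_AMPLITUDE_UV
)


@dataclass
class BehaviorParams:
    """Button-press model: per-class press probability and RT law.

    Reaction times are log-normal, parameterized by their median (ms) and the
    log-scale spread ``rt_sigma``; the distribution is positive and
    right-skewed, the canonical shape of simple-RT data.  Fields left None are
    filled with condition defaults (TO: hit rate 0.95, median RT 514.67 ms;
    TN: hit rate 0.85, median RT 602.82 ms — detection is slower and less
    accurate when target-like non-targets are present).
    """

    hit_probability: float | None = None
    nontarget_press_probability: float | None = None
    background_press_probability: float = 0.002
    rt_median_ms: float | None = None
    rt_sigma: float = 0.25

    def fill_condition_defaults(self, condition: str) -> None:
        to = condition == "TO"
        if self.hit_probability is None:
            self.hit_probability = 0.95 if to else 0.85
        if self.nontarget_press_probability is None:
            self.nontarget_press_probability = 0.0 if to else 0.08
        if self.rt_median_ms is None:
            self.rt_median_ms = 514.67 if to else 602.82


@dataclass
class SimulationConfig:
    """Full description of one synthetic RSVP session.

    ``condition`` is ``"TO"`` (targets only among backgrounds, 1:20) or
    ``"TN"`` (targets and visually similar non-targets, each 1:14 relative to
    backgrounds).  Rare stimuli are never adjacent and are followed by at
    least ``min_background_gap`` backgrounds.  ``seed`` fully determines all
    outputs.
    """

    condition: str = "TO"
    n_blocks: int = 6
    block_duration_s: float | None = None  # 120 s TO / 134 s TN when None
    presentation_rate_hz: float = 2.0
    target_ratio: float = None  # rare:frequent, 1/20 TO, 1/14 TN when None
    nontarget_ratio: float = 1.0 / 14.0  # TN only
    min_background_gap: int = 2
    n_channels: int = 16
    sampling_rate_hz: float = 256.0
    erp_amplitudes_uv: dict = field(default_factory=dict)
    erp_peak_ms: float = 550.0
    erp_halfwidth_ms: float = 250.0
    noise_model: str = "pink"  # or "white"
    noise_scale_uv: float = 30.0
    inter_block_gap_s: float = 2.0
    pad_s: float = 1.5
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ("TO", "TN"):
            raise ValueError(f"condition must be 'TO' or 'TN', got {self.condition!r}")
        if self.block_duration_s is None:
            self.block_duration_s = 120.0 if self.condition == "TO" else 134.0
        if self.target_ratio is None:
            self.target_ratio = 1.0 / 20.0 if self.condition == "TO" else 1.0 / 14.0
        amps = {
            TARGET: DEFAULT_TARGET_AMPLITUDE_UV,
            NONTARGET: DEFAULT_NONTARGET_AMPLITUDE_UV,
            BACKGROUND: DEFAULT_BACKGROUND_AMPLITUDE_UV,
        }
        amps.update(self.erp_amplitudes_uv)
        self.erp_amplitudes_uv = amps
        if isinstance(self.behavior, dict):
            self.behavior = BehaviorParams(**self.behavior)
        self.behavior.fill_condition_defaults(self.condition)
        if self.min_background_gap < 0:
            raise ValueError("min_background_gap must be non-negative")
        if self.presentation_rate_hz <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.noise_model not in ("white", "pink"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def stimuli_per_block(self) -> int:
        return int(math.floor(self.block_duration_s * self.presentation_rate_hz))

    def rare_counts_per_block(self) -> dict:
        """Realized integer class counts per block implied by the ratios.

        The ratio system (rare:background) has a fractional solution; rare
        counts are rounded down and backgrounds take up the remainder.
        """
        n = self.stimuli_per_block
        if self.condition == "TO":
            n_t = int(n * self.target_ratio / (1.0 + self.target_ratio))
            counts = {TARGET: n_t, NONTARGET: 0, BACKGROUND: n - n_t}
        else:
            denom = 1.0 + self.target_ratio + self.nontarget_ratio
            n_t = int(n * self.target_ratio / denom)
            n_nt = int(n * self.nontarget_ratio / denom)
            counts = {TARGET: n_t, NONTARGET: n_nt, BACKGROUND: n - n_t - n_nt}
        return counts

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a YAML (or JSON) structured-text file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class EventSequence:
    """Ordered stimulus onsets with class labels, blocks and button presses."""

    onsets_s: np.ndarray  # float, seconds from session start
    classes: np.ndarray  # str in CLASSES
    block_ids: np.ndarray  # int
    presses_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.classes = np.asarray(self.classes, dtype=object)
        self.block_ids = np.asarray(self.block_ids, dtype=int)
        self.presses_s = np.asarray(self.presses_s, dtype=float)

    @property
    def n_events(self) -> int:
        return self.onsets_s.size

    def mask(self, *classes: str) -> np.ndarray:
        return np.isin(self.classes, classes)


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording in microvolts."""

    data: np.ndarray  # channels x samples
    sampling_rate_hz: float
    channel_labels: list

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def pz_index(self) -> int:
        return self.channel_labels.index("Pz")


class InfeasibleSequenceError(ValueError):
    """Raised when the spacing constraint cannot host the requested rare count."""


# ---------------------------------------------------------------------------
# Stimulus sequences
# ---------------------------------------------------------------------------

def count_admissible_placements(n_slots: int, n_rare: int, gap: int) -> int:
    """Number of ways to place ``n_rare`` rare stimuli in ``n_slots`` positions
    such that each rare stimulus is followed by >= ``gap`` backgrounds (which
    also forbids adjacent rare stimuli for gap >= 1).

    Follows from the gap-removal bijection used by :func:`_sample_rare_slots`.
    """
    m = n_slots - gap * n_rare
    if m < n_rare:
        return 0
    return math.comb(m, n_rare)


def _sample_rare_slots(rng: np.random.Generator, n_slots: int, n_rare: int,
                       gap: int) -> np.ndarray:
    """Uniformly sample an admissible set of rare-stimulus positions.

    Admissible: positions p_1 < ... < p_k in [0, n_slots-1-gap] with
    p_{i+1} - p_i >= gap + 1.  The map q_i = p_i - (i-1)*gap is a bijection
    onto plain k-subsets of {0, ..., n_slots - k*gap - 1}, so sampling a
    uniform k-subset and mapping back is exactly uniform over admissible sets.
    """
    if n_rare == 0:
        return np.empty(0, dtype=int)
    m = n_slots - gap * n_rare
    if m < n_rare:
        raise InfeasibleSequenceError(
            f"cannot place {n_rare} rare stimuli with trailing gap {gap} "
            f"in {n_slots} slots"
        )
    q = np.sort(rng.choice(m, size=n_rare, replace=False))
    return q + gap * np.arange(n_rare)


def generate_sequence(config: SimulationConfig) -> EventSequence:
    """Generate the session's stimulus sequence.

    Onsets are spaced 1/presentation_rate within a block; blocks are separated
    by ``inter_block_gap_s`` and the session starts after ``pad_s`` of
    recording.  Realized per-block class counts are logged.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.rare_counts_per_block()
    n = config.stimuli_per_block
    soa = 1.0 / config.presentation_rate_hz
    gap = config.min_background_gap

    onsets, classes, blocks = [], [], []
    for b in range(config.n_blocks):
        n_rare = counts[TARGET] + counts[NONTARGET]
        slots = _sample_rare_slots(rng, n, n_rare, gap)
        labels = np.full(n, BACKGROUND, dtype=object)
        rare_labels = np.array(
            [TARGET] * counts[TARGET] + [NONTARGET] * counts[NONTARGET],
            dtype=object,
        )
        rng.shuffle(rare_labels)
        labels[slots] = rare_labels
        t0 = config.pad_s + b * (config.block_duration_s + config.inter_block_gap_s)
        onsets.append(t0 + np.arange(n) * soa)
        classes.append(labels)
        blocks.append(np.full(n, b, dtype=int))

    logger.info(
        "generated %d blocks of %d stimuli (per block: %d targets, "
        "%d non-targets, %d backgrounds)",
        config.n_blocks, n, counts[TARGET], counts[NONTARGET], counts[BACKGROUND],
    )
    return EventSequence(
        onsets_s=np.concatenate(onsets),
        classes=np.concatenate(classes),
        block_ids=np.concatenate(blocks),
    )


def check_sequence_constraints(seq: EventSequence, config: SimulationConfig) -> None:
    """Raise AssertionError if the spacing invariants are violated."""
    soa = 1.0 / config.presentation_rate_hz
    for b in np.unique(seq.block_ids):
        sel = seq.block_ids == b
        on = seq.onsets_s[sel]
        cl = seq.classes[sel]
        assert np.all(np.diff(on) > 0), "onsets not strictly increasing"
        assert np.allclose(np.diff(on), soa), "uneven spacing within block"
        rare = np.flatnonzero(np.isin(cl, (TARGET, NONTARGET)))
        for r in rare:
            trailing = cl[r + 1 : r + 1 + config.min_background_gap]
            assert len(trailing) == config.min_background_gap, (
                "rare stimulus too close to block end"
            )
            assert np.all(trailing == BACKGROUND), (
                "rare stimulus not followed by enough backgrounds"
            )


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def erp_template(config: SimulationConfig) -> np.ndarray:
    """Discrete single-stimulus ERP kernel at the session sampling rate.

    A raised-cosine bump supported on ``peak +/- halfwidth`` ms, normalized so
    that its mean over the 400-800 ms P3 window equals 1; scaling by a class
    amplitude then makes the noise-free 400-800 ms epoch mean at the Pz-role
    channel equal that amplitude exactly.
    """
    rate = config.sampling_rate_hz
    start_ms = config.erp_peak_ms - config.erp_halfwidth_ms
    end_ms = config.erp_peak_ms + config.erp_halfwidth_ms
    if start_ms < 0:
        raise ValueError("ERP template extends before stimulus onset")
    n = int(math.ceil(end_ms / 1000.0 * rate)) + 1
    t_ms = np.arange(n) / rate * 1000.0
    tmpl = np.zeros(n)
    inside = (t_ms >= start_ms) & (t_ms <= end_ms)
    phase = (t_ms[inside] - config.erp_peak_ms) / config.erp_halfwidth_ms
    tmpl[inside] = 0.5 * (1.0 + np.cos(np.pi * phase))
    lo = int(math.ceil(0.400 * rate))
    hi = int(math.ceil(0.800 * rate))
    w = tmpl[lo:hi].mean()
    if w <= 0:
        raise ValueError("ERP template has no mass in the 400-800 ms window")
    return tmpl / w


def spatial_pattern(config: SimulationConfig) -> tuple[np.ndarray, list]:
    """Fixed smooth topography, maximal (weight 1) at the Pz-role channel.

    Channels are laid out on a 1-D axis; the pattern is a Gaussian in channel
    index centred on "Pz".  Real scalp topographies are 2-D, but a smooth
    rank-1 pattern is all the downstream spatial filtering assumes.
    """
    n = config.n_channels
    labels = [f"Ch{i:02d}" for i in range(n)]
    pz = n // 2
    labels[pz] = "Pz"
    sigma = max(n / 4.0, 1.0)
    pattern = np.exp(-0.5 * ((np.arange(n) - pz) / sigma) ** 2)
    pattern /= pattern[pz]  # exact 1 at Pz
    return pattern, labels


def _noise(rng: np.random.Generator, config: SimulationConfig,
           n_samples: int) -> np.ndarray:
    """Channels x samples noise with unit std per channel, times the scale."""
    scale = config.noise_scale_uv
    shape = (config.n_channels, n_samples)
    if scale == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if config.noise_model == "white":
        return scale * white
    # pink: shape the spectrum as 1/f in power
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / config.sampling_rate_hz)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** -0.5
    pink = np.fft.irfft(spec * gain, n=n_samples, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return scale * pink


def generate_eeg(seq: EventSequence, config: SimulationConfig) -> ContinuousEEG:
    """Superimpose class-scaled ERP kernels on ongoing noise.

    Each stimulus adds ``amplitude[class] * kernel`` through the fixed spatial
    pattern at its onset sample (onset time rounded down to the sample grid).
    """
    rate = config.sampling_rate_hz
    n_samples = int(math.ceil((seq.onsets_s[-1] + config.pad_s) * rate)) + 1
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    data = _noise(rng, config, n_samples)

    kernel = erp_template(config)
    pattern, labels = spatial_pattern(config)
    evoked = np.zeros(n_samples)
    for cls in CLASSES:
        amp = config.erp_amplitudes_uv[cls]
        if amp == 0:
            continue
        onset_idx = np.floor(seq.onsets_s[seq.classes == cls] * rate).astype(int)
        for i0 in onset_idx:
            hi = min(i0 + kernel.size, n_samples)
            evoked[i0:hi] += amp * kernel[: hi - i0]
    data += pattern[:, None] * evoked[None, :]
    if not np.all(np.isfinite(data)):  # pragma: no cover - defensive
        raise FloatingPointError("non-finite samples in synthesized EEG")
    return ContinuousEEG(data=data, sampling_rate_hz=rate, channel_labels=labels)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def sample_reaction_times(rng: np.random.Generator, median_ms: float,
                          sigma: float, n: int) -> np.ndarray:
    """Log-normal reaction times (ms) with the given median."""
    if median_ms <= 0 or sigma <= 0:
        raise ValueError("RT distribution parameters must be positive")
    return np.exp(np.log(median_ms) + sigma * rng.standard_normal(n))


def simulate_behavior(seq: EventSequence, config: SimulationConfig) -> EventSequence:
    """Fill in button presses: hits on targets, sparse false presses elsewhere."""
    if seq.presses_s.size:
        raise ValueError("sequence already contains button presses")
    p = config.behavior
    if p.rt_median_ms <= 0 or p.rt_sigma <= 0:
        raise ValueError("RT distribution parameters must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    press_prob = {
        TARGET: p.hit_probability,
        NONTARGET: p.nontarget_press_probability,
        BACKGROUND: p.background_press_probability,
    }
    probs = np.array([press_prob[c] for c in seq.classes])
    pressed = rng.random(seq.n_events) < probs
    rts_ms = sample_reaction_times(rng, p.rt_median_ms, p.rt_sigma,
                                   int(pressed.sum()))
    presses = np.sort(seq.onsets_s[pressed] + rts_ms / 1000.0)
    return EventSequence(
        onsets_s=seq.onsets_s,
        classes=seq.classes,
        block_ids=seq.block_ids,
        presses_s=presses,
    )


def simulate_session(config: SimulationConfig) -> tuple[EventSequence, ContinuousEEG]:
    """Sequence + behavior + EEG for one session, fully seed-determined."""
    seq = simulate_behavior(generate_sequence(config), config)
    eeg = generate_eeg(seq, config)
    return seq, eeg


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

def save_session(out_dir: str | Path, seq: EventSequence, eeg: ContinuousEEG,
                 config: SimulationConfig | None = None) -> None:
    """Write a session as npz arrays + JSON sidecar + tab-delimited events."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "eeg.npz", data=eeg.data, presses_s=seq.presses_s)
    meta = {
        "sampling_rate_hz": eeg.sampling_rate_hz,
        "channel_labels": eeg.channel_labels,
        "units": "uV",
    }
    if config is not None:
        meta["config"] = json.loads(json.dumps(config.to_dict(), default=float))
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    with open(out / "events.tsv", "w") as fh:
        fh.write("onset_s\tclass\tblock\n")
        for t, c, b in zip(seq.onsets_s, seq.classes, seq.block_ids):
            fh.write(f"{t:.6f}\t{c}\t{b}\n")


def load_session(in_dir: str | Path) -> tuple[EventSequence, ContinuousEEG]:
    """Read back a session written by :func:`save_session`."""
    src = Path(in_dir)
    arrays = np.load(src / "eeg.npz")
    meta = json.loads((src / "meta.json").read_text())
    import pandas as pd

    ev = pd.read_csv(src / "events.tsv", sep="\t")
    seq = EventSequence(
        onsets_s=ev["onset_s"].to_numpy(),
        classes=ev["class"].to_numpy(dtype=object),
        block_ids=ev["block"].to_numpy(),
        presses_s=arrays["presses_s"],
    )
    eeg = ContinuousEEG(
        data=arrays["data"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        channel_labels=list(meta["channel_labels"]),
    )
    return seq, eeg
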