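"""Containers for epoched data, spatial filters and classifier models.

Arrays go into npz files with a JSON sidecar carrying the metadata; the
session-level container (continuous EEG + TSV events) lives in
:mod:`rsvptriage.simulate`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .blda import BLDAModel
from .preprocess import EpochedData
from .xdawn import SpatialFilterSet


def save_epochs(path: str | Path, epochs: EpochedData) -> None:
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        data=epochs.data,
        labels=epochs.labels.astype(str),
        onsets_s=epochs.onsets_s,
    )
    meta = {
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "window_ms": list(epochs.window_ms),
        "channel_labels": epochs.channel_labels,
        "units": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_epochs(path: str | Path) -> EpochedData:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochedData(
        data=arrays["data"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        window_ms=tuple(meta["window_ms"]),
        labels=arrays["labels"].astype(object),
        channel_labels=list(meta["channel_labels"]),
        onsets_s=arrays["onsets_s"],
    )


def save_filters(path: str | Path, filters: SpatialFilterSet) -> None:
    np.savez(
        Path(path).with_suffix(".npz"),
        U=filters.U,
        ssnr_values=filters.ssnr_values,
        A1_hat=filters.A1_hat,
        A2_hat=filters.A2_hat,
    )


def load_filters(path: str | Path) -> SpatialFilterSet:
    a = np.load(Path(path).with_suffix(".npz"))
    return SpatialFilterSet(U=a["U"], ssnr_values=a["ssnr_values"],
                            A1_hat=a["A1_hat"], A2_hat=a["A2_hat"])


def save_model(path: str | Path, model: BLDAModel) -> None:
    np.savez(
        Path(path).with_suffix(".npz"),
        weights=model.weights,
        bias=model.bias,
        alpha=model.alpha,
        beta=model.beta,
        n_iterations_run=model.n_iterations_run,
        converged=model.converged,
        evidence_path=model.evidence_path,
    )


def load_model(path: str | Path) -> BLDAModel:
    a = np.load(Path(path).with_suffix(".npz"))
    return BLDAModel(
        weights=a["weights"],
        bias=float(a["bias"]),
        alpha=float(a["alpha"]),
        beta=float(a["beta"]),
        n_iterations_run=int(a["n_iterations_run"]),
        converged=bool(a["converged"]),
        evidence_path=a["evidence_path"],
    )
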