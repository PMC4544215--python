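"""xDAWN spatial filtering.

The recorded signal X (N_t samples x N_s sensors) is modeled algebraically as

    X = D1 A1 + D2 A2 + H,

where D1 and D2 are 0/1 Toeplitz design matrices whose first columns mark
target onsets and all stimulus onsets respectively, A1 is the prototypical
target-evoked response (N_1 samples x N_s), A2 the response common to every
stimulus, and H residual noise.  A1 is estimated jointly by least squares,

    [A1_hat; A2_hat] = ([D1 D2]^T [D1 D2])^-1 [D1 D2]^T X,

and spatial filters U maximize the signal to signal-plus-noise ratio

    SSNR(U) = Tr(U^T A1_hat^T D1^T D1 A1_hat U) / Tr(U^T X^T X U),

a Rayleigh quotient whose maximizers are the top generalized eigenvectors of
(A1_hat^T D1^T D1 A1_hat, X^T X).  Filters are ranked by SSNR and normalized
to unit norm in the X^T X metric so their time courses share a common scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .preprocess import EpochedData

logger = logging.getLogger(__name__)

#: Default ridge added to X^T X, scaled by trace/N_s, for numerical stability.
DEFAULT_COND_LAMBDA = 1e-9


@dataclass
class DesignMatrices:
    """Toeplitz designs: D1 marks target onsets, D2 all stimulus onsets."""

    D1: np.ndarray  # N_t x N_1, 0/1
    D2: np.ndarray  # N_t x N_2, 0/1


@dataclass
class SpatialFilterSet:
    U: np.ndarray  # N_s x N_f
    ssnr_values: np.ndarray  # per filter, descending
    A1_hat: np.ndarray  # N_1 x N_s
    A2_hat: np.ndarray  # N_2 x N_s


def _toeplitz_design(onsets: np.ndarray, n_samples: int, width: int) -> np.ndarray:
    """0/1 Toeplitz matrix: column k is the onset indicator shifted down k."""
    D = np.zeros((n_samples, width))
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size and (onsets.min() < 0 or onsets.max() >= n_samples):
        raise ValueError("onset sample indices must lie within [0, n_samples)")
    for k in range(width):
        idx = onsets + k
        idx = idx[idx < n_samples]  # truncate responses past the recording end
        D[idx, k] = 1.0
    return D


def build_design(target_onsets: np.ndarray, all_onsets: np.ndarray,
                 n_samples: int, n1: int, n2: int) -> DesignMatrices:
    """Design matrices from onset sample indices on the analysis timeline."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("response lengths N1 and N2 must be positive")
    return DesignMatrices(
        D1=_toeplitz_design(target_onsets, n_samples, n1),
        D2=_toeplitz_design(all_onsets, n_samples, n2),
    )


def estimate_responses(X: np.ndarray, design: DesignMatrices) -> tuple:
    """Joint least-squares estimate (A1_hat, A2_hat) of the evoked responses."""
    D = np.hstack([design.D1, design.D2])
    G = D.T @ D
    rhs = D.T @ X
    n1 = design.D1.shape[1]
    if np.linalg.matrix_rank(G) < G.shape[0]:
        warnings.warn(
            "[D1;D2] is rank deficient; falling back to the Moore-Penrose "
            "pseudoinverse", RuntimeWarning, stacklevel=2,
        )
        A = np.linalg.pinv(G) @ rhs
    else:
        A = linalg.solve(G, rhs, assume_a="sym")
    return A[:n1], A[n1:]


def ssnr(U: np.ndarray, X: np.ndarray, design: DesignMatrices,
         A1_hat: np.ndarray) -> float:
    """Signal to signal-plus-noise ratio of the filter set U (Rayleigh quotient)."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.shape[0] != X.shape[1]:
        U = U.T
    S = design.D1 @ A1_hat
    num = np.trace(U.T @ S.T @ S @ U)
    den = np.trace(U.T @ X.T @ X @ U)
    return float(num / den)


def fit_filters(X: np.ndarray, design: DesignMatrices, A1_hat: np.ndarray,
                n_filters: int = 8,
                cond_lambda: float = DEFAULT_COND_LAMBDA) -> SpatialFilterSet:
    """SSNR-maximizing spatial filters via the generalized eigenproblem.

    Columns of U are the top ``n_filters`` generalized eigenvectors of
    (A1_hat^T D1^T D1 A1_hat, X^T X); the reported SSNR values are the exact
    Rayleigh quotients of the returned filters, in descending order.
    """
    n_s = X.shape[1]
    if n_filters > n_s:
        raise ValueError(f"n_filters={n_filters} exceeds {n_s} channels")
    S = design.D1 @ A1_hat
    B = S.T @ S
    C = X.T @ X
    C = C + cond_lambda * (np.trace(C) / n_s) * np.eye(n_s)
    eigvals, eigvecs = linalg.eigh(B, C)
    order = np.argsort(eigvals)[::-1][:n_filters]
    U = eigvecs[:, order]
    # eigh already normalizes u^T C u = 1; re-normalize against the exact
    # metric in case cond_lambda perturbed it.
    scale = np.sqrt(np.einsum("ij,jk,ki->i", U.T, X.T @ X, U))
    U = U / scale
    values = np.array([ssnr(U[:, [k]], X, design, A1_hat)
                       for k in range(U.shape[1])])
    _, A2_hat = estimate_responses(X, design)
    return SpatialFilterSet(U=U, ssnr_values=values, A1_hat=A1_hat,
                            A2_hat=A2_hat)


def fit_xdawn(X: np.ndarray, target_onsets: np.ndarray, all_onsets: np.ndarray,
              n1: int, n2: int, n_filters: int = 8) -> SpatialFilterSet:
    """Convenience wrapper: design -> response estimate -> filters."""
    design = build_design(target_onsets, all_onsets, X.shape[0], n1, n2)
    A1_hat, _ = estimate_responses(X, design)
    return fit_filters(X, design, A1_hat, n_filters=n_filters)


def apply_filters(epochs: EpochedData, filters: SpatialFilterSet) -> np.ndarray:
    """Per-trial feature vectors: the N_f filtered time courses concatenated.

    Ordering is filter-major (all samples of filter 1, then filter 2, ...);
    the result has shape (n_trials, N_f * samples_per_epoch).
    """
    if epochs.n_channels != filters.U.shape[0]:
        raise ValueError(
            f"epochs have {epochs.n_channels} channels but filters expect "
            f"{filters.U.shape[0]}"
        )
    # trials x channels x samples -> trials x filters x samples
    filtered = np.einsum("cf,tcs->tfs", filters.U, epochs.data)
    return filtered.reshape(epochs.n_trials, -1)


def stack_epochs(epochs: EpochedData, positive_class: str = "target") -> tuple:
    """Assemble (X, target_onsets, all_onsets) by stacking epochs in time order.

    Each trial contributes one block of samples to the analysis timeline, with
    a stimulus onset at the block start; D1 marks the blocks whose trial label
    equals ``positive_class``.
    """
    T = epochs.n_samples
    X = epochs.data.transpose(0, 2, 1).reshape(-1, epochs.n_channels)
    all_onsets = np.arange(epochs.n_trials) * T
    target_onsets = all_onsets[epochs.labels == positive_class]
    return X, target_onsets, all_onsets
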