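"""Bayesian linear discriminant analysis.

Binary classification posed as Bayesian linear regression onto class-size-
balanced targets (+N/N+ for positives, -N/N- for negatives), with an isotropic
Gaussian prior of precision alpha on the augmented weight vector (bias
included) and Gaussian observation noise of precision beta.  Both
hyperparameters are set by evidence maximization with the classic fixed-point
updates

    gamma = sum_i  beta s_i / (alpha + beta s_i)     (effective dof)
    alpha = gamma / ||m||^2
    beta  = (n - gamma) / ||y - X m||^2

where s_i are the eigenvalues of X^T X and m the posterior mean.  The ridge
regularization this induces is what makes the classifier robust to noisy,
heavily imbalanced training data.  The trial score is the affine projection
w^T x + b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass
class BLDAModel:
    weights: np.ndarray  # per feature
    bias: float
    alpha: float
    beta: float
    n_iterations_run: int
    converged: bool
    evidence_path: np.ndarray  # log evidence per iteration

    @property
    def augmented(self) -> np.ndarray:
        return np.append(self.weights, self.bias)


def regression_targets(labels: np.ndarray) -> np.ndarray:
    """Class-size-balanced coding: +N/N+ for class 1, -N/N- for class 0."""
    labels = np.asarray(labels).astype(bool)
    n = labels.size
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least two trials in each class")
    y = np.where(labels, n / n_pos, -n / n_neg)
    return y.astype(float)


def _log_evidence(alpha: float, beta: float, s: np.ndarray, n: int,
                  m_sq: float, rss: float) -> float:
    d = s.size
    return float(
        0.5 * d * np.log(alpha)
        + 0.5 * n * np.log(beta)
        - 0.5 * beta * rss
        - 0.5 * alpha * m_sq
        - 0.5 * np.sum(np.log(alpha + beta * s))
        - 0.5 * n * np.log(2 * np.pi)
    )


def fit(features: np.ndarray, labels: np.ndarray, max_iter: int = 100,
        tol: float = 1e-6, alpha: float = 1.0, beta: float = 1.0,
        update_hyperparameters: bool = True,
        standardize: bool = False) -> BLDAModel:
    """Fit the BLDA model by evidence maximization.

    With ``update_hyperparameters=False`` the posterior mean at the given
    (alpha, beta) is returned, i.e. ridge regression with penalty alpha/beta.
    ``standardize`` optionally z-scores the features first (off by default:
    xDAWN's metric normalization already fixes the feature scale).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be trials x dims")
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate features: zero variance in every dimension")
    y = regression_targets(labels)
    n = X.shape[0]
    Xa = np.hstack([X, np.ones((n, 1))])  # augment with bias column
    d = Xa.shape[1]

    # one-time eigendecomposition makes every fixed-point iteration O(d^2)
    s, V = linalg.eigh(Xa.T @ Xa)
    s = np.clip(s, 0.0, None)
    Vt_Xty = V.T @ (Xa.T @ y)
    yy = float(y @ y)

    evidence = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m_rot = (beta * Vt_Xty) / (alpha + beta * s)
        m_sq = float(m_rot @ m_rot)
        # rss = ||y||^2 - 2 m^T X^T y + m^T X^T X m in the eigenbasis
        rss = yy - 2.0 * float(m_rot @ Vt_Xty) + float((m_rot**2) @ s)
        rss = max(rss, np.finfo(float).tiny)
        evidence.append(_log_evidence(alpha, beta, s, n, m_sq, rss))
        if not update_hyperparameters:
            converged = True
            break
        gamma = float(np.sum(beta * s / (alpha + beta * s)))
        alpha_new = gamma / max(m_sq, np.finfo(float).tiny)
        beta_new = max(n - gamma, np.finfo(float).tiny) / rss
        delta = abs(np.log(alpha_new) - np.log(alpha)) + abs(
            np.log(beta_new) - np.log(beta)
        )
        alpha, beta = float(alpha_new), float(beta_new)
        if delta < tol:
            converged = True
            break

    m_rot = (beta * Vt_Xty) / (alpha + beta * s)
    m = V @ m_rot
    if standardize:
        # undo the z-scoring so score() applies to raw features
        w = m[:-1] / sd
        b = m[-1] - float(w @ mu)
    else:
        w, b = m[:-1], m[-1]
    return BLDAModel(
        weights=w, bias=float(b), alpha=alpha, beta=beta,
        n_iterations_run=it, converged=converged,
        evidence_path=np.asarray(evidence),
    )


def score(model: BLDAModel, features: np.ndarray) -> np.ndarray:
    """Per-trial classifier score w^T x + b."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.weights.size})"
        )
    return X @ model.weights + model.bias
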