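"""Common spatial patterns: covariance estimation, the generalized
eigenproblem, and log band-power features.

For a trial X in R^{CxT} the normalized spatial covariance is
Sigma = X X^T / trace(X X^T) (trace exactly 1), class covariances are
arithmetic means over trials, and the spatial filters w solve

    Sigma_r w = lambda Sigma_l w

with Sigma_l / Sigma_r the left/right class means. Filters with the
largest lambda maximize right-class variance relative to left, the
smallest do the opposite; the model keeps ``n_pairs`` of each, ordered
[top_1..top_np, bottom_1..bottom_np], each scaled to unit Euclidean
norm. Features are the log of the projected variance per filter
(2*n_pairs dimensions; a variance-normalized variant is available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .preprocess import EpochSet

__all__ = ["CovarianceSet", "CSPModel", "FeatureSet", "trial_covariance",
           "class_mean_covariances", "fit_csp", "fit_csp_from_epochs",
           "extract_features"]

#: condition-number threshold beyond which Sigma_l is ridge-regularized
COND_LIMIT = 1e12
RIDGE_FACTOR = 1e-10


@dataclass
class CovarianceSet:
    """Per-trial normalized spatial covariances and their class means."""

    covs: np.ndarray          # n_trials x C x C, trace 1 each
    labels: np.ndarray        # 1 = left, 2 = right
    cov_left: np.ndarray
    cov_right: np.ndarray


@dataclass
class CSPModel:
    """Spatial filters (rows of ``filters``) and their eigenvalues."""

    filters: np.ndarray       # 2*n_pairs x C, unit-norm rows
    eigenvalues: np.ndarray   # lambda per filter
    n_pairs: int
    channel_labels: tuple[str, ...] = ()
    session_id: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_pairs": self.n_pairs,
            "channel_labels": list(self.channel_labels),
            "session_id": self.session_id,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CSPModel":
        d = json.loads(Path(path).read_text())
        return cls(filters=np.array(d["filters"]),
                   eigenvalues=np.array(d["eigenvalues"]),
                   n_pairs=d["n_pairs"],
                   channel_labels=tuple(d["channel_labels"]),
                   session_id=d["session_id"])


@dataclass
class FeatureSet:
    """Per-trial log band-power features in the space of one CSP model."""

    x: np.ndarray             # n_trials x 2*n_pairs
    labels: np.ndarray
    source_session: str = ""
    csp_session: str = ""

    def __len__(self) -> int:
        return len(self.x)

    @property
    def dim(self) -> int:
        return self.x.shape[1]


def trial_covariance(trial: np.ndarray) -> np.ndarray:
    """Normalized CxC spatial covariance of one trial, trace exactly 1."""
    X = np.asarray(trial, dtype=float)
    if X.ndim != 2 or X.shape[1] <= X.shape[0]:
        raise ValueError("trial must be C x T with T > C")
    S = X @ X.T
    tr = np.trace(S)
    if tr <= 0:
        raise ValueError("all-zero trial (zero trace)")
    return S / tr


def class_mean_covariances(covs: np.ndarray,
                           labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean covariance per class -> (Sigma_left, Sigma_right)."""
    labels = np.asarray(labels)
    left = covs[labels == 1]
    right = covs[labels == 2]
    if not len(left) or not len(right):
        raise ValueError("both classes must be non-empty")
    return left.mean(axis=0), right.mean(axis=0)


def covariance_set(epochs: EpochSet) -> CovarianceSet:
    covs = np.array([trial_covariance(t) for t in epochs.trials])
    cl, cr = class_mean_covariances(covs, epochs.labels)
    return CovarianceSet(covs=covs, labels=epochs.labels.copy(),
                         cov_left=cl, cov_right=cr)


def fit_csp(cov_left: np.ndarray, cov_right: np.ndarray,
            n_pairs: int = 3, channel_labels: tuple[str, ...] = (),
            session_id: str = "") -> CSPModel:
    """Solve Sigma_r w = lambda Sigma_l w and keep the extreme pairs.

    Eigenvalues are sorted descending; the model keeps the ``n_pairs``
    largest followed by the ``n_pairs`` smallest (ties broken by first
    occurrence), each filter normalized to unit Euclidean norm.
    """
    C = cov_left.shape[0]
    if n_pairs > C // 2:
        raise ValueError("n_pairs too large for the channel count")
    cl = cov_left.copy()
    if np.linalg.cond(cl) > COND_LIMIT:
        cl = cl + RIDGE_FACTOR * np.trace(cl) * np.eye(C)
    w, v = linalg.eigh(cov_right, cl)      # ascending eigenvalues
    order = np.argsort(w, kind="stable")[::-1]
    w, v = w[order], v[:, order]
    keep = list(range(n_pairs)) + list(range(C - n_pairs, C))
    filters = v[:, keep].T
    filters = filters / np.linalg.norm(filters, axis=1, keepdims=True)
    return CSPModel(filters=filters, eigenvalues=w[keep], n_pairs=n_pairs,
                    channel_labels=channel_labels, session_id=session_id)


def fit_csp_from_epochs(epochs: EpochSet, n_pairs: int = 3) -> CSPModel:
    """Convenience: covariances, class means and eigenproblem in one call."""
    cs = covariance_set(epochs)
    return fit_csp(cs.cov_left, cs.cov_right, n_pairs=n_pairs,
                   channel_labels=epochs.channel_labels,
                   session_id=epochs.session_id)


def extract_features(model: CSPModel, epochs: EpochSet,
                     normalize_variance: bool = False) -> FeatureSet:
    """Log band power of the spatially filtered trials.

    feature_j = log var(w_j^T X). With ``normalize_variance`` the
    variance is divided by the sum over all filters first (the normalized
    variant common in the CSP literature; off by default).
    """
    if epochs.trials.shape[1] != model.filters.shape[1]:
        raise ValueError("channel count does not match the CSP model")
    proj = np.einsum("fc,nct->nft", model.filters, epochs.trials)
    var = proj.var(axis=2)
    if normalize_variance:
        var = var / var.sum(axis=1, keepdims=True)
    if np.any(var <= 0):
        raise ValueError("zero-variance projection (log undefined)")
    return FeatureSet(x=np.log(var), labels=epochs.labels.copy(),
                      source_session=epochs.session_id,
                      csp_session=model.session_id)
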