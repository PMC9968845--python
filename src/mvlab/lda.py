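"""Closed-form two-class linear discriminant analysis.

With class means mu_1, mu_2 and the (unscaled) within-class scatter
S = sum_k sum_{x in D_k} (x - mu_k)(x - mu_k)^T, the discriminant is

    g(x) = w^T x + b,   w = S^{-1} (mu_1 - mu_2),
    b = -1/2 (mu_1 + mu_2)^T S^{-1} (mu_1 - mu_2),

so g vanishes exactly at the midpoint of the class means. g(x) > 0
predicts class 1 (left), g(x) < 0 class 2 (right); the g = 0 tie goes to
class 1 deterministically. No iteration, no scaling of S (any positive
rescaling cancels between w and b).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .csp import FeatureSet

__all__ = ["LDAModel", "DegenerateSeparationWarning", "fit_lda", "predict",
           "decision_values", "accuracy"]

RIDGE = 1e-8


class DegenerateSeparationWarning(UserWarning):
    """Raised when the class means coincide and w collapses to zero."""


@dataclass
class LDAModel:
    w: np.ndarray
    b: float
    scatter: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    n1: int
    n2: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "w": self.w.tolist(), "b": self.b,
            "scatter": self.scatter.tolist(),
            "mu1": self.mu1.tolist(), "mu2": self.mu2.tolist(),
            "n1": self.n1, "n2": self.n2}, indent=1))


def fit_lda(features: FeatureSet | None = None, x: np.ndarray | None = None,
            labels: np.ndarray | None = None) -> LDAModel:
    """Fit the closed-form discriminant from a FeatureSet (or raw arrays)."""
    if features is not None:
        x, labels = features.x, features.labels
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    x1, x2 = x[labels == 1], x[labels == 2]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each class needs at least 2 trials")
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    d1, d2 = x1 - mu1, x2 - mu2
    S = d1.T @ d1 + d2.T @ d2
    dim = S.shape[0]
    if np.linalg.cond(S) > 1e12:
        S = S + RIDGE * np.trace(S) / dim * np.eye(dim)
    diff = mu1 - mu2
    if np.allclose(diff, 0):
        warnings.warn("identical class means: zero weight vector, "
                      "predictions fall back to the tie-break",
                      DegenerateSeparationWarning)
        w = np.zeros(dim)
        b = 0.0
    else:
        w = np.linalg.solve(S, diff)
        b = -0.5 * float((mu1 + mu2) @ w)
    return LDAModel(w=w, b=b, scatter=S, mu1=mu1, mu2=mu2,
                    n1=len(x1), n2=len(x2))


def decision_values(model: LDAModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(model.w):
        raise ValueError("feature dimension mismatch")
    return x @ model.w + model.b


def predict(model: LDAModel, features: FeatureSet | np.ndarray) -> np.ndarray:
    """Class labels (1/2) from the sign of g(x); g = 0 goes to class 1."""
    x = features.x if isinstance(features, FeatureSet) else features
    g = decision_values(model, x)
    return np.where(g >= 0, 1, 2)


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percent correct."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("length mismatch")
    if len(pred) == 0:
        raise ValueError("empty input")
    return float((pred == truth).mean() * 100.0)
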