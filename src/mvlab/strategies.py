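"""Training-set selection strategies for cross-session / cross-subject
decoding.

Six strategies pick which session(s) train the CSP+LDA model applied to
a target session:

* ``Prev`` / ``Next`` — the adjacent session in acquisition order
  (cross-session tasks only; unavailable at the first/last session);
* ``Best`` / ``Worst`` — the candidate with the highest / lowest
  self-test accuracy;
* ``Closest`` — the candidate whose 2-D feature distribution has the
  smallest symmetrized Gaussian KL divergence to the target's, with both
  clouds expressed in the *candidate's* CSP space (the space its
  classifier will operate in);
* ``All`` — every candidate concatenated.

Ties are broken by the lowest session index; selections are fully
deterministic given the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csp import FeatureSet, fit_csp_from_epochs, extract_features
from .lda import fit_lda, predict, accuracy
from .preprocess import EpochSet, concatenate_epochs

__all__ = ["STRATEGY_NAMES", "CROSS_SESSION_ONLY", "StrategyReport",
           "ApplicabilityError", "select_training", "kl_divergence",
           "gaussian_kl", "evaluate_strategies", "self_test_accuracies"]

STRATEGY_NAMES = ("Prev", "Next", "Best", "Worst", "Closest", "All")
CROSS_SESSION_ONLY = frozenset({"Prev", "Next"})

#: covariance ridge for the Gaussian KL fit
_KL_RIDGE = 1e-9


class ApplicabilityError(ValueError):
    """Strategy not defined for this task (Prev/Next on cross-subject)."""


@dataclass
class StrategyReport:
    """Accuracy table: rows = target sessions, columns = strategies.

    Unavailable cells (Prev at the first session, Next at the last) are
    NaN in ``table`` and rendered as "None" by :meth:`to_frame`; per-
    strategy means are taken over available cells only.
    """

    task: str
    table: pd.DataFrame            # float accuracies, NaN = unavailable
    selections: pd.DataFrame       # chosen training session(s) per cell

    def means(self) -> pd.Series:
        return self.table.mean(axis=0, skipna=True)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.round(2).astype(object)
        return out.where(self.table.notna(), "None")


def gaussian_kl(mu0: np.ndarray, cov0: np.ndarray,
                mu1: np.ndarray, cov1: np.ndarray) -> float:
    """KL(N0 || N1) for multivariate normals, closed form."""
    mu0, mu1 = np.atleast_1d(mu0), np.atleast_1d(mu1)
    cov0, cov1 = np.atleast_2d(cov0), np.atleast_2d(cov1)
    d = len(mu0)
    c1_inv = np.linalg.inv(cov1)
    diff = mu1 - mu0
    _, ld0 = np.linalg.slogdet(cov0)
    _, ld1 = np.linalg.slogdet(cov1)
    return float(0.5 * (np.trace(c1_inv @ cov0) + diff @ c1_inv @ diff
                        - d + ld1 - ld0))


def gaussian_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    cov = np.cov(x.T)
    cov = np.atleast_2d(cov)
    cov = cov + _KL_RIDGE * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    return mu, cov


def kl_divergence(feats_train: FeatureSet, feats_test: FeatureSet) -> float:
    """Symmetrized Gaussian KL between two pooled feature clouds.

    Each cloud (classes pooled) is summarized by its mean and covariance;
    the closed multivariate-normal form gives KL(P||Q) + KL(Q||P).
    """
    xa, xb = feats_train.x, feats_test.x
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("feature dimensions differ")
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 trials per cloud")
    mu_a, cov_a = gaussian_fit(xa)
    mu_b, cov_b = gaussian_fit(xb)
    return (gaussian_kl(mu_a, cov_a, mu_b, cov_b)
            + gaussian_kl(mu_b, cov_b, mu_a, cov_a))


def self_test_accuracies(sessions: list[EpochSet],
                         n_pairs: int = 1) -> dict[str, float]:
    """Within-session (train = test) accuracy per session."""
    out = {}
    for s in sessions:
        model = fit_csp_from_epochs(s, n_pairs=n_pairs)
        f = extract_features(model, s)
        lda = fit_lda(f)
        out[s.session_id] = accuracy(predict(lda, f), f.labels)
    return out


def select_training(strategy: str, target_id: str, sessions: list[EpochSet],
                    self_test_acc: dict[str, float] | None = None,
                    task: str = "cross-session",
                    n_pairs: int = 1) -> list[str] | None:
    """Session ids to train on, or None when the strategy is unavailable.

    ``sessions`` must be in acquisition order for Prev/Next. Best/Worst
    need the self-test diagonal; Closest fits each candidate's CSP and
    compares feature clouds by symmetrized Gaussian KL.
    """
    if strategy not in STRATEGY_NAMES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy in CROSS_SESSION_ONLY and task != "cross-session":
        raise ApplicabilityError(f"{strategy} applies to cross-session tasks only")
    ids = [s.session_id for s in sessions]
    ti = ids.index(target_id)
    candidates = [s for s in sessions if s.session_id != target_id]

    if strategy == "Prev":
        return None if ti == 0 else [ids[ti - 1]]
    if strategy == "Next":
        return None if ti == len(ids) - 1 else [ids[ti + 1]]
    if strategy == "All":
        return [s.session_id for s in candidates]
    if strategy in ("Best", "Worst"):
        if self_test_acc is None:
            raise ValueError("Best/Worst need self-test accuracies")
        accs = [(self_test_acc[s.session_id], s.session_id) for s in candidates]
        pick = max if strategy == "Best" else min
        best_val = pick(a for a, _ in accs)
        return [next(sid for a, sid in accs if a == best_val)]
    # Closest: KL in each candidate's own feature space
    target = sessions[ti]
    kls = []
    for cand in candidates:
        model = fit_csp_from_epochs(cand, n_pairs=n_pairs)
        f_cand = extract_features(model, cand)
        f_target = extract_features(model, target)
        kls.append((kl_divergence(f_cand, f_target), cand.session_id))
    best_val = min(k for k, _ in kls)
    return [next(sid for k, sid in kls if k == best_val)]


def evaluate_strategies(sessions: list[EpochSet], task: str = "cross-session",
                        n_pairs: int = 1,
                        strategies: tuple[str, ...] | None = None) -> StrategyReport:
    """Score every applicable strategy on every target session.

    For each (target, strategy): select the training set, fit CSP+LDA on
    its concatenated trials, and record accuracy on the target.
    """
    if len(sessions) < 3:
        raise ValueError("need at least 3 sessions for meaningful selection")
    if task not in ("cross-session", "cross-subject"):
        raise ValueError(f"unknown task {task!r}")
    if strategies is None:
        strategies = tuple(s for s in STRATEGY_NAMES
                           if task == "cross-session" or s not in CROSS_SESSION_ONLY)
    for s in strategies:
        if s in CROSS_SESSION_ONLY and task != "cross-session":
            raise ApplicabilityError(f"{s} applies to cross-session tasks only")

    ids = [s.session_id for s in sessions]
    by_id = {s.session_id: s for s in sessions}
    diag = self_test_accuracies(sessions, n_pairs=n_pairs)

    table = pd.DataFrame(index=ids, columns=list(strategies), dtype=float)
    chosen = pd.DataFrame(index=ids, columns=list(strategies), dtype=object)
    for target_id in ids:
        target = by_id[target_id]
        for strat in strategies:
            train_ids = select_training(strat, target_id, sessions,
                                        self_test_acc=diag, task=task,
                                        n_pairs=n_pairs)
            if train_ids is None:
                chosen.loc[target_id, strat] = None
                continue
            train = concatenate_epochs([by_id[i] for i in train_ids])
            model = fit_csp_from_epochs(train, n_pairs=n_pairs)
            lda = fit_lda(extract_features(model, train))
            f = extract_features(model, target)
            table.loc[target_id, strat] = accuracy(predict(lda, f), f.labels)
            chosen.loc[target_id, strat] = "+".join(train_ids)
    return StrategyReport(task=task, table=table, selections=chosen)
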