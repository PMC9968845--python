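"""Cross-train/test transfer matrices and feature-distribution statistics.

For m sessions, every ordered pair (i, j) gets a CSP+LDA model fit on
all trials of session i and evaluated on session j (the diagonal is the
within-session self-test, training set = test set). Each cell also keeps
session j's features in session i's CSP space, summarized by four
statistics of the 2-D feature cloud:

* Mean  mu = pooled mean over both classes (per dimension)
* Std   s  = pooled per-dimension standard deviation, 1/(2n) normalization
* Dist_w   = mean Euclidean distance of trials to their own class center
* Dist_b   = Euclidean distance between the two class centers

Diagonal (self-test) and off-diagonal (transfer) cells of two cohorts
are compared per statistic with two-sample t-tests under Bonferroni
correction (family of 12: 6 statistics x {self-test, transfer}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .csp import FeatureSet, covariance_set, fit_csp, extract_features
from .lda import fit_lda, predict, accuracy
from .preprocess import EpochSet

__all__ = ["CrossMatrix", "DistStats", "TTestReport", "build_cross_matrix",
           "dist_stats", "compare_exp_groups", "paired_ttest",
           "STATISTIC_NAMES"]

STATISTIC_NAMES = ("mean_dim1", "mean_dim2", "std_dim1", "std_dim2",
                   "dist_w", "dist_b")


@dataclass
class CrossMatrix:
    """Accuracy and feature grids for one cohort of sessions."""

    session_ids: list[str]
    acc: np.ndarray                       # m x m, percent; [i, j] = train i, test j
    feats: list[list[FeatureSet]]

    @property
    def m(self) -> int:
        return len(self.session_ids)

    def diagonal(self) -> np.ndarray:
        return np.diag(self.acc)

    def accuracy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(np.round(self.acc, 2), index=self.session_ids,
                            columns=self.session_ids)

    def cell_stats(self, which: str = "offdiag") -> list["DistStats"]:
        """DistStats of the diagonal or off-diagonal cells, row-major."""
        out = []
        for i in range(self.m):
            for j in range(self.m):
                if (which == "diag") == (i == j):
                    out.append(dist_stats(self.feats[i][j]))
        return out


@dataclass
class DistStats:
    """The four distribution statistics of one 2-D feature cloud."""

    mu: np.ndarray
    s: np.ndarray
    dist_w: float
    dist_b: float
    mu_class: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)

    def as_row(self) -> dict[str, float]:
        return {"mean_dim1": self.mu[0], "mean_dim2": self.mu[1],
                "std_dim1": self.s[0], "std_dim2": self.s[1],
                "dist_w": self.dist_w, "dist_b": self.dist_b}


@dataclass
class TTestReport:
    """Per-statistic two-sample t-test results at a Bonferroni-adjusted
    threshold (family alpha / number of family-wide comparisons)."""

    rows: pd.DataFrame
    family_alpha: float
    n_comparisons: int
    group_sizes: tuple[int, int]

    @property
    def adjusted_alpha(self) -> float:
        return self.family_alpha / self.n_comparisons

    def significant(self) -> dict[str, bool]:
        return dict(zip(self.rows["statistic"], self.rows["significant"]))


def build_cross_matrix(sessions: list[EpochSet], n_pairs: int = 1) -> CrossMatrix:
    """Fit per-session CSP+LDA and evaluate on every session.

    All trials of the training session are used both to fit and for its
    own diagonal score (self-test). Feature dimension is 2*n_pairs;
    n_pairs = 1 gives the 2-D space the distribution statistics assume.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions")
    chans = sessions[0].channel_labels
    if any(s.channel_labels != chans for s in sessions):
        raise ValueError("sessions have different channel sets")
    ids = [s.session_id for s in sessions]
    m = len(sessions)

    models = []
    for s in sessions:
        cs = covariance_set(s)
        csp = fit_csp(cs.cov_left, cs.cov_right, n_pairs=n_pairs,
                      channel_labels=chans, session_id=s.session_id)
        train_feats = extract_features(csp, s)
        lda = fit_lda(train_feats)
        models.append((csp, lda))

    acc = np.zeros((m, m))
    feats: list[list[FeatureSet]] = [[None] * m for _ in range(m)]
    for i, (csp, lda) in enumerate(models):
        for j, s in enumerate(sessions):
            f = extract_features(csp, s)
            feats[i][j] = f
            acc[i, j] = accuracy(predict(lda, f), f.labels)
    return CrossMatrix(session_ids=ids, acc=acc, feats=feats)


def dist_stats(feats: FeatureSet) -> DistStats:
    """Mean, Std, within- and between-class distance of a 2-D cloud."""
    x, labels = feats.x, feats.labels
    if x.shape[1] != 2:
        raise ValueError("distribution statistics are defined for 2-D features")
    x1, x2 = x[labels == 1], x[labels == 2]
    if not len(x1) or not len(x2):
        raise ValueError("both classes must be present")
    mu = x.mean(axis=0)
    s = np.sqrt(((x - mu) ** 2).mean(axis=0))      # 1/(2n) normalization
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    dist_w = float(np.mean(np.concatenate([
        np.linalg.norm(x1 - mu1, axis=1), np.linalg.norm(x2 - mu2, axis=1)])))
    dist_b = float(np.linalg.norm(mu1 - mu2))
    return DistStats(mu=mu, s=s, dist_w=dist_w, dist_b=dist_b,
                     mu_class=(mu1, mu2))


def compare_exp_groups(stats_a: list[DistStats], stats_b: list[DistStats],
                       family_alpha: float = 0.05, n_comparisons: int = 12,
                       welch: bool = False) -> TTestReport:
    """Two-sample t-test per statistic between two groups of DistStats.

    Student's equal-variance test by default (``welch`` switches to the
    unequal-variance form). Significance is judged against
    family_alpha / n_comparisons; with the default family of 12 that is
    0.05/12 ~= 4.17e-3.
    """
    if not stats_a or not stats_b:
        raise ValueError("both groups must be non-empty")
    a = pd.DataFrame([s.as_row() for s in stats_a])
    b = pd.DataFrame([s.as_row() for s in stats_b])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    alpha = family_alpha / n_comparisons
    rows = []
    for name in STATISTIC_NAMES:
        t, p = sps.ttest_ind(a[name], b[name], equal_var=not welch)
        rows.append({"statistic": name,
                     "group_a_mean": a[name].mean(),
                     "group_b_mean": b[name].mean(),
                     "t": float(t), "p": float(p),
                     "significant": bool(p < alpha)})
    return TTestReport(rows=pd.DataFrame(rows), family_alpha=family_alpha,
                       n_comparisons=n_comparisons,
                       group_sizes=(len(a), len(b)))


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Paired two-sample t-test; (nan, nan) for zero-variance differences."""
    a, b = np.asarray(acc_a, dtype=float), np.asarray(acc_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        import warnings
        warnings.warn("zero-variance differences: p undefined")
        return (float("nan"), float("nan"))
    t, p = sps.ttest_rel(a, b)
    return (float(t), float(p))
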