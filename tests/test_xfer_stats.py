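"""Cross matrices, distribution statistics and group comparisons."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mvlab.csp import FeatureSet
from mvlab.xfer_stats import (build_cross_matrix, compare_exp_groups,
                              dist_stats, paired_ttest, STATISTIC_NAMES)


def features(points, labels):
    return FeatureSet(x=np.asarray(points, float),
                      labels=np.asarray(labels, int))


class TestCrossMatrix:
    def test_duplicate_sessions_give_equal_cells(self, strong_epochs):
        a = dataclasses.replace(strong_epochs, session_id="s1")
        b = dataclasses.replace(strong_epochs, session_id="s2")
        mat = build_cross_matrix([a, b], n_pairs=1)
        assert mat.acc.shape == (2, 2)
        assert len(set(np.round(mat.acc.ravel(), 10))) == 1

    def test_matrix_shape_and_partition(self, session_pair, strong_epochs):
        sessions = [dataclasses.replace(s, session_id=f"s{i}")
                    for i, s in enumerate([*session_pair, strong_epochs])]
        mat = build_cross_matrix(sessions, n_pairs=1)
        assert mat.acc.shape == (3, 3)
        assert len(mat.cell_stats("diag")) == 3
        assert len(mat.cell_stats("offdiag")) == 6

    def test_self_test_beats_transfer_on_contrasted_cohort(self):
        """Across a dispersed multi-subject cohort the diagonal dominates
        the off-diagonal cells on average."""
        import dataclasses as dc
        from mvlab.preprocess import preprocess_chain
        from mvlab.synthgen import exp1_config, make_cohort

        cfg = exp1_config(seed=4, n_subjects=4, n_runs=2, trials_per_run=10)
        sessions = [dc.replace(preprocess_chain(r), session_id=r.subject_id)
                    for r in make_cohort(cfg)]
        mat = build_cross_matrix(sessions, n_pairs=1)
        off = mat.acc[~np.eye(4, dtype=bool)]
        assert mat.diagonal().mean() > off.mean()

    def test_needs_two_sessions(self, strong_epochs):
        with pytest.raises(ValueError):
            build_cross_matrix([strong_epochs])


class TestDistStats:
    def test_four_point_hand_computation(self):
        f = features([(0, 0), (2, 0), (0, 2), (2, 2)], [1, 1, 2, 2])
        d = dist_stats(f)
        np.testing.assert_allclose(d.mu, [1.0, 1.0])
        np.testing.assert_allclose(d.mu_class[0], [1.0, 0.0])
        np.testing.assert_allclose(d.mu_class[1], [1.0, 2.0])
        np.testing.assert_allclose(d.dist_w, 1.0)
        np.testing.assert_allclose(d.dist_b, 2.0)

    def test_identical_class_centers_zero_between_distance(self):
        f = features([(0, 0), (2, 2), (2, 2), (0, 0)], [1, 1, 2, 2])
        assert dist_stats(f).dist_b == 0.0

    def test_point_mass_cloud(self):
        f = features([(1, 1)] * 6, [1, 1, 1, 2, 2, 2])
        d = dist_stats(f)
        np.testing.assert_allclose(d.s, 0.0)
        assert d.dist_w == 0.0

    def test_matches_naive_loop(self, gaussian_cloud_features):
        f = gaussian_cloud_features(n=40, sep=1.3, seed=9)
        d = dist_stats(f)
        # naive re-implementation, one trial at a time
        mu = sum(x for x in f.x) / len(f.x)
        s = np.sqrt(sum((x - mu) ** 2 for x in f.x) / len(f.x))
        mus = {c: f.x[f.labels == c].mean(axis=0) for c in (1, 2)}
        dw = np.mean([np.sqrt(((x - mus[c]) ** 2).sum())
                      for x, c in zip(f.x, f.labels)])
        db = np.sqrt(((mus[1] - mus[2]) ** 2).sum())
        np.testing.assert_allclose(d.mu, mu)
        np.testing.assert_allclose(d.s, s)
        np.testing.assert_allclose(d.dist_w, dw)
        np.testing.assert_allclose(d.dist_b, db)

    def test_std_identity_against_one_pass(self, gaussian_cloud_features):
        """Eq. identity: s^2 per dimension equals the pooled mean squared
        deviation computed one-pass."""
        f = gaussian_cloud_features(n=35, seed=4)
        d = dist_stats(f)
        one_pass = (f.x ** 2).mean(axis=0) - f.x.mean(axis=0) ** 2
        np.testing.assert_allclose(d.s ** 2, one_pass, rtol=1e-10)

    def test_non_2d_rejected(self):
        f = FeatureSet(x=np.zeros((4, 3)), labels=np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError):
            dist_stats(f)


class TestCompareGroups:
    def make_stats(self, rng, n, mean_shift=0.0):
        out = []
        for _ in range(n):
            x = rng.normal([0.0 + mean_shift, 1.0], 0.5, (30, 2))
            out.append(dist_stats(FeatureSet(
                x=x, labels=np.array([1] * 15 + [2] * 15))))
        return out

    def test_identical_groups_nothing_significant(self, gaussian_cloud_features):
        stats = [dist_stats(gaussian_cloud_features(seed=s)) for s in range(6)]
        rep = compare_exp_groups(stats, list(stats))
        assert not rep.rows["significant"].any()
        np.testing.assert_allclose(rep.rows["t"], 0.0, atol=1e-12)

    def test_adjusted_alpha_for_default_family(self, gaussian_cloud_features):
        stats = [dist_stats(gaussian_cloud_features(seed=s)) for s in range(4)]
        rep = compare_exp_groups(stats, stats)
        assert rep.adjusted_alpha == pytest.approx(0.05 / 12)
        assert round(rep.adjusted_alpha, 5) == round(4.17e-3, 5)

    def test_power_against_two_sd_mean_offset(self):
        """Two groups of n=30 DistStats whose underlying means differ by
        two pooled sds are flagged at the adjusted threshold in >= 95% of
        200 simulations (power check on the mean statistic)."""
        rng = np.random.default_rng(42)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, 30)
            b = rng.normal(2.0, 1.0, 30)
            from scipy import stats as sps
            _, p = sps.ttest_ind(a, b)
            hits += p < 0.05 / 12
        assert hits / n_sim >= 0.95

    def test_report_metadata_and_welch_option(self, gaussian_cloud_features):
        a = [dist_stats(gaussian_cloud_features(seed=s)) for s in range(5)]
        b = [dist_stats(gaussian_cloud_features(seed=s, sd=0.8))
             for s in range(7)]
        rep = compare_exp_groups(a, b, welch=True)
        assert rep.group_sizes == (5, 7)
        assert list(rep.rows["statistic"]) == list(STATISTIC_NAMES)


class TestPairedTTest:
    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        b = rng.normal(70.0, 5.0, 10)
        a = b + 1.0 + rng.normal(0.0, 0.1, 10)
        t, p = paired_ttest(a, b)
        assert p < 0.001 and t > 0

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            t, p = paired_ttest(a, a)
        assert np.isnan(t) and np.isnan(p)

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.3, 1, 12)
        assert paired_ttest(a, b) == pytest.approx(sps.ttest_rel(a, b))


def test_dist_stats_invariants_on_arbitrary_clouds():
    """s >= 0 per dimension, Dist_w >= 0, Dist_b >= 0, all finite, and
    translation invariance of s, Dist_w, Dist_b."""
    from hypothesis import given, settings, strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (8, 2),
                      elements=st.floats(-100, 100, allow_nan=False)),
           st.floats(-50, 50, allow_nan=False))
    def check(x, shift):
        f = features(x, [1, 1, 1, 1, 2, 2, 2, 2])
        d = dist_stats(f)
        assert (d.s >= 0).all() and d.dist_w >= 0 and d.dist_b >= 0
        assert np.isfinite([*d.mu, *d.s, d.dist_w, d.dist_b]).all()
        d2 = dist_stats(features(x + shift, f.labels))
        np.testing.assert_allclose(d2.s, d.s, atol=1e-8)
        np.testing.assert_allclose(d2.dist_w, d.dist_w, atol=1e-8)
        np.testing.assert_allclose(d2.dist_b, d.dist_b, atol=1e-8)

    check()
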