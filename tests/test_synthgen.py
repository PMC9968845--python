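"""Cohort generator: priors, determinism, signal phenomenology."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from mvlab.synthgen import (CohortConfig, PARAM_SCALES, draw_session_params,
                            draw_subject_params, exp1_config, exp2_config,
                            expected_erd_index, make_cohort,
                            synthesize_session)
from tests.conftest import nominal_session, nominal_subject


class TestConfig:
    def test_paradigm_defaults(self):
        cfg = CohortConfig()
        assert cfg.trials_per_session == 240
        assert cfg.fs == 250.0
        assert len(cfg.channel_labels) == 20

    @pytest.mark.parametrize("kw", [
        {"trials_per_run": 7},
        {"inter_session_sd": -0.1},
        {"fs": 300.0},
        {"n_runs": 0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CohortConfig(**kw)


class TestSubjectDraws:
    def test_zero_dispersion_gives_nominal_parameters(self):
        cfg = CohortConfig(inter_subject_sd=0.0)
        a = draw_subject_params(cfg, np.random.default_rng(0))
        b = draw_subject_params(cfg, np.random.default_rng(99))
        for f in ("mu_peak_hz", "beta_peak_hz", "erd_depth_contra",
                  "erd_depth_ipsi", "ers_rebound", "snr", "lapse_rate"):
            assert getattr(a, f) == getattr(b, f)
        np.testing.assert_allclose(a.topo_left, b.topo_left)

    def test_same_seed_same_parameters(self):
        cfg = CohortConfig(seed=3)
        a = draw_subject_params(cfg, np.random.default_rng(42))
        b = draw_subject_params(cfg, np.random.default_rng(42))
        assert a.mu_peak_hz == b.mu_peak_hz
        assert a.snr == b.snr
        np.testing.assert_array_equal(a.topo_right, b.topo_right)

    def test_erd_prior_sd_recovered_by_monte_carlo(self):
        """Sample sd of erd_depth_contra over 1000 draws matches the
        configured prior sd within 15%.

        The prior is the product of a truncated normal (depth) and a
        clipped log-normal (vigilance); its moments are computed here by
        quadrature, independent of the sampling path."""
        from scipy import integrate, stats

        from mvlab.synthgen import (NOMINAL, PARAM_BOUNDS, VIGILANCE_BOUNDS,
                                    VIGILANCE_SIGMA)

        s = 0.1
        cfg = CohortConfig(inter_subject_sd=s)
        rng = np.random.default_rng(123)
        draws = np.array([draw_subject_params(cfg, rng).erd_depth_contra
                          for _ in range(1000)])
        mu_x = NOMINAL["erd_depth_contra"]
        sd_x = PARAM_SCALES["erd_depth_contra"] * s
        lo, hi = PARAM_BOUNDS["erd_depth_contra"]
        a, b = (lo - mu_x) / sd_x, (hi - mu_x) / sd_x
        ex = stats.truncnorm.mean(a, b, mu_x, sd_x)
        ex2 = stats.truncnorm.var(a, b, mu_x, sd_x) + ex ** 2
        sig = VIGILANCE_SIGMA * s

        def moment(k):
            f = lambda z: stats.norm.pdf(z) * np.clip(
                np.exp(sig * z), *VIGILANCE_BOUNDS) ** k
            return integrate.quad(f, -10, 10)[0]

        target = np.sqrt(ex2 * moment(2) - (ex * moment(1)) ** 2)
        assert abs(draws.std(ddof=1) - target) / target < 0.15

    def test_bounds_always_respected(self):
        cfg = CohortConfig(inter_subject_sd=1.0)  # extreme dispersion
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = draw_subject_params(cfg, rng)
            p.validate()
            assert 0.0 <= p.erd_depth_contra < 1.0
            assert p.snr > 0


class TestSessionDraws:
    def test_zero_session_dispersion_copies_subject(self):
        cfg = CohortConfig(inter_session_sd=0.0)
        subj = nominal_subject()
        sess = draw_session_params(subj, cfg, np.random.default_rng(0), 4)
        for f in ("mu_peak_hz", "erd_depth_contra", "erd_depth_ipsi", "snr",
                  "lapse_rate"):
            assert getattr(sess, f) == pytest.approx(getattr(subj, f))
        np.testing.assert_allclose(sess.topo_left, subj.topo_left)
        assert sess.session_index == 4

    def test_clipping_keeps_depth_below_one(self):
        cfg = CohortConfig(inter_session_sd=2.0)
        subj = nominal_subject(erd_contra=0.95)
        rng = np.random.default_rng(1)
        for _ in range(100):
            sess = draw_session_params(subj, cfg, rng)
            assert sess.erd_depth_contra < 1.0

    def test_variance_decomposition_across_cohort(self):
        """With inter_session_sd < inter_subject_sd, between-subject
        variance exceeds mean within-subject variance for every scalar
        parameter (checked on the stored ground truth)."""
        cfg = CohortConfig(n_subjects=10, n_sessions_per_subject=10,
                           n_runs=1, trials_per_run=2, seed=17)
        rng_root = np.random.SeedSequence(17)
        fields = ("mu_peak_hz", "beta_peak_hz", "erd_depth_contra",
                  "erd_depth_ipsi", "ers_rebound", "snr", "lapse_rate")
        per_subject = {f: [] for f in fields}
        within_var = {f: [] for f in fields}
        for sseq in rng_root.spawn(cfg.n_subjects):
            subj = draw_subject_params(cfg, np.random.default_rng(sseq))
            rng = np.random.default_rng(sseq.spawn(1)[0])
            draws = [draw_session_params(subj, cfg, rng, k)
                     for k in range(cfg.n_sessions_per_subject)]
            for f in fields:
                vals = [getattr(d, f) for d in draws]
                per_subject[f].append(np.mean(vals))
                within_var[f].append(np.var(vals, ddof=1))
        for f in fields:
            between = np.var(per_subject[f], ddof=1)
            within = np.mean(within_var[f])
            assert between > within, f

    def test_mu_peak_between_exceeds_within(self):
        """Spot check on the generated cohort's stored ground truth."""
        cfg = exp2_config(seed=5, n_subjects=8, n_sessions_per_subject=6,
                          n_runs=1, trials_per_run=2)
        recs = make_cohort(cfg)
        by_subject = {}
        for r in recs:
            by_subject.setdefault(r.subject_id, []).append(
                r.ground_truth.mu_peak_hz)
        means = [np.mean(v) for v in by_subject.values()]
        withins = [np.var(v, ddof=1) for v in by_subject.values()]
        assert np.var(means, ddof=1) > np.mean(withins)


class TestSynthesizeSession:
    def test_event_count_and_balance(self, strong_recording, small_config):
        assert len(strong_recording.events) == small_config.trials_per_session
        labels = [e[1] for e in strong_recording.events]
        assert labels.count("left") == labels.count("right")
        strong_recording.validate()

    def test_full_paradigm_trial_count(self):
        """The standard session layout: 8 runs x 30 trials = 240 events,
        120 per class."""
        cfg = CohortConfig(seed=1)
        rec = synthesize_session(nominal_session(), cfg,
                                 np.random.default_rng(1))
        assert len(rec.events) == 240
        assert sum(e[1] == "left" for e in rec.events) == 120

    def test_no_modulation_gives_near_zero_erd_index(self, small_config):
        from mvlab.preprocess import TFR_WINDOW, preprocess_chain
        from mvlab.tfa import erd_ers_index, wavelet_tfr

        params = nominal_session(erd_contra=0.0, erd_ipsi=0.0, ers=0.0)
        idx = []
        for seed in range(6):
            rec = synthesize_session(params, small_config,
                                     np.random.default_rng(seed))
            ep = preprocess_chain(rec, window=TFR_WINDOW)
            tfr = wavelet_tfr(ep, class_label=1, channels=["C4"])
            idx.append(erd_ers_index(tfr, "C4").index)
        # narrowband power estimates are noisy per session (sd ~18% with
        # 10 trials); the mean over sessions must sit near zero
        assert abs(np.mean(idx)) < 15.0

    def test_spectral_peaks_above_one_over_f_floor(self, small_config):
        rec = synthesize_session(nominal_session(snr=5.0), small_config,
                                 np.random.default_rng(2))
        c3 = list(rec.channel_labels).index("C3")
        f, pxx = sps.welch(rec.data[c3], fs=rec.fs, nperseg=2048)
        def band_mean(lo, hi):
            return pxx[(f >= lo) & (f <= hi)].mean()
        mu = band_mean(9.0, 11.0)
        beta = band_mean(19.0, 21.0)
        floor_mu = 0.5 * (band_mean(5.5, 7.0) + band_mean(14.0, 16.0))
        floor_beta = 0.5 * (band_mean(15.0, 17.0) + band_mean(24.0, 26.0))
        assert mu > 2.0 * floor_mu
        assert beta > 1.3 * floor_beta

    def test_erd_index_matches_generative_oracle(self, small_config):
        """Wavelet ERD index on the contralateral channel agrees with the
        index predicted from the generative band powers."""
        from mvlab.preprocess import TFR_WINDOW, preprocess_chain
        from mvlab.tfa import erd_ers_index, wavelet_tfr

        params = nominal_session(snr=10.0, erd_contra=0.5, erd_ipsi=0.1)
        expected = expected_erd_index(params, small_config, "C4", "left")
        got = []
        for seed in range(8):
            rec = synthesize_session(params, small_config,
                                     np.random.default_rng(seed))
            ep = preprocess_chain(rec, window=TFR_WINDOW)
            tfr = wavelet_tfr(ep, class_label=1, channels=["C4"])
            got.append(erd_ers_index(tfr, "C4").index)
        # the wavelet estimate is systematically slightly shallower than
        # the band-variance oracle (onset/offset ramps and wavelet
        # temporal smearing dilute the fixed 0-4 s window)
        assert abs(np.mean(got) - expected) < 10.0
        assert expected < -25.0  # the modulation is substantial


class TestMakeCohort:
    def test_exp1_preset_shape(self):
        recs = make_cohort(exp1_config(seed=0, n_runs=1, trials_per_run=2))
        assert len(recs) == 8
        assert len({r.subject_id for r in recs}) == 8

    def test_exp2_preset_shape(self):
        recs = make_cohort(exp2_config(seed=0, n_runs=1, trials_per_run=2))
        assert len(recs) == 10
        assert len({r.subject_id for r in recs}) == 1
        assert len({r.session_id for r in recs}) == 10

    def test_bit_identical_reproduction(self):
        cfg = CohortConfig(n_subjects=2, n_sessions_per_subject=2,
                           n_runs=1, trials_per_run=4, seed=33)
        a = make_cohort(cfg)
        b = make_cohort(cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)
            assert ra.events == rb.events
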