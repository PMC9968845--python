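"""Shared fixtures: small synthetic cohorts and feature clouds.

Everything is generated at reduced size (fewer runs/trials than the full
paradigm) to keep the suite fast; the generator itself is exercised at
full scale in dedicated tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mvlab.channels import CHANNELS_20, gaussian_topography
from mvlab.preprocess import CLASSIFY_WINDOW, preprocess_chain
from mvlab.synthgen import (CohortConfig, SessionParams, SubjectParams,
                            draw_session_params, synthesize_session)


def nominal_subject(snr: float = 8.0, erd_contra: float = 0.5,
                    erd_ipsi: float = 0.2, lapse: float = 0.0,
                    ers: float = 0.4) -> SubjectParams:
    """A subject at fixed, known parameters (no random draw)."""
    return SubjectParams(
        mu_peak_hz=10.0, beta_peak_hz=20.0, erd_depth_contra=erd_contra,
        erd_depth_ipsi=erd_ipsi, ers_rebound=ers, snr=snr, lapse_rate=lapse,
        topo_left=gaussian_topography("C3"),
        topo_right=gaussian_topography("C4"))


def nominal_session(**kw) -> SessionParams:
    p = nominal_subject(**kw)
    return SessionParams(session_index=0, **{
        f: getattr(p, f) for f in (
            "mu_peak_hz", "beta_peak_hz", "erd_depth_contra",
            "erd_depth_ipsi", "ers_rebound", "snr", "lapse_rate",
            "topo_left", "topo_right")})


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_runs=2, trials_per_run=10, seed=0)


@pytest.fixture(scope="session")
def strong_recording(small_config):
    """One session with strong, known lateralized ERD (seeded)."""
    rng = np.random.default_rng(7)
    return synthesize_session(nominal_session(snr=8.0), small_config, rng)


@pytest.fixture(scope="session")
def strong_epochs(strong_recording):
    return preprocess_chain(strong_recording, window=CLASSIFY_WINDOW)


@pytest.fixture(scope="session")
def session_pair(small_config):
    """Two sessions of the same subject, mild perturbation, preprocessed."""
    rng = np.random.default_rng(21)
    subj = nominal_subject(snr=8.0)
    out = []
    for k in range(2):
        sp = draw_session_params(subj, small_config, rng, session_index=k)
        rec = synthesize_session(sp, small_config, rng,
                                 session_id=f"ses{k + 1:02d}")
        out.append(preprocess_chain(rec, window=CLASSIFY_WINDOW))
    return out


@pytest.fixture()
def gaussian_cloud_features():
    """Factory for 2-D Gaussian two-class FeatureSet objects."""
    from mvlab.csp import FeatureSet

    def make(n=60, sep=2.0, sd=0.5, seed=0, session=""):
        rng = np.random.default_rng(seed)
        x1 = rng.normal([0.0, 0.0], sd, (n, 2))
        x2 = rng.normal([sep, 0.0], sd, (n, 2))
        x = np.vstack([x1, x2])
        labels = np.array([1] * n + [2] * n)
        return FeatureSet(x=x, labels=labels, source_session=session,
                          csp_session=session)

    return make
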