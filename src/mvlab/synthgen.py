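"""Synthetic sensorimotor-rhythm EEG cohorts.

Generates multi-subject / multi-session motor-imagery recordings whose
statistical structure mirrors a two-class (left vs right hand) cued MI
paradigm: runs of balanced trials, each trial a fixation period, an
imagery period with lateralized mu-band (8-13 Hz) event-related
desynchronization (ERD), and a post-imagery beta-band event-related
synchronization (ERS) rebound on the contralateral side.

The generative model is deliberately simple but produces genuine ERD/ERS
in wavelet power:

* background: 1/f-shaped Gaussian noise, spatially correlated across
  channels through a distance-based mixing kernel (so a shared background
  exists for CSP to filter out);
* rhythms: amplitude-modulated narrowband Gaussian processes (bandpass
  filtered white noise) around the subject's mu and beta peak
  frequencies, one source per hemisphere, mixed through Gaussian gain
  maps centred on C3 and C4;
* modulation: during each imagery interval the mu source power on the
  side contralateral to the imagined hand is scaled by
  ``1 - erd_depth_contra`` (ipsilateral by ``1 - erd_depth_ipsi``); for
  2 s after imagery offset the contralateral beta power is scaled by
  ``1 + ers_rebound``. Envelopes use 250 ms linear ramps to avoid edge
  ringing.

Subject-level parameters are drawn from truncated-normal priors whose
spread is controlled by ``inter_subject_sd``; session-level parameters
perturb a subject's values with spread ``inter_session_sd``. With the
default 3:1 ratio, between-subject parameter variance dominates
within-subject between-session variance, which is the cohort-level
property the downstream analysis is designed to detect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .channels import CHANNELS_20, channel_positions, gaussian_topography

__all__ = [
    "CohortConfig",
    "SubjectParams",
    "SessionParams",
    "SessionRecording",
    "draw_subject_params",
    "draw_session_params",
    "synthesize_session",
    "make_cohort",
    "exp1_config",
    "exp2_config",
    "expected_band_powers",
    "expected_erd_index",
]

#: Nominal (population-median) rhythm parameters.
NOMINAL = {
    "mu_peak_hz": 10.0,
    "beta_peak_hz": 20.0,
    "erd_depth_contra": 0.7,
    "erd_depth_ipsi": 0.25,
    "ers_rebound": 0.4,
    "snr": 7.0,
    "lapse_rate": 0.1,
}

#: log-normal sigma of snr per unit of dispersion
SNR_SIGMA_FACTOR = 1.5

#: ipsilateral ERD depth as a fraction of contralateral: nominal value
#: and prior sd per unit of inter-subject dispersion
IPSI_RATIO_NOMINAL = 0.35
IPSI_RATIO_SCALE = 0.35

#: per-channel log-normal gain jitter per unit of dispersion; kept well
#: below the scalar scales because 2-filter CSP is very sensitive to
#: spatial-pattern rotation (day-to-day cap placement shifts are small,
#: anatomical differences between subjects act mostly through the map
#: width below)
TOPO_JITTER_SCALE = 0.2

#: log-normal sigma of the subject-level topography width per unit of
#: inter-subject dispersion
TOPO_WIDTH_SIGMA = 0.4

#: session vigilance: log-normal sigma per unit of inter-session
#: dispersion of a multiplicative factor on both ERD depths (a drowsy
#: day produces globally weaker desynchronization, never a reversed
#: lateralization), and the rate at which low vigilance distorts the
#: session's topography (per-channel log-normal sd added per unit of
#: vigilance shortfall, quadratic so only genuinely bad days distort).
#: Together these make a session's self-test accuracy predictive of how
#: well models trained on it transfer.
VIGILANCE_SIGMA = 3.0
VIGILANCE_BOUNDS = (0.4, 1.25)
TOPO_DISTORT = 0.8

#: extra attention-lapse probability per unit of vigilance shortfall
LAPSE_VIG = 0.6

#: global recording gain: log-normal sigma per unit of dispersion.
#: Electrode impedance and cap seating scale the whole recording between
#: sessions (and anatomy between subjects) without touching decodability;
#: the resulting diagonal shift of the log-power feature cloud is what a
#: naive distribution-similarity measure mostly sees.
GAIN_SIGMA = 2.0

#: within-session cross-run variability, expressed per unit of
#: inter_session_sd (run-to-run drift is a scaled-down version of the
#: day-to-day change; zero session dispersion gives identical runs):
#: log-normal sigma of the run vigilance drift and per-channel sd of the
#: run topography micro-jitter
RUN_VIGILANCE_PER_SD = 2.5
RUN_TOPO_JITTER_PER_SD = 0.8

#: Per-field prior sd per unit of dispersion (inter_subject_sd or
#: inter_session_sd). erd/ers fields use the dispersion directly.
PARAM_SCALES = {
    "mu_peak_hz": 8.0,
    "beta_peak_hz": 12.0,
    "erd_depth_contra": 0.4,
    "erd_depth_ipsi": 0.4,
    "ers_rebound": 0.6,
    "lapse_rate": 0.4,
}

#: Hard bounds applied after every draw / perturbation.
PARAM_BOUNDS = {
    "mu_peak_hz": (8.0, 13.0),
    "beta_peak_hz": (15.0, 28.0),
    "erd_depth_contra": (0.0, 0.95),
    "erd_depth_ipsi": (0.0, 0.95),
    "ers_rebound": (0.0, 3.0),
    "snr": (0.05, np.inf),
    "lapse_rate": (0.0, 0.9),
}

#: Beta rhythm amplitude relative to mu at the topography peak. Motor mu
#: is typically the stronger rhythm over the hand knob.
BETA_AMP_RATIO = 0.5

#: beta desynchronizes together with mu during imagery (the rebound
#: comes only after imagery ends), at this fraction of the mu ERD depth
BETA_ERD_RATIO = 0.8

#: RMS of the 1/f background per channel, microvolts.
BG_RMS_UV = 10.0

#: Width (channel-layout units) of the spatial mixing kernel of the
#: background noise and of the C3/C4 gain maps.
BG_MIX_WIDTH = 1.5
TOPO_WIDTH = 1.2

#: fraction of background variance that is channel-independent sensor
#: noise; keeps every channel covariance full-rank (a purely kernel-mixed
#: background is near-singular over 20 channels, which no amplifier
#: produces)
SENSOR_NOISE_FRACTION = 0.3

#: Linear ramp length for envelope transitions, seconds.
RAMP_S = 0.25

#: ERS rebound duration after imagery offset, seconds.
ERS_DURATION_S = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for one synthetic cohort."""

    n_subjects: int = 1
    n_sessions_per_subject: int = 1
    n_runs: int = 8
    trials_per_run: int = 30
    fs: float = 250.0
    channel_labels: tuple[str, ...] = CHANNELS_20
    fixation_s: float = 2.0
    imagery_s: float = 4.0
    rest_s: float = 2.0
    inter_subject_sd: float = 0.3
    inter_session_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_run % 2:
            raise ValueError("trials_per_run must be even (balanced classes)")
        if self.inter_subject_sd < 0 or self.inter_session_sd < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.fs not in (250.0, 5000.0):
            raise ValueError("fs must be 250 or 5000 Hz")
        if min(self.n_subjects, self.n_sessions_per_subject,
               self.n_runs, self.trials_per_run) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def trials_per_session(self) -> int:
        return self.n_runs * self.trials_per_run


@dataclass
class SubjectParams:
    """Subject-level rhythm phenotype."""

    mu_peak_hz: float
    beta_peak_hz: float
    erd_depth_contra: float
    erd_depth_ipsi: float
    ers_rebound: float
    snr: float
    #: probability that a trial carries no ERD/ERS modulation (attention
    #: lapse); the dominant source of session-to-session decodability
    #: swings at near-constant trial-averaged time-frequency response
    lapse_rate: float
    #: global recording gain (impedance / cap seating); scales the whole
    #: session, invisible to the ERD index and to classification
    gain: float = 1.0
    #: per-channel gain of the left-hemisphere (C3) and right-hemisphere
    #: (C4) rhythm sources
    topo_left: np.ndarray = field(repr=False, default=None)
    topo_right: np.ndarray = field(repr=False, default=None)

    def validate(self) -> None:
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not (0 <= self.erd_depth_contra < 1 and 0 <= self.erd_depth_ipsi < 1):
            raise ValueError("erd depths must lie in [0, 1)")
        for topo in (self.topo_left, self.topo_right):
            if topo is None or np.any(topo < 0):
                raise ValueError("topography gains must be present and >= 0")


@dataclass
class SessionParams(SubjectParams):
    """Session-level perturbation of a subject's phenotype."""

    session_index: int = 0


@dataclass
class SessionRecording:
    """Continuous EEG for one subject-session plus its event table."""

    data: np.ndarray  # channels x samples, microvolts
    fs: float
    channel_labels: tuple[str, ...]
    #: (onset_sample, class, run); class is "left" or "right",
    #: onset_sample marks imagery onset
    events: list[tuple[int, str, int]]
    subject_id: str
    session_id: str
    ground_truth: SessionParams | None = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self, pre_s: float = 2.0, post_s: float = 8.0) -> None:
        for onset, label, _run in self.events:
            if onset - pre_s * self.fs < 0 or onset + post_s * self.fs > self.n_samples:
                raise ValueError("event epoch window exceeds recording bounds")
            if label not in ("left", "right"):
                raise ValueError(f"unknown class label {label!r}")
        labels = [e[1] for e in self.events]
        if labels.count("left") != labels.count("right"):
            raise ValueError("classes are not balanced")


# ---------------------------------------------------------------------------
# parameter draws


def _truncnorm(rng: np.random.Generator, loc: float, sd: float,
               lo: float, hi: float) -> float:
    """Normal draw clipped to [lo, hi] (truncation by clipping)."""
    return float(np.clip(rng.normal(loc, sd), lo, hi))


def draw_subject_params(config: CohortConfig, rng: np.random.Generator) -> SubjectParams:
    """Draw a subject phenotype from the cohort priors.

    Scalar fields are truncated normals centred on the nominal values with
    sd ``PARAM_SCALES[field] * inter_subject_sd``; snr is log-normal
    (multiplicative spread ``exp(3 * inter_subject_sd)`` at one sigma);
    topography maps are C3/C4 Gaussian bumps with per-channel log-normal
    gain jitter. Deterministic given the rng state.
    """
    s = config.inter_subject_sd
    vals = {
        name: _truncnorm(rng, NOMINAL[name], PARAM_SCALES[name] * s,
                         *PARAM_BOUNDS[name])
        for name in PARAM_SCALES
    }
    # baseline engagement: subjects differ in how reliably they produce
    # the modulation at all, exactly as sessions differ day-to-day (same
    # mechanism, wider spread) — low vigilance scales both ERD depths
    # down, adds attention lapses and distorts the topography
    vigilance = float(np.clip(np.exp(rng.normal(0.0, VIGILANCE_SIGMA * s)),
                              *VIGILANCE_BOUNDS))
    vals["erd_depth_contra"] = float(np.clip(
        vals["erd_depth_contra"] * vigilance, *PARAM_BOUNDS["erd_depth_contra"]))
    # ipsilateral ERD is a fraction of contralateral (lateralized SMR);
    # drawing the two depths independently would too often erase the
    # contra-ipsi contrast that carries the class information
    ratio = _truncnorm(rng, IPSI_RATIO_NOMINAL, IPSI_RATIO_SCALE * s, 0.0, 1.0)
    vals["erd_depth_ipsi"] = float(np.clip(vals["erd_depth_contra"] * ratio,
                                           *PARAM_BOUNDS["erd_depth_ipsi"]))
    vals["lapse_rate"] = float(np.clip(
        vals["lapse_rate"] + LAPSE_VIG * max(0.0, 1.0 - vigilance),
        *PARAM_BOUNDS["lapse_rate"]))
    snr = NOMINAL["snr"] * float(np.exp(rng.normal(0.0, SNR_SIGMA_FACTOR * s)))
    snr = float(np.clip(snr, *PARAM_BOUNDS["snr"]))
    gain = float(np.exp(rng.normal(0.0, GAIN_SIGMA * s)))

    width_l = TOPO_WIDTH * float(np.exp(rng.normal(0.0, TOPO_WIDTH_SIGMA * s)))
    width_r = TOPO_WIDTH * float(np.exp(rng.normal(0.0, TOPO_WIDTH_SIGMA * s)))
    base_l = gaussian_topography("C3", width_l, config.channel_labels)
    base_r = gaussian_topography("C4", width_r, config.channel_labels)
    n_ch = len(config.channel_labels)
    jitter_sd = (TOPO_JITTER_SCALE * s
                 + TOPO_DISTORT * max(0.0, 1.0 - vigilance) ** 2)
    jit_l = np.exp(rng.normal(0.0, jitter_sd, n_ch))
    jit_r = np.exp(rng.normal(0.0, jitter_sd, n_ch))
    p = SubjectParams(snr=snr, gain=gain, topo_left=base_l * jit_l,
                      topo_right=base_r * jit_r, **vals)
    p.validate()
    return p


def draw_session_params(subject: SubjectParams, config: CohortConfig,
                        rng: np.random.Generator,
                        session_index: int = 0) -> SessionParams:
    """Perturb a subject phenotype into one session's parameters.

    Perturbation sd is ``PARAM_SCALES[field] * inter_session_sd`` per
    field (log-normal for snr and topography gains); results are clipped
    to the same bounds as subject parameters.
    """
    subject.validate()
    s = config.inter_session_sd
    vals = {
        name: _truncnorm(rng, getattr(subject, name), PARAM_SCALES[name] * s,
                         *PARAM_BOUNDS[name])
        for name in PARAM_SCALES
        if not name.startswith("erd_depth")
    }
    # vigilance scales both ERD depths multiplicatively and, when low,
    # distorts the day's topography
    vigilance = float(np.clip(np.exp(rng.normal(0.0, VIGILANCE_SIGMA * s)),
                              *VIGILANCE_BOUNDS))
    for name in ("erd_depth_contra", "erd_depth_ipsi"):
        vals[name] = float(np.clip(getattr(subject, name) * vigilance,
                                   *PARAM_BOUNDS[name]))
    vals["lapse_rate"] = float(np.clip(
        vals["lapse_rate"] + LAPSE_VIG * max(0.0, 1.0 - vigilance),
        *PARAM_BOUNDS["lapse_rate"]))
    snr = subject.snr * float(np.exp(rng.normal(0.0, SNR_SIGMA_FACTOR * s)))
    snr = float(np.clip(snr, *PARAM_BOUNDS["snr"]))
    gain = subject.gain * float(np.exp(rng.normal(0.0, GAIN_SIGMA * s)))
    n_ch = len(subject.topo_left)
    jitter_sd = (TOPO_JITTER_SCALE * s
                 + TOPO_DISTORT * max(0.0, 1.0 - vigilance) ** 2)
    topo_l = subject.topo_left * np.exp(rng.normal(0.0, jitter_sd, n_ch))
    topo_r = subject.topo_right * np.exp(rng.normal(0.0, jitter_sd, n_ch))
    p = SessionParams(snr=snr, gain=gain, topo_left=topo_l, topo_right=topo_r,
                      session_index=session_index, **vals)
    p.validate()
    return p


# ---------------------------------------------------------------------------
# signal synthesis

_GEN_FS = 250.0  # native generation rate; 5 kHz output is upsampled


def _one_over_f_background(n_ch: int, n_samples: int, positions: np.ndarray,
                           rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Spatially correlated 1/f noise, unit variance per channel.

    Returns (background, band_fraction) where band_fraction is the
    expected fraction of each channel's variance that falls in 8-30 Hz —
    known exactly because the spectrum is shaped deterministically.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / _GEN_FS)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])  # amplitude 1/sqrt(f) -> power 1/f
    shaping[freqs < 0.5] = 0.0               # no drift below 0.5 Hz

    def shaped(seed_rows: int) -> np.ndarray:
        white = rng.standard_normal((seed_rows, n_samples))
        return np.fft.irfft(np.fft.rfft(white, axis=1) * shaping,
                            n=n_samples, axis=1)

    # spatially correlated part: distance-kernel mixing of shaped noise
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-d2 / (2.0 * BG_MIX_WIDTH ** 2))
    corr = kernel @ shaped(n_ch)
    corr /= corr.std(axis=1, keepdims=True)
    # channel-independent sensor noise, same spectral shape
    indep = shaped(n_ch)
    indep /= indep.std(axis=1, keepdims=True)
    f = SENSOR_NOISE_FRACTION
    bg = np.sqrt(1.0 - f) * corr + np.sqrt(f) * indep
    bg /= bg.std(axis=1, keepdims=True)

    power = shaping ** 2
    band = (freqs >= 8.0) & (freqs <= 30.0)
    band_fraction = float(power[band].sum() / power.sum())
    return bg, band_fraction


def _narrowband_source(n_samples: int, center_hz: float, half_bw_hz: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance narrowband Gaussian process around center_hz."""
    sos = signal.butter(4, [center_hz - half_bw_hz, center_hz + half_bw_hz],
                        btype="bandpass", fs=_GEN_FS, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def _apply_interval(env: np.ndarray, start: int, stop: int, factor: float,
                    ramp: int) -> None:
    """Multiply env by `factor` on [start, stop) with linear on/off ramps."""
    n = len(env)
    start, stop = max(start, 0), min(stop, n)
    if stop <= start:
        return
    ramp = min(ramp, (stop - start) // 2)
    seg = np.full(stop - start, factor)
    if ramp > 0:
        up = np.linspace(1.0, factor, ramp, endpoint=False)
        seg[:ramp] = up
        seg[-ramp:] = up[::-1]
    env[start:stop] *= seg


def synthesize_session(params: SessionParams, config: CohortConfig,
                       rng: np.random.Generator,
                       subject_id: str = "sub01",
                       session_id: str = "ses01") -> SessionRecording:
    """Render one continuous session from session parameters.

    The session is generated at 250 Hz; a 5 kHz configuration upsamples
    the finished recording by 20 (polyphase), which exists to exercise the
    downsampling stage of the preprocessing chain.
    """
    params.validate()
    fs = _GEN_FS
    trial_len = config.fixation_s + config.imagery_s + config.rest_s
    lead, tail = 2.0, 8.0  # so the first/last [-2, +8] s windows fit
    n_trials = config.trials_per_session
    total_s = lead + n_trials * trial_len + tail
    n = int(round(total_s * fs))
    if config.imagery_s <= 0 or trial_len <= 0:
        raise ValueError("trial timeline does not fit run length")

    # event schedule: per-run balanced random order
    events: list[tuple[int, str, int]] = []
    for run in range(config.n_runs):
        order = ["left"] * (config.trials_per_run // 2) + \
                ["right"] * (config.trials_per_run // 2)
        order = [order[i] for i in rng.permutation(config.trials_per_run)]
        for t, label in enumerate(order):
            idx = run * config.trials_per_run + t
            onset = (lead + idx * trial_len + config.fixation_s) * fs
            events.append((int(round(onset)), label, run))

    positions = channel_positions(config.channel_labels)
    bg, band_fraction = _one_over_f_background(
        len(config.channel_labels), n, positions, rng)
    bg *= BG_RMS_UV

    # rhythm amplitudes: at the topography peak, mu RMS = snr * background
    # RMS inside the 8-30 Hz band
    bg_band_rms = BG_RMS_UV * np.sqrt(band_fraction)
    mu_amp = params.snr * bg_band_rms
    beta_amp = BETA_AMP_RATIO * mu_amp

    mu_l = _narrowband_source(n, params.mu_peak_hz, 1.0, rng)
    mu_r = _narrowband_source(n, params.mu_peak_hz, 1.0, rng)
    beta_l = _narrowband_source(n, params.beta_peak_hz, 2.0, rng)
    beta_r = _narrowband_source(n, params.beta_peak_hz, 2.0, rng)

    # run-level states: vigilance drifts from run to run within a session
    # (fatigue/arousal), scaling the ERD depths, raising the lapse
    # probability and micro-jittering the effective topography — the
    # cross-run variability that makes pooling many runs pay off
    n_ch = len(config.channel_labels)
    run_sigma = RUN_VIGILANCE_PER_SD * config.inter_session_sd
    run_jit_sd = RUN_TOPO_JITTER_PER_SD * config.inter_session_sd
    run_v = np.clip(np.exp(rng.normal(0.0, run_sigma, config.n_runs)),
                    0.5, 1.3)
    run_jit = [(np.exp(rng.normal(0.0, run_jit_sd, n_ch)),
                np.exp(rng.normal(0.0, run_jit_sd, n_ch)))
               for _ in range(config.n_runs)]

    env_mu_l = np.ones(n)
    env_mu_r = np.ones(n)
    env_beta_l = np.ones(n)
    env_beta_r = np.ones(n)
    ramp = int(round(RAMP_S * fs))
    im_len = int(round(config.imagery_s * fs))
    ers_len = int(round(ERS_DURATION_S * fs))
    f_ers = np.sqrt(1.0 + params.ers_rebound)
    for onset, label, run in events:
        v = run_v[run]
        lapse = np.clip(params.lapse_rate + LAPSE_VIG * max(0.0, 1.0 - v),
                        *PARAM_BOUNDS["lapse_rate"])
        if rng.random() < lapse:
            continue  # attention lapse: no modulation this trial
        d_c = min(params.erd_depth_contra * v, 0.95)
        d_i = min(params.erd_depth_ipsi * v, 0.95)
        f_contra = np.sqrt(1.0 - d_c)  # amplitude factor
        f_ipsi = np.sqrt(1.0 - d_i)
        fb_contra = np.sqrt(1.0 - BETA_ERD_RATIO * d_c)
        fb_ipsi = np.sqrt(1.0 - BETA_ERD_RATIO * d_i)
        # left-hand imagery -> contralateral = right hemisphere (C4)
        contra_mu, ipsi_mu = (env_mu_r, env_mu_l) if label == "left" \
            else (env_mu_l, env_mu_r)
        contra_beta, ipsi_beta = (env_beta_r, env_beta_l) if label == "left" \
            else (env_beta_l, env_beta_r)
        _apply_interval(contra_mu, onset, onset + im_len, f_contra, ramp)
        _apply_interval(ipsi_mu, onset, onset + im_len, f_ipsi, ramp)
        _apply_interval(contra_beta, onset, onset + im_len, fb_contra, ramp)
        _apply_interval(ipsi_beta, onset, onset + im_len, fb_ipsi, ramp)
        _apply_interval(contra_beta, onset + im_len,
                        onset + im_len + ers_len, f_ers, ramp)

    data = bg
    run_len = int(round(config.trials_per_run * trial_len * fs))
    lead_n = int(round(lead * fs))
    seg_starts = [0] + [lead_n + r * run_len for r in range(1, config.n_runs)]
    seg_stops = seg_starts[1:] + [n]
    for run, (i0, i1) in enumerate(zip(seg_starts, seg_stops)):
        jl, jr = run_jit[run]
        topo_l = params.topo_left * jl
        topo_r = params.topo_right * jr
        sl = slice(i0, i1)
        data[:, sl] += topo_l[:, None] * (mu_amp * env_mu_l[sl] * mu_l[sl])
        data[:, sl] += topo_r[:, None] * (mu_amp * env_mu_r[sl] * mu_r[sl])
        data[:, sl] += topo_l[:, None] * (beta_amp * env_beta_l[sl] * beta_l[sl])
        data[:, sl] += topo_r[:, None] * (beta_amp * env_beta_r[sl] * beta_r[sl])

    data *= params.gain

    out_fs = config.fs
    if out_fs != fs:
        q = int(round(out_fs / fs))
        data = signal.resample_poly(data, q, 1, axis=1)
        events = [(onset * q, label, run) for onset, label, run in events]

    rec = SessionRecording(data=data, fs=out_fs,
                           channel_labels=config.channel_labels,
                           events=events, subject_id=subject_id,
                           session_id=session_id, ground_truth=params)
    rec.validate()
    return rec


def make_cohort(config: CohortConfig) -> list[SessionRecording]:
    """Generate the full cohort, reproducibly from ``config.seed``.

    Child RNG streams are spawned per subject and per session, so a
    cohort is bit-identical across runs with the same config.
    """
    root = np.random.SeedSequence(config.seed)
    recordings: list[SessionRecording] = []
    subject_seeds = root.spawn(config.n_subjects)
    for si, sseq in enumerate(subject_seeds):
        subj_rng = np.random.default_rng(sseq)
        subject = draw_subject_params(config, subj_rng)
        session_seeds = sseq.spawn(config.n_sessions_per_subject)
        for ki, kseq in enumerate(session_seeds):
            ses_rng = np.random.default_rng(kseq)
            sess = draw_session_params(subject, config, ses_rng,
                                       session_index=ki)
            rec = synthesize_session(sess, config, ses_rng,
                                     subject_id=f"sub{si + 1:02d}",
                                     session_id=f"ses{ki + 1:02d}")
            recordings.append(rec)
    return recordings


def exp1_config(seed: int = 0, **overrides) -> CohortConfig:
    """Multi-subject design: 8 subjects, one session each."""
    kw = dict(n_subjects=8, n_sessions_per_subject=1, seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


def exp2_config(seed: int = 0, **overrides) -> CohortConfig:
    """Multi-session design: one subject, 10 sessions on different days."""
    kw = dict(n_subjects=1, n_sessions_per_subject=10, seed=seed)
    kw.update(overrides)
    return CohortConfig(**kw)


# ---------------------------------------------------------------------------
# generative-model oracles (used by tests and sanity checks)


def expected_band_powers(params: SessionParams,
                         config: CohortConfig) -> dict[str, np.ndarray]:
    """Per-channel expected 8-30 Hz variance of each additive component.

    Computed from the generative amplitudes and gain maps, independent of
    any spectral estimator: background in-band variance, baseline mu and
    beta variance per channel.
    """
    # band fraction of the 1/f shaping, same computation as the generator
    n = int(round(60.0 * _GEN_FS))
    freqs = np.fft.rfftfreq(n, d=1.0 / _GEN_FS)
    power = np.zeros_like(freqs)
    nz = freqs > 0
    power[nz] = 1.0 / freqs[nz]
    power[freqs < 0.5] = 0.0
    band = (freqs >= 8.0) & (freqs <= 30.0)
    frac = power[band].sum() / power.sum()

    bg_band_var = np.full(len(config.channel_labels), (BG_RMS_UV ** 2) * frac)
    mu_amp = params.snr * BG_RMS_UV * np.sqrt(frac)
    beta_amp = BETA_AMP_RATIO * mu_amp
    mu_var = (params.topo_left ** 2 + params.topo_right ** 2) * mu_amp ** 2
    beta_var = (params.topo_left ** 2 + params.topo_right ** 2) * beta_amp ** 2
    return {"background": bg_band_var, "mu": mu_var, "beta": beta_var}


def expected_erd_index(params: SessionParams, config: CohortConfig,
                       channel: str, imagined_hand: str) -> float:
    """Analytic ERD/ERS index (percent) for the imagery window.

    Uses the generative band variances: only the mu source on the
    modulated hemisphere changes between the reference and imagery
    windows, so the index is the mu power drop diluted by the unmodulated
    beta and background power on that channel.
    """
    pw = expected_band_powers(params, config)
    ci = list(config.channel_labels).index(channel)
    # which hemisphere's mu source is contralateral to the imagined hand
    contra_topo = params.topo_right if imagined_hand == "left" else params.topo_left
    ipsi_topo = params.topo_left if imagined_hand == "left" else params.topo_right

    frac = pw["background"][0] / BG_RMS_UV ** 2
    mu_amp2 = (params.snr * BG_RMS_UV) ** 2 * frac
    # expectations over the run-vigilance drift (clipped log-normal),
    # by quadrature on a normal grid
    z = np.linspace(-6.0, 6.0, 2001)
    wgt = np.exp(-z ** 2 / 2)
    wgt /= wgt.sum()
    run_sigma = RUN_VIGILANCE_PER_SD * config.inter_session_sd
    v = np.clip(np.exp(run_sigma * z), 0.5, 1.3)
    e_v = float((wgt * v).sum())
    e_extra_lapse = LAPSE_VIG * float((wgt * np.maximum(0.0, 1.0 - v)).sum())
    # lapsed trials stay at baseline power; others carry the run-scaled ERD
    keep = 1.0 - min(params.lapse_rate + e_extra_lapse, 0.9)
    d_c = params.erd_depth_contra * e_v * keep
    d_i = params.erd_depth_ipsi * e_v * keep
    beta_amp2 = BETA_AMP_RATIO ** 2 * mu_amp2
    pre = pw["background"][ci] + pw["mu"][ci] + pw["beta"][ci]
    post = (pw["background"][ci]
            + contra_topo[ci] ** 2 * (mu_amp2 * (1 - d_c)
                                      + beta_amp2 * (1 - BETA_ERD_RATIO * d_c))
            + ipsi_topo[ci] ** 2 * (mu_amp2 * (1 - d_i)
                                    + beta_amp2 * (1 - BETA_ERD_RATIO * d_i)))
    return float((post - pre) / pre * 100.0)
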