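"""Wavelet time-frequency analysis and the ERD/ERS percent index.

Power is computed per trial with complex Morlet wavelets (fixed 7
cycles, mne backend) and averaged across trials *after* taking power —
the induced-activity convention, appropriate because ERD/ERS is not
phase-locked to the cue. Baseline correction subtracts the mean over a
pre-cue reference interval. The ERD/ERS index is

    index = (P_post - P_pre) / P_pre * 100  [percent]

with P_pre the mean uncorrected power over the reference interval
(default -2..0 s) and P_post over the imagery interval (default 0..4 s),
both averaged over 8-30 Hz. Negative values are desynchronization (ERD),
positive synchronization (ERS).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .preprocess import EpochSet

__all__ = ["TFResponse", "ERDReport", "wavelet_tfr", "baseline_correct",
           "erd_ers_index", "DEFAULT_FREQS", "REF_INTERVAL", "POST_INTERVAL"]

DEFAULT_FREQS = np.arange(8.0, 31.0)  # 8..30 Hz in 1 Hz steps
REF_INTERVAL = (-2.0, 0.0)
POST_INTERVAL = (0.0, 4.0)
N_CYCLES = 7.0

#: seconds of data mirrored-padded on each side before the transform to
#: keep wavelet edge artifacts out of the analysis windows
EDGE_PAD_S = 1.0


@dataclass
class TFResponse:
    """Trial-averaged wavelet power for one class.

    ``power`` has shape (channels, freqs, times), µV²; ``times`` are
    seconds relative to imagery onset.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    class_label: int | None = None
    baseline_corrected: bool = False


@dataclass
class ERDReport:
    """ERD/ERS index on one channel (percent) and its two ingredients."""

    channel: str
    p_pre: float
    p_post: float
    index: float


def wavelet_tfr(epochs: EpochSet, freqs: np.ndarray = DEFAULT_FREQS,
                class_label: int | None = None,
                channels: list[str] | None = None) -> TFResponse:
    """Per-trial Morlet power averaged over trials of one class.

    ``class_label`` of None averages over every trial. ``channels``
    restricts computation (the index is conventionally evaluated on C3
    and C4 only, and the transform is the expensive stage).
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= epochs.fs / 2:
        raise ValueError("requested frequency at or above Nyquist")
    trials = epochs.trials if class_label is None else epochs.class_trials(class_label)
    ch_idx = np.arange(len(epochs.channel_labels))
    labels = epochs.channel_labels
    if channels is not None:
        ch_idx = np.array([list(epochs.channel_labels).index(c) for c in channels])
        labels = tuple(channels)
    data = trials[:, ch_idx, :]

    pad = int(round(EDGE_PAD_S * epochs.fs))
    pad = min(pad, data.shape[2] - 1)
    padded = np.pad(data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    power = tfr_array_morlet(padded, sfreq=epochs.fs, freqs=freqs,
                             n_cycles=N_CYCLES, output="power",
                             zero_mean=True, verbose="error")
    power = power[..., pad:power.shape[-1] - pad].mean(axis=0)
    return TFResponse(power=power, freqs=freqs, times=epochs.time_axis.copy(),
                      channel_labels=labels, class_label=class_label)


def baseline_correct(tfr: TFResponse,
                     ref: tuple[float, float] = REF_INTERVAL) -> TFResponse:
    """Subtract the mean power over ``ref`` per channel and frequency."""
    if tfr.baseline_corrected:
        raise ValueError("already baseline-corrected")
    mask = (tfr.times >= ref[0]) & (tfr.times <= ref[1])
    if not mask.any():
        raise ValueError("reference interval outside the time axis")
    base = tfr.power[:, :, mask].mean(axis=2, keepdims=True)
    return dataclasses.replace(tfr, power=tfr.power - base,
                               baseline_corrected=True)


def erd_ers_index(tfr: TFResponse, channel: str,
                  pre: tuple[float, float] = REF_INTERVAL,
                  post: tuple[float, float] = POST_INTERVAL) -> ERDReport:
    """Percent band-power change from the reference to the imagery window.

    Must be fed *uncorrected* power: the index is a ratio of raw powers.
    """
    if tfr.baseline_corrected:
        raise ValueError("index must be computed on uncorrected power")
    ci = list(tfr.channel_labels).index(channel)
    pre_mask = (tfr.times >= pre[0]) & (tfr.times <= pre[1])
    post_mask = (tfr.times >= post[0]) & (tfr.times <= post[1])
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("interval outside the time axis")
    p_pre = float(tfr.power[ci][:, pre_mask].mean())
    p_post = float(tfr.power[ci][:, post_mask].mean())
    if p_pre <= 0:
        raise ValueError("reference power is zero")
    return ERDReport(channel=channel, p_pre=p_pre, p_post=p_post,
                     index=(p_post - p_pre) / p_pre * 100.0)
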