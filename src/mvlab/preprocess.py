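"""Offline preprocessing chain: downsample -> notch -> bandpass -> epoch.

All filters are zero-phase (forward-backward second-order sections), so
the effective order doubles relative to the stated Butterworth order and
no group delay is introduced; this protects ERD latency estimates in the
offline analyses even though an online system would have to filter
causally. Epochs are cut after whole-recording filtering, so no per-epoch
padding is needed.

Time convention: t = 0 at imagery onset everywhere. The classification
window is [0, 4] s, the time-frequency window [-2, 8] s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthgen import SessionRecording

__all__ = ["EpochSet", "downsample", "notch_filter", "bandpass", "epoch",
           "preprocess_chain", "concatenate_epochs",
           "CLASSIFY_WINDOW", "TFR_WINDOW"]

#: Imagery-relative analysis windows, seconds.
CLASSIFY_WINDOW = (0.0, 4.0)
TFR_WINDOW = (-2.0, 8.0)

#: Integer class codes: left = 1, right = 2.
CLASS_CODES = {"left": 1, "right": 2}


@dataclass
class EpochSet:
    """Per-trial channels x samples arrays with class labels.

    ``trials`` has shape (n_trials, C, T); ``labels`` holds 1 (left) or
    2 (right); ``runs`` the run index of each trial; ``time_axis`` is in
    seconds relative to imagery onset.
    """

    trials: np.ndarray
    labels: np.ndarray
    time_axis: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    runs: np.ndarray | None = None
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, C, T)")
        if len(self.labels) != len(self.trials):
            raise ValueError("labels/trials length mismatch")
        if self.trials.size and not np.isin(self.labels, (1, 2)).all():
            raise ValueError("labels must be 1 (left) or 2 (right)")
        if len(self.time_axis) != self.trials.shape[2]:
            raise ValueError("time_axis length must equal T")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_per_class(self) -> tuple[int, int]:
        return int((self.labels == 1).sum()), int((self.labels == 2).sum())

    def class_trials(self, code: int) -> np.ndarray:
        return self.trials[self.labels == code]


def _per_channel(rec: SessionRecording, data: np.ndarray,
                 fs: float | None = None,
                 events: list | None = None) -> SessionRecording:
    return dataclasses.replace(rec, data=data, fs=fs or rec.fs,
                               events=events if events is not None else rec.events)


def downsample(rec: SessionRecording, target_fs: float) -> SessionRecording:
    """Anti-alias low-pass and decimate to ``target_fs``.

    The decimation factor must be an integer; event sample indices are
    rescaled to the new rate.
    """
    if target_fs == rec.fs:
        return rec
    q = rec.fs / target_fs
    if abs(q - round(q)) > 1e-9:
        raise ValueError(f"non-integer decimation factor {q}")
    q = int(round(q))
    data = signal.resample_poly(rec.data, 1, q, axis=1)
    events = [(onset // q, label, run) for onset, label, run in rec.events]
    return _per_channel(rec, data, fs=target_fs, events=events)


def notch_filter(rec: SessionRecording, freq: float = 50.0,
                 order: int = 4, half_width: float = 2.0) -> SessionRecording:
    """Zero-phase Butterworth band-stop at ``freq`` +/- ``half_width`` Hz."""
    if freq >= rec.fs / 2:
        raise ValueError("notch frequency at or above Nyquist")
    sos = signal.butter(order, [freq - half_width, freq + half_width],
                        btype="bandstop", fs=rec.fs, output="sos")
    return _per_channel(rec, signal.sosfiltfilt(sos, rec.data, axis=1))


def bandpass(rec: SessionRecording, lo: float = 8.0, hi: float = 30.0,
             order: int = 4) -> SessionRecording:
    """Zero-phase Butterworth band-pass (default 8-30 Hz, the SMR band)."""
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(f"invalid band [{lo}, {hi}] at fs={rec.fs}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs,
                        output="sos")
    return _per_channel(rec, signal.sosfiltfilt(sos, rec.data, axis=1))


def epoch(rec: SessionRecording,
          window: tuple[float, float] = CLASSIFY_WINDOW) -> EpochSet:
    """Cut one trial per event, ``window`` seconds around imagery onset."""
    start, end = window
    off0 = int(round(start * rec.fs))
    n_t = int(round((end - start) * rec.fs))
    trials, labels, runs = [], [], []
    for onset, label, run in rec.events:
        i0 = onset + off0
        if i0 < 0 or i0 + n_t > rec.n_samples:
            raise ValueError("epoch window exceeds recording bounds")
        trials.append(rec.data[:, i0:i0 + n_t])
        labels.append(CLASS_CODES[label])
        runs.append(run)
    time_axis = start + np.arange(n_t) / rec.fs
    trials_arr = np.array(trials) if trials else np.empty((0, rec.n_channels, n_t))
    return EpochSet(trials=trials_arr, labels=np.array(labels, dtype=int),
                    time_axis=time_axis, fs=rec.fs,
                    channel_labels=rec.channel_labels,
                    runs=np.array(runs, dtype=int),
                    subject_id=rec.subject_id, session_id=rec.session_id)


def preprocess_chain(rec: SessionRecording, target_fs: float = 250.0,
                     window: tuple[float, float] = CLASSIFY_WINDOW,
                     notch_freq: float = 50.0,
                     band: tuple[float, float] = (8.0, 30.0)) -> EpochSet:
    """The full fixed-order chain: downsample, notch, bandpass, epoch."""
    rec = downsample(rec, target_fs)
    rec = notch_filter(rec, notch_freq)
    rec = bandpass(rec, *band)
    return epoch(rec, window)


def concatenate_epochs(sets: list[EpochSet]) -> EpochSet:
    """Stack several EpochSets (same montage, fs and window) into one."""
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.trials.shape[1:] != first.trials.shape[1:] or s.fs != first.fs:
            raise ValueError("incompatible epoch sets")
    return EpochSet(
        trials=np.concatenate([s.trials for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        time_axis=first.time_axis, fs=first.fs,
        channel_labels=first.channel_labels,
        runs=np.concatenate([s.runs for s in sets]) if first.runs is not None else None,
        subject_id="+".join(dict.fromkeys(s.subject_id for s in sets)),
        session_id="+".join(s.session_id for s in sets),
    )
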