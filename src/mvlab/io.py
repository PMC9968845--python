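"""Session I/O: the native array+metadata bundle, and an EDF reader.

A bundle is one directory per session containing

* ``data.npz``     — compressed ``data`` array, channels x samples (µV)
* ``meta.json``    — fs, channel labels, subject/session ids
* ``events.csv``   — columns onset_sample, class, run

EDF recordings with a sidecar ``events.csv`` of the same layout can be
read through :func:`read_edf` (mne backend).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import SessionRecording

__all__ = ["write_bundle", "read_bundle", "write_events_csv",
           "read_events_csv", "read_edf"]


def write_events_csv(events: list[tuple[int, str, int]], path: Path) -> None:
    pd.DataFrame(events, columns=["onset_sample", "class", "run"]).to_csv(
        path, index=False)


def read_events_csv(path: Path) -> list[tuple[int, str, int]]:
    df = pd.read_csv(path)
    return [(int(r.onset_sample), str(r["class"]), int(r.run))
            for _, r in df.iterrows()]


def write_bundle(rec: SessionRecording, directory: str | Path) -> Path:
    """Write one session to a bundle directory; returns the directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "data.npz", data=rec.data)
    meta = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))
    write_events_csv(rec.events, d / "events.csv")
    return d


def read_bundle(directory: str | Path) -> SessionRecording:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    with np.load(d / "data.npz") as z:
        data = z["data"]
    return SessionRecording(
        data=data, fs=float(meta["fs"]),
        channel_labels=tuple(meta["channel_labels"]),
        events=read_events_csv(d / "events.csv"),
        subject_id=meta["subject_id"], session_id=meta["session_id"],
        ground_truth=None)


def read_edf(edf_path: str | Path, events_csv: str | Path,
             subject_id: str = "", session_id: str = "") -> SessionRecording:
    """Read an EDF recording plus its sidecar event table.

    Data are converted from mne's volts to microvolts so downstream code
    sees the same units as the synthetic generator.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    return SessionRecording(
        data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        events=read_events_csv(events_csv),
        subject_id=subject_id, session_id=session_id, ground_truth=None)
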