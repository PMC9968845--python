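"""Electrode montage used throughout the package.

Twenty channels over the sensorimotor strip surrounding C3, Cz and C4,
in the fixed acquisition order. A flat 2-D layout (lateral position x,
anterior-posterior row y) is attached for topography maps and for the
distance-based spatial correlation of the background noise.
"""

from __future__ import annotations

import numpy as np

#: Acquisition order of the 20 sensorimotor channels.
CHANNELS_20: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
)

_ROW_Y = {"FC": 1.0, "C": 0.0, "CP": -1.0}


def channel_positions(labels: tuple[str, ...] = CHANNELS_20) -> np.ndarray:
    """Flat (x, y) coordinates for 10-20 sensorimotor labels.

    Odd digits are left of the midline, even digits right, 'z' on it;
    C1/C2 sit one unit from the midline, C3/C4 two, C5/C6 three.
    """
    pos = np.empty((len(labels), 2))
    for i, lab in enumerate(labels):
        row = lab.rstrip("123456z")
        suffix = lab[len(row):]
        if suffix == "z":
            x = 0.0
        else:
            d = int(suffix)
            x = -((d + 1) // 2) if d % 2 else (d // 2)
        pos[i] = (x, _ROW_Y[row])
    return pos


def gaussian_topography(center: str, width: float = 1.2,
                        labels: tuple[str, ...] = CHANNELS_20) -> np.ndarray:
    """Per-channel gain map: Gaussian bump around one electrode, peak 1."""
    pos = channel_positions(labels)
    c = pos[list(labels).index(center)]
    d2 = ((pos - c) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * width ** 2))
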