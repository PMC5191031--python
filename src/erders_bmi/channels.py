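"""The 28-channel sensorimotor montage and its planar geometry.

Electrodes cover the fronto-central to parietal strip of the extended 10-20
system in four rows (FC, C, CP, P) of seven positions (5, 3, 1, z, 2, 4, 6).
A flat grid with unit spacing between neighbouring positions stands in for
scalp geometry; it is only used for distance-decay source mixing and for
grouping channels around the classical hand/foot motor sites C3, C4 and Cz.
"""

from __future__ import annotations

import numpy as np

CHANNELS_28: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P5", "P3", "P1", "Pz", "P2", "P4", "P6",
)

_ROW_Y = {"FC": 1.0, "C": 0.0, "CP": -1.0, "P": -2.0}
_COL_X = {"5": -3.0, "3": -2.0, "1": -1.0, "z": 0.0, "2": 1.0, "4": 2.0, "6": 3.0}


def channel_position(label: str) -> tuple[float, float]:
    """Planar (x, y) position of a montage channel, unit electrode spacing."""
    row = label[:-1]
    col = label[-1]
    if row not in _ROW_Y or col not in _COL_X:
        raise ValueError(f"unknown channel label {label!r}")
    return (_COL_X[col], _ROW_Y[row])


#: Oscillatory source sites: left-hand area is C4 (right hemisphere),
#: right-hand area is C3, foot area is Cz (midline).
SOURCE_SITES: tuple[str, ...] = ("C3", "Cz", "C4")

#: Default sensorimotor channels used for ERD/ERS summaries and band choice.
SENSORIMOTOR_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4")


def mixing_matrix(
    channel_labels: tuple[str, ...],
    source_sites: tuple[str, ...] = SOURCE_SITES,
    spread: float = 0.5,
) -> np.ndarray:
    """Gaussian distance-decay mixing from source sites to channels.

    ``spread`` in [0, 1] scales the spatial leakage; the Gaussian sigma is
    ``2 * spread`` electrode spacings, so at the default 0.5 a source leaks
    with weight exp(-1/2) to its immediate neighbours and exp(-2) two
    positions away.
    """
    if not 0.0 <= spread <= 1.0:
        raise ValueError("mixing_spread must lie in [0, 1]")
    sigma = max(2.0 * spread, 1e-6)
    pos = np.array([channel_position(c) for c in channel_labels])
    src = np.array([channel_position(s) for s in source_sites])
    d2 = ((pos[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma**2))


def frontal_weights(channel_labels: tuple[str, ...]) -> np.ndarray:
    """Blink-artifact projection: strongest on the frontal row, decaying back."""
    w = {"FC": 1.0, "C": 0.85, "CP": 0.7, "P": 0.55}
    return np.array([w[c[:-1]] for c in channel_labels])
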