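"""32-channel 10-20 montage used by the simulator.

The channel set matches a standard 32-electrode ActiCap layout. Positions are
schematic 2-D head coordinates (top view, nose up, unit head radius) — good
enough to define smooth scalp weighting profiles for simulated components; they
are not digitized electrode positions.
"""

from __future__ import annotations

import numpy as np

#: Channel order is fixed and used everywhere (data arrays, feature layouts).
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8",
    "FC5", "FC6", "FC1", "FC2", "T7", "T8",
    "C3", "C4", "Cz", "CP1", "CP2", "CP5", "CP6",
    "TP9", "TP10", "P3", "P4", "P7", "P8", "Pz",
    "PO9", "PO10", "O1", "O2", "Oz",
)

N_CHANNELS = len(CHANNELS)

# Schematic (x, y): x positive toward the right ear, y positive toward nasion.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.56), "Fz": (0.0, 0.50),
    "F4": (0.43, 0.56), "F8": (0.81, 0.59),
    "FC5": (-0.60, 0.28), "FC1": (-0.22, 0.26),
    "FC2": (0.22, 0.26), "FC6": (0.60, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "TP9": (-1.05, -0.36), "CP5": (-0.60, -0.28), "CP1": (-0.22, -0.26),
    "CP2": (0.22, -0.26), "CP6": (0.60, -0.28), "TP10": (1.05, -0.36),
    "P7": (-0.81, -0.59), "P3": (-0.43, -0.56), "Pz": (0.0, -0.50),
    "P4": (0.43, -0.56), "P8": (0.81, -0.59),
    "PO9": (-0.55, -0.93), "O1": (-0.31, -0.95), "Oz": (0.0, -1.0),
    "O2": (0.31, -0.95), "PO10": (0.55, -0.93),
}


def channel_index(name: str) -> int:
    """Index of *name* in the canonical channel order."""
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}") from None


def positions(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """(n_channels, 2) schematic coordinates."""
    return np.array([_POSITIONS[ch] for ch in channels], dtype=float)


def gaussian_profile(
    center: str | tuple[float, float],
    sigma: float = 0.4,
    reference: str | None = None,
    channels: tuple[str, ...] = CHANNELS,
) -> np.ndarray:
    """Smooth scalp weighting decaying with distance from *center*.

    Parameters
    ----------
    center
        Channel name or (x, y) coordinate of the field maximum.
    sigma
        Spatial decay scale in head-radius units.
    reference
        Channel at which the profile is normalized to exactly 1 (the electrode
        whose amplitude a template specifies). Defaults to the nearest channel
        to *center*. Values are clipped to [0, 1].
    """
    pos = positions(channels)
    if isinstance(center, str):
        cxy = np.asarray(_POSITIONS[center], dtype=float)
    else:
        cxy = np.asarray(center, dtype=float)
    d2 = np.sum((pos - cxy) ** 2, axis=1)
    prof = np.exp(-d2 / (2.0 * sigma**2))
    if reference is None:
        ref_val = prof.max()
    else:
        ref_val = prof[channels.index(reference)]
    if ref_val <= 0:
        raise ValueError("reference channel has zero weight under this profile")
    return np.clip(prof / ref_val, 0.0, 1.0)
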