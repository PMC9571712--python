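"""Default sensor layouts.

The EEG montage is a 30-channel 10-20 subset stored as 2-D projected
coordinates on a unit head circle (x to the right, y toward the nasion).
The 36-channel fNIRS layout covers frontal, central and parieto-occipital
strips and includes the right-frontal AF8 and posterior PPOz positions.
Coordinates are a documented schematic approximation, adequate for
inverse-distance topographic interpolation; they are not an optode-geometry
forward model.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EEG_MONTAGE_30",
    "FNIRS_MONTAGE_36",
    "DEFAULT_EEG_CHANNELS",
    "DEFAULT_EEG_CHANNELS_28",
    "DEFAULT_FNIRS_CHANNELS",
    "montage_array",
]

EEG_MONTAGE_30 = {
    "Fp1": (-0.31, 0.90), "Fp2": (0.31, 0.90),
    "AFz": (0.00, 0.80),
    "F7": (-0.73, 0.54), "F3": (-0.45, 0.55), "F1": (-0.22, 0.56),
    "F2": (0.22, 0.56), "F4": (0.45, 0.55), "F8": (0.73, 0.54),
    "FC5": (-0.59, 0.28), "FC1": (-0.22, 0.29),
    "FC2": (0.22, 0.29), "FC6": (0.59, 0.28),
    "T7": (-0.95, 0.00), "C3": (-0.48, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.48, 0.00), "T8": (0.95, 0.00),
    "CP5": (-0.59, -0.28), "CP1": (-0.22, -0.29),
    "CP2": (0.22, -0.29), "CP6": (0.59, -0.28),
    "P7": (-0.73, -0.54), "P3": (-0.45, -0.55), "Pz": (0.00, -0.57),
    "P4": (0.45, -0.55), "P8": (0.73, -0.54),
    "POz": (0.00, -0.80), "O1": (-0.31, -0.90), "O2": (0.31, -0.90),
}

DEFAULT_EEG_CHANNELS = list(EEG_MONTAGE_30)

# 28-channel set used for feature accounting (temporal T7/T8 dropped).
DEFAULT_EEG_CHANNELS_28 = [c for c in DEFAULT_EEG_CHANNELS if c not in ("T7", "T8")]

# frontal strip (16), central strip (8), parieto-occipital strip (12)
_FNIRS_ROWS = [
    (["AF7", "AF5", "AF3", "AF1", "AFz'", "AF2", "AF4", "AF6", "AF8"], 0.78),
    (["AFp5", "AFp3", "AFp1", "AFpz", "AFp2", "AFp4", "AFp6"], 0.88),
    (["FCC5", "FCC3", "FCC1", "FCC2", "FCC4", "FCC6"], 0.15),
    (["CCP3", "CCP4"], -0.15),
    (["PPO5", "PPO3", "PPO1", "PPOz", "PPO2", "PPO4", "PPO6"], -0.68),
    (["POO3", "POO1", "POOz", "POO2", "POO4"], -0.85),
]


def _spread(labels, y):
    n = len(labels)
    xs = np.linspace(-0.75, 0.75, n) if n > 1 else [0.0]
    return {lab: (float(x), y) for lab, x in zip(labels, xs)}


FNIRS_MONTAGE_36: dict = {}
for _labels, _y in _FNIRS_ROWS:
    FNIRS_MONTAGE_36.update(_spread(_labels, _y))

DEFAULT_FNIRS_CHANNELS = list(FNIRS_MONTAGE_36)
assert len(DEFAULT_FNIRS_CHANNELS) == 36


def montage_array(channels, montage=None) -> np.ndarray:
    """Return (n, 2) coordinates for ``channels`` from a montage dict."""
    if montage is None:
        montage = {**EEG_MONTAGE_30, **FNIRS_MONTAGE_36}
    return np.array([montage[c] for c in channels], dtype=float)
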