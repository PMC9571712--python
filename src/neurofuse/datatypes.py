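"""Core containers shared across the pipeline.

A :class:`Recording` is a channels x samples matrix with a sampling rate,
modality tag, channel labels and 2-D montage coordinates.  Windowed slices
of a recording tied to a task are :class:`Segment` objects.  Feature
extraction produces a :class:`FeatureMatrix` whose columns are described by
:class:`FeatureDescriptor` records; connectivity estimators fill a
:class:`ConnectivityMatrix`.  Cross-validation results are reported in a
:class:`CVReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Segment",
    "BandSpec",
    "BANDS",
    "FeatureDescriptor",
    "FeatureMatrix",
    "ConnectivityMatrix",
    "ConfusionCounts",
    "CVReport",
    "ScalarMap",
    "SweepCurve",
    "validate_events",
    "LOAD_RANK",
]

#: Canonical task labels in increasing workload order.
LOAD_RANK = {"0-back": 0, "2-back": 1, "3-back": 2}

EVENT_COLUMNS = ["participant", "session", "series", "label", "onset_s", "duration_s"]


@dataclass
class BandSpec:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band edges: {self.low}..{self.high}")

    def check_rate(self, rate: float) -> None:
        if self.high >= rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz is at or above "
                f"Nyquist ({rate / 2} Hz)"
            )


#: EEG analysis bands: delta 0.5-4 Hz, theta 4-7 Hz, alpha 8-15 Hz.
BANDS = {
    "delta": BandSpec("delta", 0.5, 4.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 15.0),
}


@dataclass
class Recording:
    """Multichannel time series.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples).  Units are uV for EEG,
        mmol/L-scale concentration change for HbO/HbR, and optical density
        for raw fNIRS.
    rate
        Sampling rate in Hz.
    modality
        One of ``eeg``, ``hbo``, ``hbr``, ``od``.
    channels
        One label per row, unique.
    montage_xy
        Optional (n_channels, 2) projected sensor positions.
    """

    data: np.ndarray
    rate: float
    modality: str
    channels: Sequence[str]
    montage_xy: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("one channel label per data row required")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data must be finite")
        if self.montage_xy is not None:
            self.montage_xy = np.asarray(self.montage_xy, dtype=float)
            if self.montage_xy.shape != (self.data.shape[0], 2):
                raise ValueError("montage_xy must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        return list(self.channels).index(label)


@dataclass
class Segment:
    """A windowed slice of a recording tied to one task.

    ``start`` is the window start in seconds relative to the task onset
    (0 = start of the 40 s task period; negative values reach into the
    instruction/rest preceding it).  ``recording`` keeps a reference to the
    parent so baseline intervals outside the window remain accessible.
    """

    data: np.ndarray
    rate: float
    channels: Sequence[str]
    start: float
    length: float
    label: str
    participant: int
    session: int
    series: int
    task_onset: float = 0.0
    recording: Optional[Recording] = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True, order=True)
class FeatureDescriptor:
    """Identity of one feature-matrix column.

    The field order defines the deterministic column sort:
    modality, band, channel (or pair), window, estimator.
    """

    modality: str  # eeg-psd | eeg-fbc | fnirs-hbo | fnirs-hbr
    band: str = ""
    channel: Tuple[str, ...] = ()
    window: str = ""
    estimator: str = ""

    def __post_init__(self) -> None:
        if len(self.channel) == 2 and self.channel[0] == self.channel[1]:
            raise ValueError("pair descriptor must reference two distinct channels")


@dataclass
class FeatureMatrix:
    """Samples x features with per-column descriptors and per-row labels."""

    values: np.ndarray
    descriptors: Sequence[FeatureDescriptor]
    labels: np.ndarray
    provenance: pd.DataFrame  # participant/session/series per row

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("column count must equal descriptor count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("row count must equal label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            self.values[:, idx],
            [self.descriptors[i] for i in idx],
            self.labels,
            self.provenance,
        )

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[mask],
            list(self.descriptors),
            self.labels[mask],
            self.provenance.loc[mask].reset_index(drop=True),
        )


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels estimator output for one band."""

    values: np.ndarray
    estimator: str
    band: str
    channels: Sequence[str]
    window: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square over channels")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CVReport:
    """Cross-validation outcome for one binary task.

    ``accuracy`` is the mean of the per-fold accuracies, in percent.
    ROC points are (FPR, TPR) pairs from pooled decision scores.
    """

    fold_accuracies: np.ndarray
    confusion: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray
    auc: float
    classifier: str
    seed: int
    positive_label: str = ""


@dataclass
class ScalarMap:
    """One scalar per channel, with montage positions for rendering."""

    channels: Sequence[str]
    values: np.ndarray
    montage_xy: np.ndarray
    semantics: str = "feature-mean"  # or "accuracy-%"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.channels):
            raise ValueError("one value per channel required")


@dataclass
class SweepCurve:
    """Accuracy against window start or window length."""

    abscissa: np.ndarray
    accuracy: np.ndarray  # percent
    spread: np.ndarray  # per-point fold standard deviation
    modality: str
    task_pair: Tuple[str, str]
    mode: str = "position"  # or "size"

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if self.abscissa.shape != self.accuracy.shape:
            raise ValueError("one accuracy per abscissa point required")
        if np.any((self.accuracy < 0) | (self.accuracy > 100)):
            raise ValueError("accuracies must lie in [0, 100] percent")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table contract and return the frame unchanged.

    One row per task with participant/session/series identifiers; onsets
    strictly increasing within each (participant, session).
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    bad = set(events["label"]) - set(LOAD_RANK)
    if bad:
        raise ValueError(f"unknown task labels: {sorted(bad)}")
    for (_, _), grp in events.groupby(["participant", "session"]):
        onsets = grp["onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("task onsets must be strictly increasing per session")
    return events
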