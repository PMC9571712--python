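"""Per-task feature extraction tying recordings + events to feature matrices.

Samples are tasks: each task contributes one row.  EEG features come from a
single window per task (default the whole 40 s task period): band power per
channel and the four connectivity estimators per channel pair, all in three
bands.  fNIRS features are baseline-corrected window means, one column per
(indicator, channel, window start) over a configurable list of window
starts, following the sliding-window design where window positions are
feature columns, not extra samples.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import BANDS, BandSpec, FeatureDescriptor, FeatureMatrix, Recording
from .features import (
    ESTIMATORS,
    assemble,
    band_power,
    connectivity_matrix,
    fnirs_window_feature,
    window_id,
)
from .preprocess import sliding_segments

__all__ = [
    "DEFAULT_FNIRS_STARTS",
    "eeg_task_blocks",
    "fnirs_task_blocks",
    "fnirs_window_means",
    "extract_session_features",
    "extract_cohort_features",
    "binary_subset",
]

#: Default fNIRS window starts (s relative to task onset): ten 5 s windows
#: straddling the hemodynamic peak.
DEFAULT_FNIRS_STARTS = tuple(float(s) for s in range(2, 12))


def eeg_task_blocks(eeg: Recording, events: pd.DataFrame,
                    win_len: float = 40.0, win_start: float = 0.0,
                    bands: Optional[Dict[str, BandSpec]] = None,
                    estimators: Sequence[str] = ("psd",) + ESTIMATORS,
                    ) -> List[Tuple[np.ndarray, List[FeatureDescriptor]]]:
    """Per-task EEG feature blocks (PSD and/or connectivity)."""
    bands = bands or BANDS
    segs = sliding_segments(eeg, events, win_len, step=1.0,
                            offset_range=(win_start, win_start))
    chans = list(eeg.channels)
    pairs = [(a, b) for i, a in enumerate(chans) for b in chans[i + 1:]]
    blocks: List[Tuple[np.ndarray, List[FeatureDescriptor]]] = []

    if "psd" in estimators:
        rows = [np.concatenate([band_power(s.data, s.rate, band)
                                for band in bands.values()]) for s in segs]
        descs = [FeatureDescriptor("eeg-psd", band.name, (ch,), "", "psd")
                 for band in bands.values() for ch in chans]
        blocks.append((np.vstack(rows), descs))

    fbc = [e for e in estimators if e in ESTIMATORS]
    if fbc:
        iu = np.triu_indices(len(chans), k=1)
        rows = []
        for s in segs:
            parts = []
            for band in bands.values():
                for est in fbc:
                    cm = connectivity_matrix(s, est, band)
                    parts.append(cm.values[iu])
            rows.append(np.concatenate(parts))
        descs = [FeatureDescriptor("eeg-fbc", band.name, pair, "", est)
                 for band in bands.values() for est in fbc for pair in pairs]
        blocks.append((np.vstack(rows), descs))
    return blocks


def fnirs_window_means(rec: Recording, events: pd.DataFrame,
                       starts: Sequence[float], win_len: float = 5.0,
                       baseline: Tuple[float, float] = (-5.0, 0.0)
                       ) -> np.ndarray:
    """Baseline-corrected window means: (n_tasks, n_channels, n_starts)."""
    out = np.empty((len(events), rec.n_channels, len(starts)))
    for j, start in enumerate(starts):
        segs = sliding_segments(rec, events, win_len, step=1.0,
                                offset_range=(start, start),
                                baseline_interval=baseline)
        if len(segs) != len(events):
            raise ValueError(f"window start {start} s does not fit every task")
        out[:, :, j] = np.vstack([fnirs_window_feature(s) for s in segs])
    return out


def fnirs_task_blocks(hbo: Optional[Recording], hbr: Optional[Recording],
                      events: pd.DataFrame,
                      starts: Sequence[float] = DEFAULT_FNIRS_STARTS,
                      win_len: float = 5.0,
                      baseline: Tuple[float, float] = (-5.0, 0.0),
                      ) -> List[Tuple[np.ndarray, List[FeatureDescriptor]]]:
    """Per-task fNIRS feature blocks, one column per (indicator, channel, window)."""
    blocks = []
    for modality, rec in (("fnirs-hbo", hbo), ("fnirs-hbr", hbr)):
        if rec is None:
            continue
        means = fnirs_window_means(rec, events, starts, win_len, baseline)
        n_tasks = means.shape[0]
        descs = [FeatureDescriptor(modality, "", (ch,), window_id(st), "mean")
                 for ch in rec.channels for st in starts]
        blocks.append((means.reshape(n_tasks, -1), descs))
    return blocks


def extract_session_features(eeg: Optional[Recording], hbo: Optional[Recording],
                             hbr: Optional[Recording], events: pd.DataFrame,
                             eeg_win_len: float = 40.0,
                             eeg_estimators: Sequence[str] = ("psd",) + ESTIMATORS,
                             fnirs_starts: Sequence[float] = DEFAULT_FNIRS_STARTS,
                             fnirs_win_len: float = 5.0,
                             bands: Optional[Dict[str, BandSpec]] = None,
                             ) -> FeatureMatrix:
    """Assemble the hybrid feature matrix for one session (rows = tasks)."""
    blocks = []
    if eeg is not None:
        blocks += eeg_task_blocks(eeg, events, eeg_win_len,
                                  bands=bands, estimators=eeg_estimators)
    if hbo is not None or hbr is not None:
        blocks += fnirs_task_blocks(hbo, hbr, events, fnirs_starts, fnirs_win_len)
    prov = events[["participant", "session", "series"]].reset_index(drop=True)
    return assemble(blocks, events["label"].to_numpy(), prov)


def extract_cohort_features(sessions: Iterable[Tuple], **kwargs) -> FeatureMatrix:
    """Concatenate per-session feature matrices over a cohort.

    ``sessions`` yields (eeg, hbo, hbr, events) tuples; see
    :meth:`neurofuse.simulate.SimulatedDataset.session`.
    """
    mats = [extract_session_features(e, o, r, ev, **kwargs)
            for e, o, r, ev in sessions]
    first = mats[0]
    for m in mats[1:]:
        if list(m.descriptors) != list(first.descriptors):
            raise ValueError("sessions produced inconsistent feature columns")
    return FeatureMatrix(
        np.vstack([m.values for m in mats]),
        list(first.descriptors),
        np.concatenate([m.labels for m in mats]),
        pd.concat([m.provenance for m in mats], ignore_index=True),
    )


def binary_subset(fm: FeatureMatrix, task_pair: Tuple[str, str]) -> FeatureMatrix:
    """Rows whose label is one of the two tasks."""
    mask = np.isin(fm.labels, list(task_pair))
    if mask.sum() == 0:
        raise ValueError(f"no samples with labels {task_pair}")
    return fm.select_rows(mask)
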