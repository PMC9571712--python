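"""Window-position and window-size sensitivity analyses.

Both sweeps repeat the standard pipeline — extract features, ANOVA top-k
selection, per-participant normalisation, stratified SVM cross-validation —
while moving one windowing parameter.  Window starts are reported relative
to the task-block onset (instruction start); the task period itself begins
``block_offset`` seconds later.  Points are evaluated independently, so a
sweep is order-independent for a fixed seed.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import crossval, normalize_per_participant
from .datatypes import FeatureDescriptor, FeatureMatrix, SweepCurve
from .features import window_id
from .pipeline import binary_subset, extract_cohort_features, fnirs_window_means
from .select_fuse import select_top_k

__all__ = ["position_sweep", "size_sweep"]

Session = Tuple  # (eeg, hbo, hbr, events)


def _fnirs_start_matrix(sessions: Sequence[Session], starts: np.ndarray,
                        win_len: float) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack per-task window means over the cohort.

    Returns (values, labels, provenance) where values has shape
    (n_tasks, n_indicators * n_channels, n_starts).
    """
    vals, labels, prov = [], [], []
    for _eeg, hbo, hbr, events in sessions:
        per_ind = [fnirs_window_means(rec, events, starts, win_len)
                   for rec in (hbo, hbr) if rec is not None]
        vals.append(np.concatenate(per_ind, axis=1))
        labels.append(events["label"].to_numpy())
        prov.append(events[["participant", "session", "series"]])
    return (np.vstack(vals), np.concatenate(labels),
            pd.concat(prov, ignore_index=True))


def _window_accuracy(values: np.ndarray, labels: np.ndarray,
                     prov: pd.DataFrame, task_pair, k_features: int,
                     classifier: str, seed: int) -> Tuple[float, float]:
    """Selection + CV accuracy for one windowed feature block."""
    descs = [FeatureDescriptor("fnirs", "", (f"ch{i}",), "", "mean")
             for i in range(values.shape[1])]
    fm = FeatureMatrix(values, descs, labels, prov)
    fm = binary_subset(fm, task_pair)
    fm = normalize_per_participant(fm)
    k = min(k_features, fm.n_features)
    sel = select_top_k(fm, fm.labels, k)
    report = crossval(fm.select_columns(sel.indices), classifier=classifier,
                      seed=seed)
    return report.accuracy, float(report.fold_accuracies.std() * 100.0)


def position_sweep(sessions: Sequence[Session], win_len: float = 5.0,
                   step: float = 1.0,
                   task_pair: Tuple[str, str] = ("0-back", "3-back"),
                   k_features: int = 10, classifier: str = "svm-rbf",
                   seed: int = 0, block_offset: float = 2.0,
                   timeline: float = 63.0,
                   n_top: int = 10) -> Tuple[SweepCurve, np.ndarray]:
    """fNIRS accuracy against the 5 s window start over the task block.

    Window starts run from 0 to ``timeline - win_len`` in steps of ``step``,
    relative to the block onset.  Returns the accuracy curve and the
    ``n_top`` best starts (sorted by accuracy, earlier start on ties).
    """
    starts_block = np.arange(0.0, timeline - win_len + 1e-9, step)
    if starts_block.size == 0:
        raise ValueError("no valid windows for this timeline")
    starts_task = starts_block - block_offset  # relative to task onset
    values, labels, prov = _fnirs_start_matrix(sessions, starts_task, win_len)
    acc = np.empty(starts_block.size)
    spread = np.empty(starts_block.size)
    for j in range(starts_block.size):
        acc[j], spread[j] = _window_accuracy(values[:, :, j], labels, prov,
                                             task_pair, k_features,
                                             classifier, seed)
    curve = SweepCurve(starts_block, acc, spread, "fnirs", tuple(task_pair),
                       mode="position")
    order = sorted(range(starts_block.size), key=lambda j: (-acc[j], starts_block[j]))
    top_starts = starts_block[order[:n_top]]
    return curve, top_starts


def size_sweep(sessions: Sequence[Session], sizes: Sequence[float],
               modality: str,
               task_pair: Tuple[str, str] = ("0-back", "3-back"),
               k_features: int = 10, classifier: str = "svm-rbf",
               seed: int = 0, block_offset: float = 2.0,
               task_duration: float = 40.0, timeline: float = 63.0,
               position_step: float = 2.0,
               eeg_estimators: Sequence[str] = ("psd",)) -> SweepCurve:
    """Accuracy against window length for one modality.

    Every size must fit inside the task period.  For fNIRS each size is
    scored at its best window position over the block (coarse grid of
    ``position_step``), mirroring the position-optimisation step of the
    original procedure; EEG windows are anchored at the task onset, where
    the planted oscillatory effects are stationary.
    """
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes > task_duration):
        raise ValueError("window size exceeds the task duration")
    if np.any(sizes <= 0):
        raise ValueError("window sizes must be positive")
    acc = np.empty(sizes.size)
    spread = np.empty(sizes.size)

    if modality == "fnirs":
        for i, size in enumerate(sizes):
            starts_block = np.arange(0.0, timeline - size + 1e-9, position_step)
            starts_task = starts_block - block_offset
            values, labels, prov = _fnirs_start_matrix(sessions, starts_task, size)
            results = [
                _window_accuracy(values[:, :, j], labels, prov, task_pair,
                                 k_features, classifier, seed)
                for j in range(starts_block.size)
            ]
            best = max(range(len(results)), key=lambda j: results[j][0])
            acc[i], spread[i] = results[best]
    elif modality == "eeg":
        for i, size in enumerate(sizes):
            fm = extract_cohort_features(
                ((eeg, None, None, ev) for eeg, _hbo, _hbr, ev in sessions),
                eeg_win_len=float(size), eeg_estimators=eeg_estimators,
            )
            fm = binary_subset(fm, task_pair)
            fm = normalize_per_participant(fm)
            k = min(k_features, fm.n_features)
            sel = select_top_k(fm, fm.labels, k)
            report = crossval(fm.select_columns(sel.indices),
                              classifier=classifier, seed=seed)
            acc[i] = report.accuracy
            spread[i] = float(report.fold_accuracies.std() * 100.0)
    else:
        raise ValueError(f"unknown modality {modality!r}")

    return SweepCurve(sizes, acc, spread, modality, tuple(task_pair), mode="size")
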