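"""Filtering, resampling, mBLL conversion, baselining and segmentation.

All filtering is zero-phase (forward-backward) so that downstream phase
estimates (PLV) are not biased by filter group delay.  Time coordinates are
seconds with 0 at the session onset; windows are half-open
``[start, start + length)``.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .datatypes import Recording, Segment, validate_events

__all__ = [
    "butter_sos",
    "butter_filter",
    "filter_array",
    "resample",
    "mbll",
    "DEFAULT_EXTINCTION",
    "DEFAULT_DPF",
    "baseline_correct",
    "sliding_segments",
    "remove_ocular_artifacts",
]

log = logging.getLogger(__name__)

# Extinction coefficients [1/(cm * mM)] at (760, 850) nm for (HbO, HbR),
# from standard published tables; rows = wavelengths, columns = (HbO, HbR).
DEFAULT_EXTINCTION = np.array([[0.5864, 1.5485],
                               [1.0580, 0.6916]])
DEFAULT_DPF = (6.0, 6.0)


def butter_sos(kind: str, edges, order: int, rate: float):
    """Design a Butterworth filter in second-order sections.

    ``kind`` is ``lowpass`` or ``bandpass``; ``edges`` one cutoff or a
    (low, high) pair, in Hz, strictly below Nyquist.
    """
    if order < 1:
        raise ValueError("filter order must be >= 1")
    nyq = rate / 2.0
    edges_arr = np.atleast_1d(np.asarray(edges, dtype=float))
    if np.any(edges_arr <= 0) or np.any(edges_arr >= nyq):
        raise ValueError(f"filter edges {edges} must lie in (0, {nyq}) Hz")
    if kind == "lowpass":
        if edges_arr.size != 1:
            raise ValueError("lowpass takes a single cutoff")
        wn = edges_arr[0]
    elif kind == "bandpass":
        if edges_arr.size != 2 or edges_arr[0] >= edges_arr[1]:
            raise ValueError("bandpass takes an increasing (low, high) pair")
        wn = edges_arr
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return signal.butter(order, wn, btype=kind, fs=rate, output="sos")


def filter_array(data: np.ndarray, kind: str, edges, order: int,
                 rate: float) -> np.ndarray:
    """Zero-phase Butterworth filtering along the last axis.

    Initial conditions follow Gustafsson's method, which makes the
    forward-backward pass exactly symmetric under time reversal (padding
    heuristics are not).
    """
    butter_sos(kind, edges, order, rate)  # shared edge/order validation
    edges_arr = np.atleast_1d(np.asarray(edges, dtype=float))
    b, a = signal.butter(order, edges_arr if kind == "bandpass" else edges_arr[0],
                         btype=kind, fs=rate)
    return signal.filtfilt(b, a, data, axis=-1, method="gust")


def butter_filter(rec: Recording, kind: str, edges, order: int = 3) -> Recording:
    """Zero-phase Butterworth filter applied to a whole recording."""
    out = filter_array(rec.data, kind, edges, order, rec.rate)
    return Recording(out, rec.rate, rec.modality, list(rec.channels), rec.montage_xy)


def resample(rec: Recording, target: float) -> Recording:
    """Polyphase resampling (anti-aliasing built in) to ``target`` Hz."""
    if target <= 0:
        raise ValueError("target rate must be positive")
    if np.isclose(target, rec.rate):
        return Recording(rec.data.copy(), rec.rate, rec.modality,
                         list(rec.channels), rec.montage_xy)
    frac = Fraction(target / rec.rate).limit_denominator(10000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return Recording(out, target, rec.modality, list(rec.channels), rec.montage_xy)


def mbll(od_wl1: Recording, od_wl2: Recording,
         extinction: np.ndarray = DEFAULT_EXTINCTION,
         distance_cm: float = 3.0,
         dpf: Sequence[float] = DEFAULT_DPF) -> Tuple[Recording, Recording]:
    """Modified Beer-Lambert conversion of optical density to (HbO, HbR).

    Per channel and sample the 2x2 system

        dOD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d * DPF_lambda

    is solved by the matrix inverse.  ``extinction`` rows are wavelengths,
    columns (HbO, HbR), in 1/(cm*mM); ``distance_cm`` the source-detector
    separation; ``dpf`` the per-wavelength differential pathlength factor.
    """
    if distance_cm <= 0 or any(d <= 0 for d in dpf):
        raise ValueError("distance and DPF must be positive")
    ext = np.asarray(extinction, dtype=float)
    if ext.shape != (2, 2):
        raise ValueError("extinction must be a 2x2 matrix")
    if od_wl1.data.shape != od_wl2.data.shape:
        raise ValueError("both wavelengths must have the same shape")
    # effective pathlength-scaled system matrix
    A = ext * (distance_cm * np.asarray(dpf, dtype=float)[:, None])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if np.isclose(det, 0.0):
        raise ValueError("singular extinction matrix")
    Ainv = np.linalg.inv(A)
    od = np.stack([od_wl1.data, od_wl2.data])  # (2, ch, n)
    conc = np.einsum("ij,jcn->icn", Ainv, od)
    hbo = Recording(conc[0], od_wl1.rate, "hbo", list(od_wl1.channels), od_wl1.montage_xy)
    hbr = Recording(conc[1], od_wl1.rate, "hbr", list(od_wl1.channels), od_wl1.montage_xy)
    return hbo, hbr


def baseline_correct(seg: Segment,
                     baseline_interval: Tuple[float, float] = (-5.0, 0.0)) -> Segment:
    """Subtract each channel's median over a pre-stimulus baseline.

    ``baseline_interval`` is (start, stop) in seconds relative to the task
    onset and must lie inside the parent recording.
    """
    if seg.recording is None:
        raise ValueError("segment has no parent recording for baselining")
    b0, b1 = baseline_interval
    if b1 <= b0:
        raise ValueError("empty baseline interval")
    rate = seg.rate
    i0 = round((seg.task_onset + b0) * rate)
    i1 = round((seg.task_onset + b1) * rate)
    if i0 < 0 or i1 > seg.recording.n_samples or i1 <= i0:
        raise ValueError("baseline interval outside the recording")
    med = np.median(seg.recording.data[:, i0:i1], axis=1, keepdims=True)
    return Segment(seg.data - med, seg.rate, list(seg.channels), seg.start,
                   seg.length, seg.label, seg.participant, seg.session,
                   seg.series, seg.task_onset, seg.recording)


def sliding_segments(rec: Recording, events: pd.DataFrame, win_len: float,
                     step: float = 1.0,
                     offset_range: Tuple[float, float] = (0.0, 0.0),
                     baseline_interval: Optional[Tuple[float, float]] = None
                     ) -> List[Segment]:
    """One segment per (task, window start).

    Window starts run from ``offset_range[0]`` to ``offset_range[1]``
    inclusive, spaced by ``step``, in seconds relative to each task onset.
    Windows that would overrun the recording end are skipped with a logged
    warning.  If ``baseline_interval`` is given, each segment is median
    baseline corrected.
    """
    if win_len <= 0 or step <= 0:
        raise ValueError("window length and step must be positive")
    validate_events(events)
    lo, hi = offset_range
    if hi < lo:
        raise ValueError("offset_range must be non-decreasing")
    n_starts = int(np.floor((hi - lo) / step + 1e-9)) + 1
    starts = lo + step * np.arange(n_starts)
    rate = rec.rate
    out: List[Segment] = []
    for row in events.itertuples():
        for start in starts:
            i0 = round((row.onset_s + start) * rate)
            i1 = i0 + round(win_len * rate)
            if i0 < 0 or i1 > rec.n_samples:
                log.warning("window at offset %.1f s for task onset %.1f s "
                            "exceeds the recording; skipped", start, row.onset_s)
                continue
            seg = Segment(rec.data[:, i0:i1], rate, list(rec.channels),
                          float(start), win_len, row.label, row.participant,
                          row.session, row.series, row.onset_s, rec)
            if baseline_interval is not None:
                seg = baseline_correct(seg, baseline_interval)
            out.append(seg)
    if not out:
        raise ValueError("no valid windows")
    return out


def remove_ocular_artifacts(rec: Recording, method: str = "none") -> Recording:
    """Optional ocular-artifact stage.

    Only the pass-through ``"none"`` method is provided; the hook exists so
    a blind-source-separation cleaner can be slotted in front of feature
    extraction without changing the pipeline surface.
    """
    if method != "none":
        raise NotImplementedError(f"artifact method {method!r} not available")
    return rec
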