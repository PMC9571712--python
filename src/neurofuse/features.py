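"""Band power, functional-connectivity estimators, and feature assembly.

Four bivariate coupling estimators are provided, mirroring the usual
taxonomy: Pearson correlation (linear, time domain), magnitude-squared
coherence (linear, frequency domain), mutual information (nonlinear, time
domain) and phase-locking value (nonlinear, frequency domain).  Scalar
pairwise functions (:func:`pcc`, :func:`msc`, :func:`mutual_information`,
:func:`plv`) define the semantics; :func:`connectivity_matrix` evaluates
the same quantities for every unordered channel pair of a segment through
vectorised paths that agree with the pairwise functions to rounding error.

Spectral choices: Welch with periodic Hann windows, per-frame constant
detrend, 50% overlap.  MI uses equal-width plug-in histograms (default
``ceil(sqrt(N))`` bins capped at 32, log base 2), with ``0 log 0 == 0``.
PLV phases come from the analytic (Hilbert) signal with 10% of samples
trimmed from each edge to suppress end effects.  MI, PCC and PLV operate
on band-filtered series so that per-band features are well defined; MSC
averages coherence over the in-band frequency bins of the raw segment.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import (
    BandSpec,
    ConnectivityMatrix,
    FeatureDescriptor,
    FeatureMatrix,
    Segment,
)
from .preprocess import filter_array

__all__ = [
    "band_power",
    "pcc",
    "msc",
    "mutual_information",
    "mi_entropy_terms",
    "plv",
    "connectivity_matrix",
    "fnirs_window_feature",
    "assemble",
    "window_id",
    "ESTIMATORS",
]

ESTIMATORS = ("pcc", "msc", "mi", "plv")


# ---------------------------------------------------------------------------
# univariate spectral power

def band_power(data: np.ndarray, rate: float, band: BandSpec) -> np.ndarray:
    """Welch PSD integrated over ``[band.low, band.high]``, per channel.

    ``data`` is (n_channels, n_samples) or (n_samples,).  The window must
    span at least two cycles of ``band.low``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[-1]
    if n / rate < 2.0 / band.low:
        raise ValueError(
            f"window of {n / rate:.2f} s too short for band {band.name} "
            f"(need >= {2.0 / band.low:.2f} s)"
        )
    band.check_rate(rate)
    nperseg = min(int(2 * rate), n)
    freqs, psd = sps.welch(data, fs=rate, nperseg=nperseg, axis=-1)
    mask = (freqs >= band.low) & (freqs <= band.high)
    if mask.sum() < 2:
        raise ValueError(f"band {band.name} covers fewer than 2 frequency bins")
    return np.trapezoid(psd[..., mask], freqs[mask], axis=-1)


# ---------------------------------------------------------------------------
# pairwise estimators

def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input series")
    return x


def pcc(x, y) -> float:
    """Sample Pearson correlation coefficient, in [-1, 1]."""
    x, y = _as_series(x), _as_series(y)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(x, y)[0, 1])


def _welch_frames(data: np.ndarray, nperseg: int) -> np.ndarray:
    """Hann-windowed, constant-detrended rFFT frames at 50% overlap.

    Returns (..., n_frames, n_freqs) complex spectra; the common scaling
    factor is omitted because it cancels in coherence ratios.
    """
    step = nperseg - nperseg // 2
    n = data.shape[-1]
    if n < nperseg:
        raise ValueError("series shorter than one Welch segment")
    n_frames = 1 + (n - nperseg) // step
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_frames)[:, None]
    frames = data[..., idx]
    frames = frames - frames.mean(axis=-1, keepdims=True)
    win = sps.get_window("hann", nperseg)
    return np.fft.rfft(frames * win, axis=-1)


def _coherence_spectrum(data: np.ndarray, rate: float, n_segments: int
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """All-pairs magnitude-squared coherence.

    Returns (freqs, C) with C of shape (n_ch, n_ch, n_freqs).
    """
    if n_segments < 2:
        raise ValueError("coherence needs >= 2 Welch segments "
                         "(single-segment coherence is identically 1)")
    n = data.shape[-1]
    nperseg = max(int(2 * n / (n_segments + 1)), 2)
    Z = _welch_frames(data, nperseg)  # (ch, frames, freq)
    S = np.einsum("afk,bfk->abk", Z, np.conj(Z)) / Z.shape[-2]
    auto = np.real(np.einsum("aak->ak", S))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(S) ** 2 / denom
    C = np.nan_to_num(C, nan=0.0)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / rate)
    return freqs, np.clip(C, 0.0, 1.0)


def msc(x, y, rate: float, band: BandSpec, n_segments: int = 8) -> float:
    """Welch-averaged magnitude-squared coherence, mean over in-band bins."""
    x, y = _as_series(x), _as_series(y)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    freqs, C = _coherence_spectrum(np.stack([x, y]), rate, n_segments)
    mask = (freqs >= band.low) & (freqs <= band.high)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    return float(C[0, 1, mask].mean())


def _discretize(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin codes over the series' own range (histogram semantics)."""
    mn, mx = v.min(), v.max()
    if mx == mn:
        return np.zeros(v.size, dtype=np.intp)
    edges = np.linspace(mn, mx, n_bins + 1)
    codes = np.searchsorted(edges, v, side="right") - 1
    return np.clip(codes, 0, n_bins - 1)


def _entropy(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(base))


def default_bins(n: int) -> int:
    return min(32, max(2, math.ceil(math.sqrt(n))))


def mutual_information(x, y, n_bins: Optional[int] = None,
                       log_base: float = 2.0) -> float:
    """Plug-in mutual information from an equal-width joint histogram.

    Non-negative; zero when the joint histogram factorises.  Units are
    ``log_base`` units (bits by default).
    """
    x, y = _as_series(x), _as_series(y)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    nb = n_bins if n_bins is not None else default_bins(x.size)
    if nb < 2:
        raise ValueError("n_bins must be >= 2")
    cx, cy = _discretize(x, nb), _discretize(y, nb)
    joint = np.bincount(cx * nb + cy, minlength=nb * nb).astype(float) / x.size
    hx = _entropy(np.bincount(cx, minlength=nb).astype(float) / x.size, log_base)
    hy = _entropy(np.bincount(cy, minlength=nb).astype(float) / x.size, log_base)
    hxy = _entropy(joint, log_base)
    return max(hx + hy - hxy, 0.0)


def mi_entropy_terms(x, y, n_bins: Optional[int] = None,
                     log_base: float = 2.0) -> Dict[str, float]:
    """Entropy decomposition H(x), H(y), H(x,y), H(y|x) from the joint table.

    H(y|x) is computed independently as ``sum_x p(x) H(y | X = x)`` so the
    two MI identities can be cross-checked.
    """
    x, y = _as_series(x), _as_series(y)
    nb = n_bins if n_bins is not None else default_bins(x.size)
    cx, cy = _discretize(x, nb), _discretize(y, nb)
    joint = (np.bincount(cx * nb + cy, minlength=nb * nb)
             .reshape(nb, nb).astype(float) / x.size)
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    h_y_given_x = 0.0
    for i in range(nb):
        if px[i] > 0:
            h_y_given_x += px[i] * _entropy(joint[i] / px[i], log_base)
    return {
        "H(x)": _entropy(px, log_base),
        "H(y)": _entropy(py, log_base),
        "H(x,y)": _entropy(joint.ravel(), log_base),
        "H(y|x)": h_y_given_x,
    }


def _phases(data: np.ndarray) -> np.ndarray:
    return np.angle(sps.hilbert(data, axis=-1))


def _check_plv_length(n: int, rate: float, band: BandSpec) -> None:
    if n / rate < 3.0 / band.low:
        raise ValueError(
            f"window of {n / rate:.2f} s shorter than 3 cycles of "
            f"{band.low} Hz; PLV unreliable"
        )


def plv(x, y, rate: float, band: Optional[BandSpec] = None,
        trim: float = 0.1) -> float:
    """Phase-locking value in [0, 1].

    If ``band`` is given the series are zero-phase band-filtered first;
    otherwise they are assumed already band limited.  ``trim`` is the
    fraction of samples dropped from each edge before averaging.
    """
    x, y = _as_series(x), _as_series(y)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if band is not None:
        _check_plv_length(x.size, rate, band)
        x = filter_array(x, "bandpass", (band.low, band.high), 3, rate)
        y = filter_array(y, "bandpass", (band.low, band.high), 3, rate)
    k = int(trim * x.size)
    sl = slice(k, x.size - k if k else None)
    dphi = _phases(x)[sl] - _phases(y)[sl]
    return float(np.abs(np.exp(1j * dphi).mean()))


# ---------------------------------------------------------------------------
# whole-segment connectivity

def connectivity_matrix(seg: Segment, estimator: str, band: BandSpec,
                        n_segments: int = 8,
                        n_bins: Optional[int] = None) -> ConnectivityMatrix:
    """Estimator applied to every unordered channel pair of a segment.

    The result is symmetric.  Diagonals: 1 for PCC/MSC/PLV; per-channel
    entropy H(x) for MI.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    data = np.asarray(seg.data, dtype=float)
    n_ch, n = data.shape
    if n_ch < 2:
        raise ValueError("connectivity needs at least 2 channels")

    if estimator == "msc":
        freqs, C = _coherence_spectrum(data, seg.rate, n_segments)
        mask = (freqs >= band.low) & (freqs <= band.high)
        if not mask.any():
            raise ValueError(f"no frequency bins inside band {band.name}")
        values = C[:, :, mask].mean(axis=-1)
        values = 0.5 * (values + values.T)  # exact symmetry
        np.fill_diagonal(values, 1.0)
        return ConnectivityMatrix(values, estimator, band.name, list(seg.channels))

    filtered = filter_array(data, "bandpass", (band.low, band.high), 3, seg.rate)

    if estimator == "pcc":
        sds = filtered.std(axis=1)
        if np.any(sds == 0):
            bad = [seg.channels[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant channel(s) {bad}: correlation undefined")
        values = np.corrcoef(filtered)
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 1.0)
    elif estimator == "plv":
        _check_plv_length(n, seg.rate, band)
        k = int(0.1 * n)
        sl = slice(k, n - k if k else None)
        U = np.exp(1j * _phases(filtered)[:, sl])
        values = np.abs(U @ np.conj(U.T)) / U.shape[1]
        values = 0.5 * (values + values.T)
        np.fill_diagonal(values, 1.0)
    else:  # mi
        nb = n_bins if n_bins is not None else default_bins(n)
        codes = np.vstack([_discretize(filtered[i], nb) for i in range(n_ch)])
        marg_h = np.array([
            _entropy(np.bincount(codes[i], minlength=nb).astype(float) / n, 2.0)
            for i in range(n_ch)
        ])
        values = np.zeros((n_ch, n_ch))
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                joint = (np.bincount(codes[i] * nb + codes[j], minlength=nb * nb)
                         .astype(float) / n)
                mi_ij = max(marg_h[i] + marg_h[j] - _entropy(joint, 2.0), 0.0)
                values[i, j] = values[j, i] = mi_ij
        np.fill_diagonal(values, marg_h)

    return ConnectivityMatrix(values, estimator, band.name, list(seg.channels))


# ---------------------------------------------------------------------------
# fNIRS window feature and assembly

def fnirs_window_feature(seg: Segment) -> np.ndarray:
    """Per-channel mean of a (baseline-corrected) hemodynamic window."""
    if seg.data.shape[-1] == 0:
        raise ValueError("empty window")
    return seg.data.mean(axis=-1)


def window_id(start: float) -> str:
    """Deterministic window identifier from a start offset in seconds."""
    return f"s{start:+07.2f}"


def assemble(blocks: Sequence[Tuple[np.ndarray, Sequence[FeatureDescriptor]]],
             labels: Sequence[str],
             provenance: Optional[pd.DataFrame] = None) -> FeatureMatrix:
    """Stack feature blocks into one matrix with deterministic column order.

    Columns are sorted by descriptor: modality, band, channel(-pair),
    window, estimator (lexicographic).  Ragged blocks or duplicate
    descriptors are rejected.
    """
    if not blocks:
        raise ValueError("no feature blocks given")
    n_rows = {np.asarray(v).shape[0] for v, _ in blocks}
    if len(n_rows) != 1:
        raise ValueError(f"inconsistent sample counts across blocks: {sorted(n_rows)}")
    values_parts: List[np.ndarray] = []
    descriptors: List[FeatureDescriptor] = []
    for vals, descs in blocks:
        vals = np.atleast_2d(np.asarray(vals, dtype=float))
        if vals.shape[1] != len(descs):
            raise ValueError("block column count must match descriptor count")
        values_parts.append(vals)
        descriptors.extend(descs)
    if len(set(descriptors)) != len(descriptors):
        raise ValueError("duplicate feature descriptors")
    values = np.hstack(values_parts)
    order = sorted(range(len(descriptors)), key=lambda i: descriptors[i])
    labels = np.asarray(labels)
    if provenance is None:
        provenance = pd.DataFrame({
            "participant": np.zeros(len(labels), dtype=int),
            "session": np.zeros(len(labels), dtype=int),
            "series": np.zeros(len(labels), dtype=int),
        })
    return FeatureMatrix(values[:, order], [descriptors[i] for i in order],
                         labels, provenance.reset_index(drop=True))
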