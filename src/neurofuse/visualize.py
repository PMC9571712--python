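"""Topographic scalp maps, connectivity heat maps and accuracy maps.

The tested artifact is always a numeric grid or matrix; colour rendering is
a thin optional layer on top and never re-runs any classification.
Interpolation is inverse-distance weighting (power 2) over the 2-D montage,
masked to the convex hull of the sensors.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay

from .classify import crossval, normalize_per_participant
from .datatypes import FeatureMatrix, ScalarMap
from .pipeline import binary_subset

__all__ = ["topomap", "per_channel_accuracy", "pair_accuracy_heatmap"]


def topomap(smap: ScalarMap, grid: int = 64, power: float = 2.0
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-distance-weighted interpolation of a per-channel map.

    Returns (x, y, values) where ``values`` is a (grid, grid) array, NaN
    outside the convex hull of the sensors.  Grid points coincident with a
    sensor take that sensor's value exactly; elsewhere the IDW weights are
    convex, so interpolated values stay within [min, max] of the data.
    """
    pts = np.asarray(smap.montage_xy, dtype=float)
    vals = np.asarray(smap.values, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("topographic map needs >= 3 channels")
    if len(np.unique(pts, axis=0)) != pts.shape[0]:
        raise ValueError("duplicate channel positions")

    margin = 0.05 * max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
    x = np.linspace(pts[:, 0].min() - margin, pts[:, 0].max() + margin, grid)
    y = np.linspace(pts[:, 1].min() - margin, pts[:, 1].max() + margin, grid)
    gx, gy = np.meshgrid(x, y)
    gpts = np.column_stack([gx.ravel(), gy.ravel()])

    d = np.sqrt(((gpts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    out = np.empty(gpts.shape[0])
    exact = d.min(axis=1) < 1e-12
    out[exact] = vals[d[exact].argmin(axis=1)]
    with np.errstate(divide="ignore"):
        w = 1.0 / d[~exact] ** power
    out[~exact] = (w * vals).sum(axis=1) / w.sum(axis=1)

    inside = Delaunay(pts).find_simplex(gpts) >= 0
    out[~inside] = np.nan
    return x, y, out.reshape(grid, grid)


def _single_channel_columns(fm: FeatureMatrix, channel: str,
                            column_filter: Optional[Callable] = None):
    idx = [i for i, d in enumerate(fm.descriptors)
           if len(d.channel) == 1 and d.channel[0] == channel
           and (column_filter is None or column_filter(d))]
    return idx


def per_channel_accuracy(fm: FeatureMatrix, task_pair: Tuple[str, str],
                         channels: Sequence[str], montage_xy: np.ndarray,
                         column_filter: Optional[Callable] = None,
                         classifier: str = "svm-rbf", seed: int = 0,
                         k_folds: int = 5) -> ScalarMap:
    """CV accuracy using only each channel's feature column(s).

    ``column_filter`` restricts which descriptors count (e.g. alpha-band
    PSD only).  Raises if a channel has no matching columns.
    """
    sub = normalize_per_participant(binary_subset(fm, task_pair))
    values = np.empty(len(channels))
    for ci, ch in enumerate(channels):
        idx = _single_channel_columns(sub, ch, column_filter)
        if not idx:
            raise ValueError(f"no feature columns for channel {ch!r}")
        report = crossval(sub.select_columns(idx), classifier=classifier,
                          seed=seed, k=k_folds)
        values[ci] = report.accuracy
    return ScalarMap(list(channels), values, np.asarray(montage_xy),
                     semantics="accuracy-%")


def pair_accuracy_heatmap(fm: FeatureMatrix, task_pair: Tuple[str, str],
                          estimator: str, band: str,
                          channels: Sequence[str],
                          classifier: str = "svm-rbf", seed: int = 0,
                          k_folds: int = 5) -> np.ndarray:
    """Symmetric channels x channels CV-accuracy matrix from pair features.

    Each upper-triangle cell is the accuracy of classifying ``task_pair``
    from that single connectivity column; the diagonal is NaN.
    """
    sub = normalize_per_participant(binary_subset(fm, task_pair))
    chans = list(channels)
    n = len(chans)
    col_of = {}
    for i, d in enumerate(sub.descriptors):
        if d.estimator == estimator and d.band == band and len(d.channel) == 2:
            col_of[d.channel] = i
    out = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            key = (chans[a], chans[b])
            if key not in col_of:
                key = (chans[b], chans[a])
            if key not in col_of:
                raise ValueError(f"missing pair column for {chans[a]}:{chans[b]}")
            report = crossval(sub.select_columns([col_of[key]]),
                              classifier=classifier, seed=seed, k=k_folds)
            out[a, b] = out[b, a] = report.accuracy
    return out
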