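"""ANOVA significance ranking, top-k selection and hybrid fusion.

Features are ranked by one-way ANOVA p-value across the three workload
levels (raw p-values, no multiple-testing correction), ties broken by
larger F then lower column index.  The hybrid feature set concatenates the
top-k EEG and top-k fNIRS columns.  By default selection is performed on
the full sample set before cross-validation — the order used in the
original analysis, which is a known information-leakage risk; a fold-nested
variant is available by embedding :class:`AnovaTopKSelector` in an sklearn
pipeline inside the CV loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import FeatureDescriptor, FeatureMatrix

__all__ = ["anova_f", "f_oneway_columns", "AnovaTopKSelector",
           "SelectionResult", "select_top_k", "fuse"]


def anova_f(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classic one-way ANOVA F and p for a list of value groups.

    Zero within-group variance with unequal means yields ``(inf, 0.0)``;
    all-constant input yields ``(nan, nan)``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    X = np.concatenate(arrs)[:, None]
    y = np.concatenate([np.full(a.size, i) for i, a in enumerate(arrs)])
    F, p = f_oneway_columns(X, y)
    return float(F[0]), float(p[0])


def f_oneway_columns(X: np.ndarray, y: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Column-wise one-way ANOVA via the between/within sum-of-squares ratio.

    Returns per-column ``(F, p)`` with p from the F(g-1, n-g) distribution.
    Degenerate columns follow the :func:`anova_f` sentinel conventions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n, g = X.shape[0], classes.size
    if g < 2:
        raise ValueError("need at least two classes")
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    for c in classes:
        grp = X[y == c]
        mean_c = grp.mean(axis=0)
        ss_between += grp.shape[0] * (mean_c - grand) ** 2
        ss_within += ((grp - mean_c) ** 2).sum(axis=0)
    df_b, df_w = g - 1, n - g
    total = ss_between + ss_within
    constant = np.ptp(X, axis=0) == 0
    degenerate = ~constant & (ss_within <= 1e-12 * np.maximum(total, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(F, df_b, df_w)
    F[degenerate], p[degenerate] = np.inf, 0.0
    F[constant], p[constant] = np.nan, np.nan
    return F, p


class AnovaTopKSelector(TransformerMixin, BaseEstimator):
    """Select the k columns with the smallest ANOVA p-values.

    sklearn-compatible transformer: ``fit(X, y)`` ranks the columns,
    ``transform(X)`` returns them in rank order (not original order).
    Ties are broken by larger F, then lower column index; columns with
    undefined F (all-constant) rank last.

    Attributes
    ----------
    f_statistic_, p_values_ : per-column statistics
    ranking_ : full permutation of column indices, best first
    selected_idx_ : the first k entries of ``ranking_``
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds {X.shape[1]} columns")
        F, p = f_oneway_columns(X, np.asarray(y))
        p_key = np.where(np.isnan(p), np.inf, p)
        f_key = np.where(np.isnan(F), -np.inf, F)
        idx = np.arange(X.shape[1])
        self.ranking_ = np.array(sorted(idx, key=lambda i: (p_key[i], -f_key[i], i)))
        self.f_statistic_, self.p_values_ = F, p
        self.selected_idx_ = self.ranking_[: self.k]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count changed between fit and transform")
        return X[:, self.selected_idx_]


@dataclass
class SelectionResult:
    """Top-k ranking with the statistics that produced it."""

    indices: np.ndarray  # ranked, length k
    f_statistic: np.ndarray  # aligned with indices
    p_values: np.ndarray
    k: int
    descriptors: Optional[Sequence[FeatureDescriptor]] = None

    def __post_init__(self) -> None:
        if len(self.indices) != self.k:
            raise ValueError("|ranking| must equal k")
        finite = self.p_values[np.isfinite(self.p_values)]
        if np.any(np.diff(finite) < 0):
            raise ValueError("p-values must be non-decreasing along the ranking")


def select_top_k(fm: FeatureMatrix, labels, k: int) -> SelectionResult:
    """Rank ``fm``'s columns by ANOVA p over ``labels`` and keep the top k."""
    sel = AnovaTopKSelector(k=k).fit(fm.values, labels)
    idx = sel.selected_idx_
    return SelectionResult(
        idx, sel.f_statistic_[idx], sel.p_values_[idx], k,
        [fm.descriptors[i] for i in idx],
    )


def fuse(eeg_sel: FeatureMatrix, fnirs_sel: FeatureMatrix) -> FeatureMatrix:
    """Concatenate selected EEG and fNIRS columns (EEG first, rank order)."""
    if eeg_sel.n_samples != fnirs_sel.n_samples:
        raise ValueError("sample counts differ between modalities")
    if not np.array_equal(eeg_sel.labels, fnirs_sel.labels):
        raise ValueError("labels differ between modalities")
    descs = list(eeg_sel.descriptors) + list(fnirs_sel.descriptors)
    if len(set(descs)) != len(descs):
        raise ValueError("duplicate descriptors in fusion")
    return FeatureMatrix(
        np.hstack([eeg_sel.values, fnirs_sel.values]), descs, eeg_sel.labels,
        eeg_sel.provenance.reset_index(drop=True),
    )
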