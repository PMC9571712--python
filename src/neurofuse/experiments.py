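"""Reduced-scale validation studies run end to end on synthetic cohorts.

These are the package's own recovery and calibration experiments: they
generate a seeded cohort, run the full pipeline (features -> ANOVA
selection -> fusion -> SVM cross-validation, plus sweeps and maps) and
summarise whether the planted effects are recovered and whether the null
is calibrated.  Problem sizes are deliberately smaller than the emulated
study (fewer participants, fewer channels, shorter EEG windows) so a full
run stays in the minutes range on one core; the planted effect sizes are
the generator defaults.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import crossval, normalize_per_participant
from .montage import DEFAULT_EEG_CHANNELS_28
from .pipeline import (
    DEFAULT_FNIRS_STARTS,
    binary_subset,
    extract_cohort_features,
    extract_session_features,
)
from .select_fuse import f_oneway_columns, fuse, select_top_k
from .simulate import SimConfig, SimulatedDataset, make_events
from .sweep import size_sweep
from .visualize import per_channel_accuracy

__all__ = [
    "REDUCED_EEG_CHANNELS", "REDUCED_FNIRS_CHANNELS", "reduced_config",
    "derive_seed", "feature_accounting", "null_calibration",
    "effect_recovery", "window_size_study",
]

REDUCED_EEG_CHANNELS = ["Fp1", "Fp2", "AFz", "F1", "F2", "Cz", "C3", "C4",
                        "Pz", "POz", "O1", "O2"]
REDUCED_FNIRS_CHANNELS = ["AF7", "AF3", "AFpz", "FCC1", "CCP3", "PPOz",
                          "POOz", "AF8"]

#: EEG window length (s) used by the reduced studies.
REDUCED_EEG_WIN = 20.0


def derive_seed(seed: int, i: int) -> int:
    """Stable sub-seed, kept below 2**31."""
    return (seed * 10007 + i) % (2 ** 31)


def reduced_config(seed: int, n_participants: int = 8,
                   null_effects: bool = False, **overrides) -> SimConfig:
    """Down-scaled cohort: fewer participants/channels, one session."""
    kwargs = dict(
        n_participants=n_participants, n_sessions=1, n_sets_per_session=3,
        eeg_channels=list(REDUCED_EEG_CHANNELS),
        fnirs_channels=list(REDUCED_FNIRS_CHANNELS),
        seed=seed,
    )
    if null_effects:
        kwargs.update(alpha_suppression=0.0, frontal_coupling_gain=0.0,
                      hbr_effect=0.0)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def _cohort_sessions(cfg: SimConfig) -> List[Tuple]:
    ds = SimulatedDataset(cfg)
    return [(eeg, hbo, hbr, ev) for _p, _s, eeg, hbo, hbr, ev in ds.iter_sessions()]


def _cohort_features(cfg: SimConfig, eeg_win: float = REDUCED_EEG_WIN):
    return extract_cohort_features(
        ((e, o, r, ev) for e, o, r, ev in _cohort_sessions(cfg)),
        eeg_win_len=eeg_win,
    )


# ---------------------------------------------------------------------------

def feature_accounting(seed: int = 0) -> Dict[str, float]:
    """Column counts of the assembled matrices under the emulated study's
    stated configuration (28 EEG channels, 3 bands, 4 estimators, 10 fNIRS
    windows x 36 channels) and the default cohort's task count."""
    cfg = SimConfig(n_participants=1, n_sessions=1, n_sets_per_session=1,
                    eeg_channels=list(DEFAULT_EEG_CHANNELS_28), seed=seed)
    eeg, hbo, hbr, ev = SimulatedDataset(cfg).session(0, 0)
    fm = extract_session_features(eeg, hbo, None, ev, eeg_win_len=8.0,
                                  fnirs_starts=DEFAULT_FNIRS_STARTS)
    counts = {"eeg-psd": 0, "eeg-fbc": 0, "fnirs-hbo": 0}
    for d in fm.descriptors:
        counts[d.modality] += 1
    n_tasks = len(make_events(SimConfig(seed=seed)))
    return {
        "eeg_psd_columns": counts["eeg-psd"],
        "eeg_fbc_columns": counts["eeg-fbc"],
        "fnirs_columns_per_indicator": counts["fnirs-hbo"],
        "default_cohort_tasks": n_tasks,
    }


def null_calibration(seed: int = 0, n_seeds: int = 3, n_permutations: int = 50,
                     n_participants: int = 8) -> Dict[str, float]:
    """False-positive rate of the ANOVA screen and permutation-null CV
    accuracy when no effects are planted."""
    fprs = []
    fm = None
    for i in range(n_seeds):
        cfg = reduced_config(derive_seed(seed, i), n_participants,
                             null_effects=True)
        fm = _cohort_features(cfg)
        _F, p = f_oneway_columns(fm.values, fm.labels)
        fprs.append(float(np.mean(p[~np.isnan(p)] < 0.05)))

    # permutation null on the last cohort: the feature set is fixed by the
    # unpermuted screen, then labels are shuffled and the CV repeated
    sub = normalize_per_participant(binary_subset(fm, ("0-back", "3-back")))
    sel = select_top_k(sub, sub.labels, 10)
    chosen = sub.select_columns(sel.indices)
    rng = np.random.default_rng(derive_seed(seed, 777))
    perm_acc = []
    for j in range(n_permutations):
        perm = rng.permutation(chosen.labels)
        rep = crossval(chosen, labels=perm, seed=derive_seed(seed, j))
        perm_acc.append(rep.accuracy)
    return {
        "anova_fpr_at_0.05": float(np.mean(fprs)),
        "n_null_features": int(fm.n_features),
        "permuted_cv_accuracy_pct": float(np.mean(perm_acc)),
        "n_permutations": n_permutations,
    }


def _is_planted(desc, cfg: SimConfig) -> bool:
    if desc.modality == "eeg-psd":
        return desc.channel[0] in cfg.posterior_channels
    if desc.modality == "eeg-fbc":
        return any(set(desc.channel) == set(p) for p in cfg.coupled_pairs)
    return desc.channel[0] in cfg.planted_fnirs


def _hybrid_accuracy(fm, task_pair: Tuple[str, str], seed: int,
                     k_each: int = 5) -> float:
    """Top-5 EEG + top-5 fNIRS fusion, SVM 5-fold CV."""
    sub = normalize_per_participant(binary_subset(fm, task_pair))
    eeg_idx = [i for i, d in enumerate(sub.descriptors)
               if d.modality.startswith("eeg")]
    fnirs_idx = [i for i, d in enumerate(sub.descriptors)
                 if d.modality.startswith("fnirs")]
    eeg_fm, fnirs_fm = sub.select_columns(eeg_idx), sub.select_columns(fnirs_idx)
    eeg_sel = select_top_k(eeg_fm, eeg_fm.labels, k_each)
    fnirs_sel = select_top_k(fnirs_fm, fnirs_fm.labels, k_each)
    hybrid = fuse(eeg_fm.select_columns(eeg_sel.indices),
                  fnirs_fm.select_columns(fnirs_sel.indices))
    return crossval(hybrid, seed=seed).accuracy


def effect_recovery(seed: int = 0, n_seeds: int = 10,
                    n_participants: int = 8) -> Dict[str, float]:
    """Planted-effect recovery across seeded cohorts.

    Measures: fraction of seeds whose three-class ANOVA top-10 contains a
    planted feature; median hybrid CV accuracies for 0-back vs 3-back and
    2-back vs 3-back; fraction of seeds whose per-channel accuracy maps
    peak at a planted channel (posterior alpha PSD for EEG, HbR window
    mean for fNIRS, 0-back vs 3-back).
    """
    hits, acc_0v3, acc_2v3, post_max, fnirs_max = [], [], [], [], []
    for i in range(n_seeds):
        s = derive_seed(seed, i)
        cfg = reduced_config(s, n_participants)
        fm = _cohort_features(cfg)

        norm = normalize_per_participant(fm)
        sel = select_top_k(norm, norm.labels, 10)
        hits.append(any(_is_planted(d, cfg) for d in sel.descriptors))

        acc_0v3.append(_hybrid_accuracy(fm, ("0-back", "3-back"), s))
        acc_2v3.append(_hybrid_accuracy(fm, ("2-back", "3-back"), s))

        eeg_map = per_channel_accuracy(
            fm, ("0-back", "3-back"), cfg.eeg_channels,
            np.zeros((len(cfg.eeg_channels), 2)),
            column_filter=lambda d: d.modality == "eeg-psd" and d.band == "alpha",
            seed=s)
        post_max.append(
            cfg.eeg_channels[int(np.argmax(eeg_map.values))] in cfg.posterior_channels)
        fnirs_map = per_channel_accuracy(
            fm, ("0-back", "3-back"), cfg.fnirs_channels,
            np.zeros((len(cfg.fnirs_channels), 2)),
            column_filter=lambda d: d.modality == "fnirs-hbr",
            seed=s)
        fnirs_max.append(
            cfg.fnirs_channels[int(np.argmax(fnirs_map.values))] in cfg.planted_fnirs)
    return {
        "planted_in_top10_rate": float(np.mean(hits)),
        "hybrid_0v3_accuracy_pct": float(np.median(acc_0v3)),
        "hybrid_2v3_accuracy_pct": float(np.median(acc_2v3)),
        "posterior_map_max_rate": float(np.mean(post_max)),
        "fnirs_map_max_rate": float(np.mean(fnirs_max)),
        "n_seeds": n_seeds,
    }


def window_size_study(seed: int = 0, n_seeds: int = 5,
                      n_participants: int = 6,
                      sizes: Sequence[float] = (5.0, 10.0, 20.0, 40.0)
                      ) -> Dict[str, object]:
    """Median accuracy against window length for each modality.

    fNIRS windows are position-optimised per size; EEG windows anchor at
    the task onset and use PSD features.
    """
    eeg_curves, fnirs_curves = [], []
    for i in range(n_seeds):
        s = derive_seed(seed, i)
        cfg = reduced_config(s, n_participants)
        sessions = _cohort_sessions(cfg)
        fnirs_curves.append(
            size_sweep(sessions, sizes, "fnirs", seed=s).accuracy)
        eeg_curves.append(
            size_sweep(sessions, sizes, "eeg", seed=s).accuracy)
    eeg_med = np.median(np.vstack(eeg_curves), axis=0)
    fnirs_med = np.median(np.vstack(fnirs_curves), axis=0)
    sizes = np.asarray(sizes, dtype=float)
    return {
        "sizes_s": sizes.tolist(),
        "eeg_accuracy_pct": eeg_med.tolist(),
        "fnirs_accuracy_pct": fnirs_med.tolist(),
        "eeg_best_size_s": float(sizes[int(np.argmax(eeg_med))]),
        "fnirs_best_size_s": float(sizes[int(np.argmax(fnirs_med))]),
        "eeg_long_minus_short_pct": float(eeg_med[-1] - eeg_med[0]),
        "fnirs_short_minus_long_pct": float(fnirs_med[0] - fnirs_med[-1]),
    }
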