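"""Seeded synthetic EEG + fNIRS n-back sessions with planted workload effects.

The generator emulates the structure of a multi-level n-back working-memory
study: a cohort of participants, each with several sessions, each session a
sequence of sets containing one 0-back, one 2-back and one 3-back task in
random order.  Every task block is 2 s instruction + 40 s task + 1 s stop +
20 s rest; a short lead-in rest opens each session so pre-stimulus baselines
exist for the first block.

Three workload effects are planted, all scaling with the load rank
(0-back -> 0, 2-back -> 1, 3-back -> 2):

* posterior alpha suppression -- the 10 Hz oscillator amplitude at
  designated posterior channels shrinks by ``alpha_suppression`` per rank;
* frontal coupling -- designated frontal channel pairs share a common theta
  oscillator mixed in with weight ``frontal_coupling_gain`` x rank;
* hemodynamic modulation -- the task-evoked HbO/HbR amplitude at designated
  frontal fNIRS channels grows by ``hbr_effect`` per rank, with the response
  delayed by a canonical double-gamma HRF peaking ~6 s after onset.

EEG background is 1/f (pink) noise; oscillators at 2, 6 and 10 Hz carry
random phase and lognormal amplitude jitter per task, so band powers vary
realistically from trial to trial.  The hemodynamic neural drive adapts
exponentially within the 40 s task (habituation), and fNIRS channels carry
random-walk drift on top of white noise; HbR is an anticorrelated copy of
HbO (``hbr = -kappa * hbo``) plus independent noise.

All randomness derives from one integer seed; per-(participant, session)
streams are keyed so any subset of the cohort is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .datatypes import LOAD_RANK, Recording, validate_events
from .montage import (
    DEFAULT_EEG_CHANNELS,
    DEFAULT_FNIRS_CHANNELS,
    EEG_MONTAGE_30,
    FNIRS_MONTAGE_36,
    montage_array,
)

__all__ = ["SimConfig", "GroundTruth", "SimulatedDataset", "generate_dataset",
           "generate_session", "make_events", "hrf"]

LABELS = ("0-back", "2-back", "3-back")


@dataclass
class SimConfig:
    """Study-design and effect-size parameters for the generator.

    Durations are seconds, rates Hz.  Effect parameters are per unit of
    load rank.  ``block_layout`` is (instruction, task, stop, rest).
    """

    n_participants: int = 26
    n_sessions: int = 3
    n_sets_per_session: int = 3
    eeg_rate: float = 200.0
    fnirs_rate: float = 10.0
    eeg_channels: Sequence[str] = field(default_factory=lambda: list(DEFAULT_EEG_CHANNELS))
    fnirs_channels: Sequence[str] = field(default_factory=lambda: list(DEFAULT_FNIRS_CHANNELS))
    block_layout: Tuple[float, float, float, float] = (2.0, 40.0, 1.0, 20.0)
    lead_in_s: float = 5.0
    # planted effects (fractional, per load rank)
    alpha_suppression: float = 0.15
    frontal_coupling_gain: float = 0.4
    hbr_effect: float = 0.5
    hrf_peak_delay: float = 6.0
    noise_sd: float = 1.0
    seed: int = 0
    # secondary generator knobs
    osc_freqs: Tuple[float, ...] = (2.0, 6.0, 10.0)
    osc_amps: Tuple[float, ...] = (1.0, 0.8, 1.0)
    posterior_alpha_amp: float = 2.0
    amplitude_jitter: float = 0.35
    fnirs_amp: float = 1.0
    fnirs_jitter: float = 0.3
    fnirs_noise_sd: float = 0.3
    fnirs_drift_sd: float = 0.02
    adaptation_tau_s: float = 12.0
    hbo_hbr_kappa: float = 0.5
    posterior_channels: Tuple[str, ...] = ("POz", "O1", "O2")
    coupled_pairs: Tuple[Tuple[str, str], ...] = (("Fp1", "Fp2"), ("Fp1", "AFz"))
    planted_fnirs: Tuple[str, ...] = ("AF8",)

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_sessions", "n_sets_per_session"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.eeg_rate <= 0 or self.fnirs_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if any(d <= 0 for d in self.block_layout):
            raise ValueError("all block durations must be positive")
        if self.lead_in_s < 0:
            raise ValueError("lead_in_s must be non-negative")
        for name in ("alpha_suppression", "frontal_coupling_gain", "hbr_effect",
                     "noise_sd", "fnirs_noise_sd", "fnirs_drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hrf_peak_delay <= 0:
            raise ValueError("hrf_peak_delay must be positive")
        for chans in (self.eeg_channels, self.fnirs_channels):
            if len(set(chans)) != len(chans):
                raise ValueError("channel labels must be unique")
        for ch in self.posterior_channels:
            if ch not in self.eeg_channels:
                raise ValueError(f"planted posterior channel {ch!r} not in montage")
        for a, b in self.coupled_pairs:
            if a not in self.eeg_channels or b not in self.eeg_channels:
                raise ValueError(f"planted pair ({a}, {b}) not in montage")
        for ch in self.planted_fnirs:
            if ch not in self.fnirs_channels:
                raise ValueError(f"planted fNIRS channel {ch!r} not in montage")

    @property
    def block_duration(self) -> float:
        return float(sum(self.block_layout))

    @property
    def tasks_per_session(self) -> int:
        return self.n_sets_per_session * len(LABELS)

    @property
    def session_duration(self) -> float:
        return self.lead_in_s + self.tasks_per_session * self.block_duration


@dataclass
class GroundTruth:
    """Which channels/pairs carry planted workload effects, and how strongly."""

    posterior_channels: Tuple[str, ...]
    coupled_pairs: Tuple[Tuple[str, str], ...]
    fnirs_channels: Tuple[str, ...]
    alpha_suppression: float
    frontal_coupling_gain: float
    hbr_effect: float


def hrf(t, peak_delay: float = 6.0):
    """Canonical double-gamma hemodynamic response, peak normalised to 1.

    Peak gamma shape 6, undershoot shape 16, undershoot ratio 1/6; the time
    axis is scaled so the positive peak lands at ``peak_delay`` seconds.

    Parameters
    ----------
    t : float or array
        Time since stimulus, seconds, >= 0.
    peak_delay : float
        Time of the response maximum, seconds, > 0.
    """
    if peak_delay <= 0:
        raise ValueError("peak_delay must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    scale = peak_delay / 5.0  # gamma(shape=6) mode is 5 * scale
    raw = (gamma_dist.pdf(t_arr, 6, scale=scale)
           - gamma_dist.pdf(t_arr, 16, scale=scale) / 6.0)
    peak = (gamma_dist.pdf(peak_delay, 6, scale=scale)
            - gamma_dist.pdf(peak_delay, 16, scale=scale) / 6.0)
    out = raw / peak
    return float(out) if np.isscalar(t) else out


def _events_rng(config: SimConfig, participant: int, session: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1, participant, session])


def _signal_rng(config: SimConfig, participant: int, session: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 2, participant, session])


def make_session_events(config: SimConfig, participant: int, session: int) -> pd.DataFrame:
    """Event rows for one session; task ordering drawn from the keyed stream."""
    rng = _events_rng(config, participant, session)
    instruction, task_dur, _, _ = config.block_layout
    rows = []
    block = 0
    for series in range(config.n_sets_per_session):
        order = rng.permutation(len(LABELS))
        for j in order:
            onset = config.lead_in_s + block * config.block_duration + instruction
            rows.append((participant, session, series, LABELS[j], onset, task_dur))
            block += 1
    return pd.DataFrame(
        rows, columns=["participant", "session", "series", "label", "onset_s", "duration_s"]
    )


def make_events(config: SimConfig) -> pd.DataFrame:
    """Full cohort event table: one row per task."""
    frames = [
        make_session_events(config, p, s)
        for p in range(config.n_participants)
        for s in range(config.n_sessions)
    ]
    return validate_events(pd.concat(frames, ignore_index=True))


def _pink_noise(rng: np.random.Generator, shape: Tuple[int, int], sd: float) -> np.ndarray:
    """1/f-power background via spectrum shaping of white noise."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    weight = np.zeros_like(freqs)
    weight[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    out = np.fft.irfft(spec * weight, n=n, axis=1)
    scale = out.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    return out / scale * sd


def _generate_eeg(config: SimConfig, events: pd.DataFrame,
                  rng: np.random.Generator) -> Recording:
    rate = config.eeg_rate
    n = round(config.session_duration * rate)
    chans = list(config.eeg_channels)
    n_ch = len(chans)
    data = _pink_noise(rng, (n_ch, n), config.noise_sd)

    posterior = set(config.posterior_channels)
    freqs = np.asarray(config.osc_freqs)
    base_amps = np.tile(np.asarray(config.osc_amps), (n_ch, 1))
    alpha_idx = int(np.argmin(np.abs(freqs - 10.0)))
    theta_freq = freqs[np.argmin(np.abs(freqs - 6.0))]
    pair_idx = [(chans.index(a), chans.index(b)) for a, b in config.coupled_pairs]

    for row in events.itertuples():
        rank = LOAD_RANK[row.label]
        i0 = round(row.onset_s * rate)
        i1 = round((row.onset_s + row.duration_s) * rate)
        t = np.arange(i1 - i0) / rate
        amps = base_amps.copy()
        for ci, ch in enumerate(chans):
            if ch in posterior:
                amps[ci, alpha_idx] = config.posterior_alpha_amp * (
                    1.0 - config.alpha_suppression * rank
                )
        # slowly varying lognormal amplitude envelope: independent draws per
        # 5 s cell, so band-power variability decreases with window length
        n_t = i1 - i0
        n_cells = max(int(np.ceil(n_t / (5.0 * rate))), 1)
        cell_factors = np.exp(rng.normal(0.0, config.amplitude_jitter,
                                         size=amps.shape + (n_cells,)))
        env = np.repeat(cell_factors, int(np.ceil(n_t / n_cells)),
                        axis=-1)[..., :n_t]
        phases = rng.uniform(0.0, 2 * np.pi, size=amps.shape)
        # sum of oscillators: (ch, osc, t) -> (ch, t)
        waves = np.sin(2 * np.pi * freqs[None, :, None] * t[None, None, :]
                       + phases[:, :, None])
        data[:, i0:i1] += np.einsum("cot,cot->ct", amps[..., None] * env, waves)
        # shared theta source per coupled pair
        for (ia, ib) in pair_idx:
            phase = rng.uniform(0.0, 2 * np.pi)
            w = config.frontal_coupling_gain * rank
            if w > 0:
                shared = w * np.sin(2 * np.pi * theta_freq * t + phase)
                data[ia, i0:i1] += shared
                data[ib, i0:i1] += shared
    return Recording(data, rate, "eeg", chans, montage_array(chans, EEG_MONTAGE_30))


def _generate_fnirs(config: SimConfig, events: pd.DataFrame,
                    rng: np.random.Generator) -> Tuple[Recording, Recording]:
    rate = config.fnirs_rate
    n = round(config.session_duration * rate)
    chans = list(config.fnirs_channels)
    n_ch = len(chans)
    planted = set(config.planted_fnirs)

    # neural drive: amplitude-scaled, exponentially adapting task boxcar
    neural = np.zeros((n_ch, n))
    for row in events.itertuples():
        rank = LOAD_RANK[row.label]
        i0 = round(row.onset_s * rate)
        i1 = min(round((row.onset_s + row.duration_s) * rate), n)
        t = np.arange(i1 - i0) / rate
        envelope = np.exp(-t / config.adaptation_tau_s)
        jitter = np.exp(rng.normal(0.0, config.fnirs_jitter, size=n_ch))
        for ci, ch in enumerate(chans):
            amp = config.fnirs_amp
            if ch in planted:
                amp *= 1.0 + config.hbr_effect * rank
            neural[ci, i0:i1] += amp * jitter[ci] * envelope

    # convolve with unit-area HRF so a sustained drive of amplitude A
    # plateaus near A
    dt = 1.0 / rate
    tk = np.arange(0.0, 32.0, dt)
    kern = hrf(tk, config.hrf_peak_delay)
    kern = kern / (kern.sum() * dt)
    response = fftconvolve(neural, kern[None, :] * dt, axes=1)[:, :n]

    drift = np.cumsum(rng.normal(0.0, config.fnirs_drift_sd, size=(n_ch, n)), axis=1)
    hbo_data = response + drift + rng.normal(0.0, config.fnirs_noise_sd, size=(n_ch, n))
    hbr_data = (-config.hbo_hbr_kappa * hbo_data
                + rng.normal(0.0, config.fnirs_noise_sd, size=(n_ch, n)))
    xy = montage_array(chans, FNIRS_MONTAGE_36)
    return (Recording(hbo_data, rate, "hbo", chans, xy),
            Recording(hbr_data, rate, "hbr", chans, xy))


def generate_session(config: SimConfig, participant: int, session: int
                     ) -> Tuple[Recording, Recording, Recording, pd.DataFrame]:
    """Generate one session: (eeg, hbo, hbr, events)."""
    events = make_session_events(config, participant, session)
    rng = _signal_rng(config, participant, session)
    eeg = _generate_eeg(config, events, rng)
    hbo, hbr = _generate_fnirs(config, events, rng)
    return eeg, hbo, hbr, events


class SimulatedDataset:
    """Lazy cohort: recordings are synthesised per session on access.

    ``events`` covers the whole cohort; ``session(p, s)`` returns the
    (eeg, hbo, hbr, events) tuple for one participant/session, identical
    on every call for a fixed config.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self.events = make_events(config)
        self.ground_truth = GroundTruth(
            tuple(config.posterior_channels),
            tuple(tuple(p) for p in config.coupled_pairs),
            tuple(config.planted_fnirs),
            config.alpha_suppression,
            config.frontal_coupling_gain,
            config.hbr_effect,
        )

    def session(self, participant: int, session: int):
        return generate_session(self.config, participant, session)

    def iter_sessions(self) -> Iterator[Tuple[int, int, Recording, Recording, Recording, pd.DataFrame]]:
        for p in range(self.config.n_participants):
            for s in range(self.config.n_sessions):
                eeg, hbo, hbr, ev = self.session(p, s)
                yield p, s, eeg, hbo, hbr, ev


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Build the cohort object (events eagerly, signals lazily)."""
    return SimulatedDataset(config)
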