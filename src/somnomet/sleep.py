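"""Hypnogram segmentation, sampling triggers, architecture summaries, EEG band power.

A hypnogram is an epoch-by-epoch sequence of scored sleep-wake states
(Wake / NREM / REM). Episodes are maximal runs of one state; they drive the
architecture summary (total time, mean episode duration, episode count,
transition ratios) and the real-time sampling triggers (tissue collected
after 1 min of continued REM or 5 min of continued NREM/wakefulness).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import periodogram

from .core_data import DataError

HYPNOGRAM_STATES = ("Wake", "NREM", "REM")

#: Continued-state durations (s) required before tissue sampling.
DEFAULT_TRIGGER_THRESHOLDS_S = {"REM": 60.0, "NREM": 300.0, "Wake": 300.0}

#: Conventional rodent EEG bands (Hz); half-open [lo, hi).
DEFAULT_BANDS = {"delta": (0.5, 4.0), "theta": (6.0, 10.0)}
TOTAL_BAND = (0.5, 30.0)


@dataclass(frozen=True)
class Hypnogram:
    epoch_s: float
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise DataError("epoch_s must be > 0")
        if not self.states:
            raise DataError("hypnogram must be non-empty")
        bad = set(self.states) - set(HYPNOGRAM_STATES)
        if bad:
            raise DataError(f"unknown state(s) in hypnogram: {sorted(bad)}")
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    @property
    def total_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch_index\tstate\n")
            for i, s in enumerate(self.states):
                fh.write(f"{i}\t{s}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, epoch_s: float = 4.0) -> "Hypnogram":
        states = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("epoch_index"):
                raise DataError("hypnogram TSV must start with an epoch_index header")
            for line in fh:
                if line.strip():
                    states.append(line.rstrip("\n").split("\t")[1])
        return cls(epoch_s=epoch_s, states=tuple(states))


@dataclass(frozen=True)
class Episode:
    state: str
    start_s: float
    duration_s: float


@dataclass
class ArchitectureSummary:
    total_s: dict[str, float]
    mean_episode_s: dict[str, float]
    episode_count: dict[str, int]
    transition_ratio: dict[tuple[str, str], float] = field(default_factory=dict)


def segment_episodes(h: Hypnogram) -> list[Episode]:
    """Maximal runs of identical state, in order; their concatenation tiles h."""
    out: list[Episode] = []
    start = 0
    for state, run in itertools.groupby(h.states):
        n = len(list(run))
        out.append(Episode(state, start * h.epoch_s, n * h.epoch_s))
        start += n
    return out


def sampling_trigger(
    h: Hypnogram,
    target: str,
    thresholds: Mapping[str, float] | None = None,
) -> float | None:
    """Earliest time (s) at which a run of ``target`` has lasted >= its threshold.

    Returns the trigger time (run start + threshold) of the first qualifying
    episode, or None if no run reaches the threshold.
    """
    if target not in HYPNOGRAM_STATES:
        raise DataError(f"unknown state {target!r}")
    thresholds = dict(thresholds or DEFAULT_TRIGGER_THRESHOLDS_S)
    thr = thresholds[target]
    n_ep = thr / h.epoch_s
    if thr <= 0 or abs(n_ep - round(n_ep)) > 1e-9:
        raise DataError("threshold must be a positive multiple of epoch_s")
    for ep in segment_episodes(h):
        if ep.state == target and ep.duration_s >= thr:
            return ep.start_s + thr
    return None


def architecture_summary(h: Hypnogram) -> ArchitectureSummary:
    """Per-state totals, mean episode durations, episode counts, transition ratios.

    transition_ratio[(X, Y)] is the fraction of episode boundaries leaving X
    that enter Y (outgoing-conditional); states with no outgoing boundary are
    absent from the map.
    """
    eps = segment_episodes(h)
    total = {s: 0.0 for s in HYPNOGRAM_STATES}
    count = {s: 0 for s in HYPNOGRAM_STATES}
    dur_sum = {s: 0.0 for s in HYPNOGRAM_STATES}
    for ep in eps:
        total[ep.state] += ep.duration_s
        count[ep.state] += 1
        dur_sum[ep.state] += ep.duration_s
    mean = {s: dur_sum[s] / count[s] for s in HYPNOGRAM_STATES if count[s]}
    out_counts: dict[tuple[str, str], int] = {}
    leaving = {s: 0 for s in HYPNOGRAM_STATES}
    for a, b in zip(eps, eps[1:]):
        out_counts[(a.state, b.state)] = out_counts.get((a.state, b.state), 0) + 1
        leaving[a.state] += 1
    ratio = {k: v / leaving[k[0]] for k, v in out_counts.items()}
    return ArchitectureSummary(
        total_s=total, mean_episode_s=mean, episode_count=count,
        transition_ratio=ratio,
    )


def _check_eeg(eeg: np.ndarray, h: Hypnogram, fs: float) -> int:
    spp = fs * h.epoch_s
    if abs(spp - round(spp)) > 1e-9:
        raise DataError("fs * epoch_s must be an integer number of samples")
    spp = int(round(spp))
    if len(eeg) != spp * h.n_epochs:
        raise DataError(
            f"EEG length {len(eeg)} != epochs x samples/epoch = {spp * h.n_epochs}"
        )
    return spp


def state_periodograms(
    eeg: np.ndarray,
    h: Hypnogram,
    fs: float = 128.0,
    window: str = "hann",
    detrend: str | bool = "constant",
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-epoch periodograms (PSD, one-sided) averaged within each state.

    Returns (freqs, {state: mean PSD}) for the states present in h.
    ``detrend=False`` keeps the DC component (so the spectrum integrates
    exactly to the time-domain mean square for a boxcar window).
    """
    eeg = np.asarray(eeg, dtype=float)
    spp = _check_eeg(eeg, h, fs)
    freqs = None
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for i, s in enumerate(h.states):
        f, pxx = periodogram(eeg[i * spp : (i + 1) * spp], fs=fs, window=window,
                             detrend=detrend)
        freqs = f
        if s in sums:
            sums[s] += pxx
            counts[s] += 1
        else:
            sums[s] = pxx.copy()
            counts[s] = 1
    return freqs, {s: sums[s] / counts[s] for s in sums}


def band_power(
    eeg: np.ndarray,
    h: Hypnogram,
    fs: float = 128.0,
    bands: Mapping[str, tuple[float, float]] | None = None,
    total_band: tuple[float, float] = TOTAL_BAND,
    window: str = "hann",
) -> dict[str, dict[str, dict[str, float]]]:
    """Per-state absolute band power and density (band / total 0.5-30 Hz).

    Bands are half-open [lo, hi) so that bands partitioning the total band
    have densities summing exactly to 1. Powers integrate the per-state mean
    PSD over the band.
    """
    bands = dict(bands or DEFAULT_BANDS)
    freqs, psds = state_periodograms(eeg, h, fs=fs, window=window)
    df = float(freqs[1] - freqs[0])
    out: dict[str, dict[str, dict[str, float]]] = {}
    for state, psd in psds.items():
        tot_mask = (freqs >= total_band[0]) & (freqs < total_band[1])
        total = float(np.sum(psd[tot_mask]) * df)
        absolute, density = {}, {}
        for name, (lo, hi) in bands.items():
            mask = (freqs >= lo) & (freqs < hi)
            p = float(np.sum(psd[mask]) * df)
            absolute[name] = p
            density[name] = p / total if total > 0 else float("nan")
        out[state] = {"absolute": absolute, "density": density}
    return out
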