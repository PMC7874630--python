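"""Synthetic inputs with planted structure for every pipeline stage.

The generators emulate the three data families the analysis chain consumes:

* log-normal metabolite abundance matrices (>200 metabolites, ~10 samples
  per group) with multiplicative group effects and optional global-scale
  outlier samples;
* alternating-state hypnograms as a semi-Markov chain with exponential
  episode lengths (REM default mean 62.6 s, the reported single-episode
  mean) and self-transition-free state switching;
* EEG traces at 128 Hz (one dominant sinusoid per state plus white noise)
  and paired behavioral freezing scores with a planted Pearson correlation.

Each generator is a pure function of its spec (including the seed) and
returns a truth record sufficient to score recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import DataError, MetaboliteTable, PROTOCOLS, STATES
from .sleep import Hypnogram

_DEFAULT_TRANSITIONS: dict[str, dict[str, float]] = {
    "Wake": {"Wake": 0.0, "NREM": 1.0, "REM": 0.0},
    "NREM": {"Wake": 0.65, "NREM": 0.0, "REM": 0.35},
    "REM": {"Wake": 0.9, "NREM": 0.1, "REM": 0.0},
}

_DEFAULT_EPISODE_MEANS = {"Wake": 180.0, "NREM": 160.0, "REM": 62.6}


def _parse_group(label: str) -> tuple[str, str]:
    """Map a group label to (state, protocol) annotations.

    A label may be a state ("REM"), a protocol ("DS", implying Wake), or a
    colon pair "NREM:DS".
    """
    if ":" in label:
        state, protocol = label.split(":", 1)
    elif label in STATES:
        state, protocol = label, "none"
    elif label in PROTOCOLS:
        state, protocol = "Wake", label
    else:
        raise DataError(f"cannot interpret group label {label!r}")
    if state not in STATES or protocol not in PROTOCOLS:
        raise DataError(f"cannot interpret group label {label!r}")
    return state, protocol


@dataclass
class MetabolomeSimSpec:
    """Design of a simulated metabolome experiment.

    ``planted_effects`` maps ``(metabolite_id, group_label)`` to a
    multiplicative effect (> 0) applied to that group's mean abundance.
    ``cv_noise`` is the log-normal coefficient of variation of the
    multiplicative measurement noise. ``n_outliers`` samples get all
    abundances scaled by ``outlier_scale`` (> 1), emulating globally
    aberrant samples gated out by PCA.
    """

    n_metabolites: int = 200
    group_sizes: Mapping[str, int] = field(default_factory=lambda: {"REM": 10, "Wake": 10})
    planted_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    cv_noise: float = 0.2
    n_outliers: int = 0
    outlier_scale: float = 8.0
    seed: int = 0
    metabolite_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise DataError("n_metabolites must be >= 1")
        if self.cv_noise <= 0:
            raise DataError("cv_noise must be > 0")
        for g, n in self.group_sizes.items():
            _parse_group(g)
            if n < 3:
                raise DataError(f"group {g!r} must have >= 3 samples")
        if self.metabolite_ids is not None and len(self.metabolite_ids) != self.n_metabolites:
            raise DataError("metabolite_ids length must equal n_metabolites")
        ids = self.metabolite_ids or [
            f"M{j + 1:04d}" for j in range(self.n_metabolites)
        ]
        for (m, g), e in self.planted_effects.items():
            if e <= 0:
                raise DataError(f"planted effect for {(m, g)} must be > 0")
            if m not in ids:
                raise DataError(f"planted metabolite {m!r} not in metabolite set")
            if g not in self.group_sizes:
                raise DataError(f"planted group {g!r} not in group_sizes")
        if self.n_outliers < 0 or self.outlier_scale <= 1:
            raise DataError("need n_outliers >= 0 and outlier_scale > 1")


def simulate_metabolome(spec: MetabolomeSimSpec) -> tuple[MetaboliteTable, dict]:
    """Generate a MetaboliteTable with planted group effects.

    Abundances are log-normal around per-metabolite baselines drawn
    log-uniformly over three decades (1e2..1e5); the multiplicative noise has
    unit mean so group-mean ratios converge to the planted effects. Returns
    ``(table, truth)`` where truth records the planted effect map and the
    outlier sample ids.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_metabolites
    met_ids = spec.metabolite_ids or [f"M{j + 1:04d}" for j in range(p)]
    baseline = 10.0 ** rng.uniform(2.0, 5.0, size=p)
    sigma = math.sqrt(math.log(1.0 + spec.cv_noise**2))

    sample_ids: list[str] = []
    states: list[str] = []
    protocols: list[str] = []
    rows: list[np.ndarray] = []
    for g, n in spec.group_sizes.items():
        state, protocol = _parse_group(g)
        mean = baseline.copy()
        for j, m in enumerate(met_ids):
            eff = spec.planted_effects.get((m, g))
            if eff is not None:
                mean = mean.copy() if mean is baseline else mean
                mean[j] *= eff
        for i in range(n):
            sample_ids.append(f"{g.replace(':', '-')}_{i + 1:02d}")
            states.append(state)
            protocols.append(protocol)
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=p))
            rows.append(mean * noise)
    values = np.vstack(rows)

    outlier_ids: list[str] = []
    if spec.n_outliers:
        if spec.n_outliers > len(sample_ids):
            raise DataError("more outliers requested than samples")
        idx = rng.choice(len(sample_ids), size=spec.n_outliers, replace=False)
        for i in sorted(int(k) for k in idx):
            values[i] *= spec.outlier_scale
            outlier_ids.append(sample_ids[i])

    zt = np.clip(5.2 + rng.normal(0.0, 0.3, size=len(sample_ids)), 0.0, None)
    ann = pd.DataFrame(
        {"state": states, "protocol": protocols, "zt": zt},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = MetaboliteTable(sample_ids, met_ids, values, ann)
    truth = {
        "planted_effects": dict(spec.planted_effects),
        "outlier_samples": outlier_ids,
    }
    return table, truth


@dataclass
class HypnogramSimSpec:
    """Semi-Markov hypnogram design: exponential episode lengths per state,
    self-transition-free switching by ``transition_probs`` (row-stochastic)."""

    epoch_s: float = 4.0
    total_s: float = 3600.0
    mean_episode_s: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EPISODE_MEANS)
    )
    transition_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_TRANSITIONS.items()}
    )
    initial_state: str = "Wake"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise DataError("epoch_s must be > 0")
        n_epochs = self.total_s / self.epoch_s
        if abs(n_epochs - round(n_epochs)) > 1e-9:
            raise DataError("epoch_s must divide total_s")
        for s in STATES:
            if self.mean_episode_s.get(s, 0) <= 0:
                raise DataError(f"mean_episode_s[{s!r}] must be > 0")
        for s in STATES:
            row = self.transition_probs.get(s)
            if row is None or abs(sum(row.values()) - 1.0) > 1e-9:
                raise DataError(f"transition row for {s!r} must sum to 1")
        if self.initial_state not in STATES:
            raise DataError(f"unknown initial state {self.initial_state!r}")


def simulate_hypnogram(spec: HypnogramSimSpec) -> tuple[Hypnogram, dict]:
    """Generate a hypnogram; returns (hypnogram, truth) with the episode list.

    Episode lengths are exponential with the stated means, rounded to whole
    epochs (min 1). The next state is drawn from the current state's
    transition row with self-transitions excluded; a row with all mass on
    self only raises if a transition actually has to be drawn from it.
    """
    rng = np.random.default_rng(spec.seed)
    n_epochs = int(round(spec.total_s / spec.epoch_s))
    states: list[str] = []
    episodes: list[tuple[str, int]] = []
    current = spec.initial_state
    while len(states) < n_epochs:
        dur = max(1, int(round(rng.exponential(spec.mean_episode_s[current]) / spec.epoch_s)))
        dur = min(dur, n_epochs - len(states))
        states.extend([current] * dur)
        if episodes and episodes[-1][0] == current:
            episodes[-1] = (current, episodes[-1][1] + dur)
        else:
            episodes.append((current, dur))
        if len(states) >= n_epochs:
            break
        row = spec.transition_probs[current]
        others = [s for s in STATES if s != current]
        mass = np.array([row.get(s, 0.0) for s in others])
        if mass.sum() <= 0:
            raise DataError(
                f"degenerate transition row for state {current!r}: all mass on self"
            )
        current = others[int(rng.choice(len(others), p=mass / mass.sum()))]
    h = Hypnogram(epoch_s=spec.epoch_s, states=tuple(states))
    truth = {"episodes": episodes}
    return h, truth


def simulate_eeg(
    hypnogram: Hypnogram,
    fs: float = 128.0,
    band_map: Mapping[str, float] | None = None,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Per-epoch sinusoid at the state's dominant frequency plus white noise.

    Default dominant frequencies: NREM 2 Hz (delta), REM 7 Hz (theta),
    Wake 8 Hz. ``fs * epoch_s`` must be integral.
    """
    band_map = dict(band_map or {"Wake": 8.0, "NREM": 2.0, "REM": 7.0})
    spp = fs * hypnogram.epoch_s
    if abs(spp - round(spp)) > 1e-9:
        raise DataError("fs * epoch_s must be an integer number of samples")
    spp = int(round(spp))
    rng = np.random.default_rng(seed)
    t = np.arange(spp) / fs
    trace = np.empty(spp * len(hypnogram.states))
    for i, s in enumerate(hypnogram.states):
        tone = amplitude * np.sin(2 * np.pi * band_map[s] * t)
        seg = tone if noise_sd == 0 else tone + rng.normal(0.0, noise_sd, size=spp)
        trace[i * spp : (i + 1) * spp] = seg
    return trace


@dataclass
class BehaviorSimSpec:
    """Paired freezing scores (post-shock vs. test) with planted correlation rho."""

    n_mice: int = 16
    rho: float = 0.6
    freezing_mean: float = 40.0
    freezing_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 4:
            raise DataError("n_mice must be >= 4")
        if not -1.0 <= self.rho <= 1.0:
            raise DataError("|rho| must be <= 1")
        if self.freezing_sd < 0:
            raise DataError("freezing_sd must be >= 0")


def simulate_behavior(spec: BehaviorSimSpec) -> tuple[pd.DataFrame, dict]:
    """Bivariate-normal freezing pairs with correlation rho, clipped to [0, 100]%.

    Returns (frame, truth); the frame has columns ``mouse_id``,
    ``post_shock_freezing_pct``, ``test_freezing_pct`` plus the unclipped
    draws (``*_raw``), and truth records the planted rho (pre-clipping).
    """
    rng = np.random.default_rng(spec.seed)
    var = spec.freezing_sd**2
    cov = [[var, spec.rho * var], [spec.rho * var, var]]
    raw = rng.multivariate_normal([spec.freezing_mean] * 2, cov, size=spec.n_mice)
    clipped = np.clip(raw, 0.0, 100.0)
    frame = pd.DataFrame(
        {
            "mouse_id": [f"mouse_{i + 1:02d}" for i in range(spec.n_mice)],
            "post_shock_freezing_pct": clipped[:, 0],
            "test_freezing_pct": clipped[:, 1],
            "post_shock_freezing_raw": raw[:, 0],
            "test_freezing_raw": raw[:, 1],
        }
    )
    return frame, {"rho": spec.rho}
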