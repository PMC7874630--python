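"""Fear-conditioning behavioral indices and pre/post-consolidation correlations.

Freezing percentages are pre-scored inputs (one row per mouse). The two
indices follow the standard contextual fear-conditioning definitions:

* discrimination index = (freezing_A - freezing_B_first3min) /
  max(freezing_A, freezing_B_first3min), in [-1, 1];
* shock reactivity = movement in the 2 s before the first shock / movement
  in the 2 s of the first shock.

Correlations between conditioned responses before and after consolidation
are two-tailed Pearson r with the exact t-based p-value
t = r sqrt((n-2)/(1-r^2)), df = n-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError


@dataclass
class FreezingRecord:
    mouse_id: str
    post_shock_freezing_pct: float = np.nan
    third_tone_freezing_pct: float = np.nan
    context_test_freezing_pct: float = np.nan
    tone_test_first_min_freezing_pct: float = np.nan
    contextA_freezing_pct: float = np.nan
    contextB_first3min_freezing_pct: float = np.nan
    pre_shock_movement: float = np.nan
    shock_movement: float = np.nan

    def __post_init__(self) -> None:
        for name in (
            "post_shock_freezing_pct", "third_tone_freezing_pct",
            "context_test_freezing_pct", "tone_test_first_min_freezing_pct",
            "contextA_freezing_pct", "contextB_first3min_freezing_pct",
        ):
            v = getattr(self, name)
            if not np.isnan(v) and not 0.0 <= v <= 100.0:
                raise DataError(f"{name} must be within [0, 100], got {v}")
        for name in ("pre_shock_movement", "shock_movement"):
            v = getattr(self, name)
            if not np.isnan(v) and v < 0:
                raise DataError(f"{name} must be >= 0, got {v}")


def discrimination_index(r: FreezingRecord) -> float:
    """(A - B) / max(A, B) with A = conditioning-context freezing and
    B = neutral-context freezing (first 3 min); undefined when both are 0."""
    a = r.contextA_freezing_pct
    b = r.contextB_first3min_freezing_pct
    if np.isnan(a) or np.isnan(b):
        raise DataError("discrimination index needs both context freezing values")
    m = max(a, b)
    if m <= 0:
        raise DataError("discrimination index undefined when both freezing values are 0")
    return (a - b) / m


def shock_reactivity(r: FreezingRecord) -> float:
    """Pre-shock movement (2 s) over movement during the first 2-s shock."""
    if np.isnan(r.pre_shock_movement) or np.isnan(r.shock_movement):
        raise DataError("shock reactivity needs both movement values")
    if r.shock_movement <= 0:
        raise DataError("shock reactivity undefined for zero shock movement")
    return r.pre_shock_movement / r.shock_movement


def freezing_correlation(x, y) -> tuple[float, float, int]:
    """Two-tailed Pearson correlation of paired per-mouse scores.

    Returns (r, p, n) with p from the t distribution with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be paired 1-d vectors")
    n = len(x)
    if n < 4:
        raise DataError("need n >= 4 pairs")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise DataError("missing values are not allowed")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0 or sy == 0:
        raise DataError("zero variance in x or y")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def read_freezing_csv(path: str | Path) -> list[FreezingRecord]:
    """One row per mouse; columns named after FreezingRecord fields."""
    df = pd.read_csv(path, dtype={"mouse_id": str})
    if "mouse_id" not in df.columns:
        raise DataError("behavior CSV needs a mouse_id column")
    fields = [f for f in FreezingRecord.__dataclass_fields__ if f != "mouse_id"]
    out = []
    for _, row in df.iterrows():
        kwargs = {f: float(row[f]) if f in df.columns and pd.notna(row[f]) else np.nan
                  for f in fields}
        out.append(FreezingRecord(mouse_id=str(row["mouse_id"]), **kwargs))
    return out
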