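"""Metabolite abundance tables: data model, delimited-text IO, and preprocessing.

A :class:`MetaboliteTable` holds a samples x metabolites abundance matrix
(dentate-gyrus metabolite profiles in the motivating experiments) together
with per-sample annotations: the scored sleep-wake state at tissue sampling
(REM / NREM / Wake), the fear-conditioning protocol (DS / IS / CO, or
``none`` for unconditioned animals), and the zeitgeber time in hours.

Missing measurements are stored as NaN, never as zero; a raw zero on read is
rejected so that "not detected" and "measured as zero" are never conflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATES = ("REM", "NREM", "Wake")
PROTOCOLS = ("DS", "IS", "CO", "none")
RESERVED_COLUMNS = ("sample_id", "state", "protocol", "zt")


class DataError(ValueError):
    """Invalid data content (bad labels, shapes, duplicate ids, ...)."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix with per-sample annotations.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    metabolite_ids
        Unique metabolite identifiers, one per matrix column.
    abundances
        Non-negative real abundances; NaN marks a missing measurement.
    annotations
        DataFrame indexed by sample id with columns ``state`` (REM/NREM/Wake),
        ``protocol`` (DS/IS/CO/none) and ``zt`` (zeitgeber hours, >= 0).
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    abundances: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.abundances = np.asarray(self.abundances, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.metabolite_ids, "metabolite")
        n, p = len(self.sample_ids), len(self.metabolite_ids)
        if self.abundances.shape != (n, p):
            raise DataError(
                f"abundance matrix shape {self.abundances.shape} does not match "
                f"{n} samples x {p} metabolites"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.abundances < 0):
                i, j = np.argwhere(self.abundances < 0)[0]
                raise DataError(
                    f"negative abundance at sample {self.sample_ids[i]!r}, "
                    f"metabolite {self.metabolite_ids[j]!r}"
                )
        ann = self.annotations
        if list(ann.index) != self.sample_ids:
            ann = ann.reindex(self.sample_ids)
        for col in ("state", "protocol", "zt"):
            if col not in ann.columns:
                raise DataError(f"missing annotation column {col!r}")
        bad_state = set(ann["state"]) - set(STATES)
        if bad_state:
            raise DataError(f"unknown state label(s): {sorted(bad_state)}")
        bad_proto = set(ann["protocol"]) - set(PROTOCOLS)
        if bad_proto:
            raise DataError(f"unknown protocol label(s): {sorted(bad_proto)}")
        zt = ann["zt"].to_numpy(dtype=float)
        if np.any(zt[~np.isnan(zt)] < 0):
            raise DataError("zeitgeber time must be >= 0")
        self.annotations = ann[["state", "protocol", "zt"]]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def sample_mask(self, **criteria: str) -> np.ndarray:
        """Boolean mask over samples matching annotation ``column=value`` pairs."""
        mask = np.ones(self.n_samples, dtype=bool)
        for col, val in criteria.items():
            if val is None:
                continue
            if col not in self.annotations.columns:
                raise DataError(f"unknown annotation column {col!r}")
            mask &= (self.annotations[col] == val).to_numpy()
        return mask

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise DataError(f"unknown metabolite id: {metabolite_id!r}") from None

    def subset(
        self,
        samples: Sequence[str] | None = None,
        metabolites: Sequence[str] | None = None,
    ) -> "MetaboliteTable":
        """Return a new table restricted to the given samples/metabolites (order kept)."""
        s_ids = self.sample_ids if samples is None else [s for s in self.sample_ids if s in set(samples)]
        m_ids = self.metabolite_ids if metabolites is None else [m for m in self.metabolite_ids if m in set(metabolites)]
        ri = [self.sample_ids.index(s) for s in s_ids]
        ci = [self.metabolite_ids.index(m) for m in m_ids]
        return MetaboliteTable(
            sample_ids=list(s_ids),
            metabolite_ids=list(m_ids),
            abundances=self.abundances[np.ix_(ri, ci)].copy(),
            annotations=self.annotations.loc[s_ids].copy(),
        )

    def equals(self, other: "MetaboliteTable", rtol: float = 1e-11) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.metabolite_ids == other.metabolite_ids
            and np.allclose(self.abundances, other.abundances, rtol=rtol, equal_nan=True)
            and self.annotations.equals(other.annotations)
        )


@dataclass
class ProcessedMatrix:
    """A transformed/scaled abundance matrix plus a record of the steps applied."""

    source: MetaboliteTable
    values: np.ndarray
    sample_ids: list[str]
    metabolite_ids: list[str]
    transform_log: list[dict] = field(default_factory=list)


def _sep_for(fmt: str) -> str:
    if fmt == "csv":
        return ","
    if fmt == "tsv":
        return "\t"
    raise DataError(f"unknown format {fmt!r}; use 'csv' or 'tsv'")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"


def read_metabolite_table(path: str | Path, format: str | None = None) -> MetaboliteTable:
    """Read a delimited abundance table.

    Layout: one row per sample; reserved columns ``sample_id``, ``state``,
    ``protocol``, ``zt``; every remaining column is a metabolite. Empty cells
    become missing (NaN). Zero or negative abundances are hard errors.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    df = pd.read_csv(path, sep=_sep_for(fmt), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError("first column must be 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    _check_unique(sample_ids, "sample")
    ann = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    ann["state"] = df["state"].tolist() if "state" in df else "Wake"
    ann["protocol"] = df["protocol"].fillna("none").tolist() if "protocol" in df else "none"
    ann["zt"] = df["zt"].to_numpy(dtype=float) if "zt" in df else np.nan
    met_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    _check_unique(met_cols, "metabolite")
    values = df[met_cols].to_numpy(dtype=float)
    nz = np.argwhere(values == 0)
    if nz.size:
        i, j = nz[0]
        raise DataError(
            f"zero abundance at sample {sample_ids[i]!r}, metabolite "
            f"{met_cols[j]!r}: encode missing values as empty cells, not 0"
        )
    return MetaboliteTable(sample_ids, list(met_cols), values, ann)


def write_metabolite_table(
    table: MetaboliteTable, path: str | Path, format: str | None = None
) -> None:
    """Write a table readable back by :func:`read_metabolite_table` (values to 17 sig. digits)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    df = pd.DataFrame(table.abundances, columns=table.metabolite_ids)
    df.insert(0, "sample_id", table.sample_ids)
    df.insert(1, "state", table.annotations["state"].to_numpy())
    df.insert(2, "protocol", table.annotations["protocol"].to_numpy())
    df.insert(3, "zt", table.annotations["zt"].to_numpy())
    df.to_csv(path, sep=_sep_for(fmt), index=False, float_format="%.17g")


def autoscale(values: np.ndarray) -> np.ndarray:
    """Column-wise unit-variance scaling (mean 0, sd 1; ddof=1)."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argwhere(sd == 0)[0][0])
        raise DataError(f"cannot autoscale zero-variance column index {j}")
    return (values - mu) / sd


def preprocess(
    table: MetaboliteTable,
    missing_policy: str = "half_min_impute",
    log_base: int | None = 10,
    scaling: str | None = "autoscale",
) -> ProcessedMatrix:
    """Missing-value handling, log transform, and scaling, in that order.

    ``missing_policy``: ``drop_metabolite`` removes any metabolite with a
    missing value; ``half_min_impute`` replaces missing values with half the
    metabolite's observed minimum. ``log_base``: 10, 2 or None. ``scaling``:
    ``autoscale`` (unit variance) or None. Every step is appended to
    ``transform_log``. Requires >= 2 non-missing values per annotated
    (state, protocol) group for every retained metabolite.
    """
    values = table.abundances.copy()
    met_ids = list(table.metabolite_ids)
    log: list[dict] = []

    if missing_policy == "drop_metabolite":
        keep = ~np.isnan(values).any(axis=0)
        dropped = [m for m, k in zip(met_ids, keep) if not k]
        values = values[:, keep]
        met_ids = [m for m, k in zip(met_ids, keep) if k]
        log.append({"step": "missing", "policy": "drop_metabolite", "dropped": dropped})
    elif missing_policy == "half_min_impute":
        for j in range(values.shape[1]):
            col = values[:, j]
            miss = np.isnan(col)
            if miss.all():
                raise DataError(f"metabolite {met_ids[j]!r} has no observed values")
            if miss.any():
                col[miss] = np.nanmin(col) / 2.0
        log.append({"step": "missing", "policy": "half_min_impute"})
    else:
        raise DataError(f"unknown missing_policy {missing_policy!r}")

    # per-group support check on retained metabolites
    groups = table.annotations.groupby(["state", "protocol"], observed=True).indices
    raw = table.abundances
    for j, m in enumerate(met_ids):
        col = raw[:, table.metabolite_ids.index(m)]
        for key, idx in groups.items():
            if np.sum(~np.isnan(col[list(idx)])) < 2:
                raise DataError(
                    f"metabolite {m!r} has < 2 observed values in group {key}"
                )

    if log_base not in (10, 2, None):
        raise DataError("log_base must be 10, 2 or None")
    if log_base is not None:
        if np.any(values <= 0):
            raise DataError("log transform requires strictly positive values")
        values = np.log(values) / math.log(log_base)
        log.append({"step": "log", "base": log_base})

    if scaling == "autoscale":
        values = autoscale(values)
        log.append({"step": "scale", "method": "autoscale"})
    elif scaling is not None:
        raise DataError(f"unknown scaling {scaling!r}")

    return ProcessedMatrix(
        source=table,
        values=values,
        sample_ids=list(table.sample_ids),
        metabolite_ids=met_ids,
        transform_log=log,
    )


def metabolite_ratio(
    table: MetaboliteTable, numerator: str, denominator: str
) -> np.ndarray:
    """Per-sample abundance ratio of two metabolites (e.g. GSH/GSSG).

    The GSH/GSSG ratio indexes oxidative stress; missing values propagate to
    NaN. A zero denominator is an error naming the offending sample.
    """
    num = table.abundances[:, table.metabolite_index(numerator)]
    den = table.abundances[:, table.metabolite_index(denominator)]
    zero = np.argwhere(den == 0)
    if zero.size:
        raise DataError(
            f"zero denominator abundance for metabolite {denominator!r} in "
            f"sample {table.sample_ids[int(zero[0][0])]!r}"
        )
    return num / den
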