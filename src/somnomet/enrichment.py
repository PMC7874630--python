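"""Hypergeometric over-representation analysis against a pathway library.

Given a selected metabolite set (top-5%-VIP metabolites for state contrasts,
or the consolidation set for memory contrasts) and a universe of detected
metabolites, each pathway is scored with the upper-tail hypergeometric
probability P(X >= k) of drawing k pathway members among n selected from a
universe of N containing K members. Pathways with p < alpha are called
enriched. Ids are compared case-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_data import DataError


def _norm(ids: Iterable[str]) -> frozenset[str]:
    return frozenset(str(i).casefold() for i in ids)


@dataclass
class PathwayLibrary:
    """Named metabolite sets; ids normalized case-insensitively."""

    pathways: dict[str, frozenset[str]]
    universe_policy: str = "detected_metabolites"

    def __post_init__(self) -> None:
        if self.universe_policy not in ("detected_metabolites", "library_union"):
            raise DataError(f"unknown universe_policy {self.universe_policy!r}")
        norm = {}
        for name, members in self.pathways.items():
            members = _norm(members)
            if not members:
                raise DataError(f"pathway {name!r} has no members")
            norm[name] = members
        self.pathways = norm

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.pathways.values():
            out |= m
        return frozenset(out)


@dataclass
class EnrichmentResult:
    pathway: str
    k_overlap: int
    n_selected: int
    K_pathway: int
    N_universe: int
    p_hyper: float
    enriched: bool
    q_bh: float | None = None


def load_pathway_library(path: str | Path) -> PathwayLibrary:
    """Read a GMT-style library: name <TAB> description <TAB> member ids..."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"line {lineno}: GMT needs name, description, members")
            name = parts[0]
            if name in pathways:
                raise DataError(f"duplicate pathway name {name!r}")
            members = [m for m in parts[2:] if m.strip()]
            if not members:
                raise DataError(f"pathway {name!r} has an empty member list")
            pathways[name] = _norm(members)
    return PathwayLibrary(pathways)


def write_pathway_library(library: PathwayLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in library.pathways:
            members = "\t".join(sorted(library.pathways[name]))
            fh.write(f"{name}\t-\t{members}\n")


def bundled_library() -> PathwayLibrary:
    """Small built-in example library (synthetic fixture; see data/example_pathways.gmt).

    Includes a purine-metabolism set (hypoxanthine, xanthine, urate,
    allantoin, urea, inosine, adenosine, guanine, ...) so purine-pathway
    recovery can be exercised without an external library.
    """
    ref = resources.files("somnomet").joinpath("data/example_pathways.gmt")
    with resources.as_file(ref) as path:
        return load_pathway_library(path)


def ora_enrich(
    selected: Iterable[str],
    library: PathwayLibrary,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric ORA, ascending by p (ties by pathway name).

    ``selected`` must be a subset of ``universe``; each pathway is
    intersected with the universe before testing.
    """
    sel = _norm(selected)
    uni = _norm(universe)
    if not uni:
        raise DataError("empty universe")
    if not sel <= uni:
        raise DataError("selected set must be a subset of the universe")
    N = len(uni)
    n = len(sel)
    out: list[EnrichmentResult] = []
    for name, members in library.pathways.items():
        in_uni = members & uni
        K = len(in_uni)
        k = len(in_uni & sel)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        out.append(EnrichmentResult(
            pathway=name, k_overlap=k, n_selected=n, K_pathway=K,
            N_universe=N, p_hyper=p, enriched=bool(p < alpha),
        ))
    out.sort(key=lambda r: (r.p_hyper, r.pathway))
    if out:
        qs = multipletests([r.p_hyper for r in out], method="fdr_bh")[1]
        for r, q in zip(out, qs):
            r.q_bh = float(q)
    return out
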