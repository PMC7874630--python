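"""End-to-end orchestration of the two headline analyses.

``run_state_comparison`` reproduces the sleep-state chain: preprocessing ->
PCA with the 95% Hotelling gate -> PLS-DA (3 components) with VIP, Q2 and a
label-permutation p -> enrichment of the top-5%-VIP metabolites -> pairwise
permutation/bootstrap fold-change contrasts with volcano classification and
Venn counts.

``run_consolidation_analysis`` runs, within each sleep-wake state, the
DS/IS, DS/CO and IS/CO contrasts, derives the consolidation set
(significant in DS/IS and not in IS/CO), and enriches it.

A single global seed is expanded into independent per-stage substreams, so
changing e.g. the number of PLS-DA permutations does not perturb the
bootstrap draws. Reports are plain JSON-serializable dicts embedding the
effective config.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import differential as diff
from .core_data import DataError, MetaboliteTable, preprocess
from .enrichment import PathwayLibrary, bundled_library, ora_enrich
from .multivariate import (
    hotelling_outliers,
    label_permutation_test,
    pca_fit,
    plsda_fit,
    q2_cross_validate,
    select_top_vip,
)


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    fc_threshold: float = 1.5
    n_perm: int = 10_000
    n_boot: int = 10_000
    plsda_components: int = 3
    plsda_perms: int = 1000
    vip_fraction: float = 0.05
    q2_folds: int = 10
    outlier_level: float = 0.95
    thresholds_s: dict = field(
        default_factory=lambda: {"REM": 60.0, "NREM": 300.0, "Wake": 300.0}
    )
    missing_policy: str = "half_min_impute"
    log_base: int | None = 10
    scaling: str | None = "autoscale"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DataError("alpha must be in (0, 1)")
        for name in ("fc_threshold", "n_perm", "n_boot", "plsda_components",
                     "plsda_perms", "vip_fraction", "q2_folds"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _result_rows(results) -> list[dict]:
    return [
        {
            "metabolite_id": r.metabolite_id,
            "ratio": r.ratio,
            "signed_fc": r.signed_fc,
            "p_perm": r.p_perm,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "significant": r.significant,
            "q_bh": r.q_bh,
        }
        for r in results
    ]


def _enrich_rows(results) -> list[dict]:
    return [
        {
            "pathway": r.pathway,
            "k_overlap": r.k_overlap,
            "n_selected": r.n_selected,
            "K_pathway": r.K_pathway,
            "N_universe": r.N_universe,
            "p_hyper": r.p_hyper,
            "enriched": r.enriched,
            "q_bh": r.q_bh,
        }
        for r in results
    ]


def _gate_outliers(table: MetaboliteTable, config: PipelineConfig) -> tuple[MetaboliteTable, list[str], dict]:
    """PCA on preprocessed data + Hotelling gate; returns (kept table, outliers, pca info)."""
    proc = preprocess(table, config.missing_policy, config.log_base, config.scaling)
    k = min(5, len(proc.sample_ids) - 1, len(proc.metabolite_ids))
    pca = pca_fit(proc, k=max(k, 2))
    outliers = sorted(hotelling_outliers(pca, level=config.outlier_level))
    kept = table
    if outliers:
        keep = [s for s in table.sample_ids if s not in set(outliers)]
        kept = table.subset(samples=keep)
    info = {
        "k": pca.k,
        "explained_variance_fraction": [float(v) for v in pca.explained_variance_fraction],
    }
    return kept, list(outliers), info


def run_state_comparison(
    table: MetaboliteTable,
    config: PipelineConfig | None = None,
    library: PathwayLibrary | None = None,
) -> dict:
    """Sleep-state analysis: PCA gate -> PLS-DA/VIP -> enrichment -> contrasts.

    The table must carry state annotations with >= 2 states present.
    """
    config = config or PipelineConfig()
    library = library or bundled_library()
    ss = np.random.SeedSequence(config.seed)
    s_q2, s_perm, s_diff = ss.spawn(3)

    try:
        kept, outliers, pca_info = _gate_outliers(table, config)
        states = [s for s in ("REM", "NREM", "Wake")
                  if (kept.annotations["state"] == s).sum() > 0]
        if len(states) < 2:
            raise DataError("need >= 2 sleep-wake states")
        proc = preprocess(kept, config.missing_policy, config.log_base, config.scaling)
        labels = kept.annotations["state"].tolist()
        model = plsda_fit(proc, labels, n_components=config.plsda_components)
        min_class = min(labels.count(s) for s in set(labels))
        model.q2 = q2_cross_validate(
            proc, labels, n_components=config.plsda_components,
            folds=min(config.q2_folds, min_class), seed=np.random.default_rng(s_q2),
        )
        model.perm_p = label_permutation_test(
            proc, labels, n_components=config.plsda_components,
            n_perm=config.plsda_perms, seed=np.random.default_rng(s_perm),
        )
        top = select_top_vip(model, fraction=config.vip_fraction)
        universe = proc.metabolite_ids
        enr = ora_enrich(top, library, universe, alpha=config.alpha)

        contrasts = [diff.state_contrast(a, b)
                     for a, b in itertools.combinations(states, 2)]
        diff_seeds = s_diff.spawn(len(contrasts))
        per_contrast: dict[str, dict] = {}
        sig_sets: dict[str, set] = {}
        for c, cseed in zip(contrasts, diff_seeds):
            res = diff.differential_analysis(
                kept, c, n_perm=config.n_perm, n_boot=config.n_boot,
                alpha=config.alpha, fc_threshold=config.fc_threshold, seed=cseed,
            )
            volcano = diff.classify_volcano(res, config.alpha, config.fc_threshold)
            sig_sets[c.name] = diff.significant_set(res)
            per_contrast[c.name] = {
                "results": _result_rows(res),
                "volcano": {k: sorted(v) for k, v in volcano.items()},
            }
        venn = {"|".join(k): v for k, v in diff.venn_counts(sig_sets).items()} \
            if len(sig_sets) >= 2 else {}
    except DataError as exc:
        raise DataError(f"state comparison failed: {exc}") from exc

    return {
        "config": config.to_dict(),
        "pca": pca_info,
        "outliers": outliers,
        "plsda": {
            "class_levels": model.class_levels,
            "r2y": float(model.r2y),
            "q2": float(model.q2),
            "perm_p": float(model.perm_p),
            "vip": {m: float(v) for m, v in zip(proc.metabolite_ids, model.vip)},
        },
        "top_vip": top,
        "enrichment": _enrich_rows(enr),
        "contrasts": per_contrast,
        "venn": venn,
    }


def run_consolidation_analysis(
    table: MetaboliteTable,
    config: PipelineConfig | None = None,
    library: PathwayLibrary | None = None,
) -> dict:
    """Within each state: PCA gate -> DS/IS, DS/CO, IS/CO -> consolidation set -> ORA."""
    config = config or PipelineConfig()
    library = library or bundled_library()
    ss = np.random.SeedSequence(config.seed)
    states = [s for s in ("REM", "NREM", "Wake")
              if (table.annotations["state"] == s).sum() > 0]
    state_seeds = ss.spawn(len(states))
    report: dict = {"config": config.to_dict(), "states": {}}
    for state, sseed in zip(states, state_seeds):
        sub = table.subset(
            samples=[s for s, st in zip(table.sample_ids, table.annotations["state"])
                     if st == state]
        )
        for proto in ("DS", "IS", "CO"):
            n = int((sub.annotations["protocol"] == proto).sum())
            if n < 3:
                raise DataError(
                    f"cell (state={state}, protocol={proto}) has {n} samples (< 3)"
                )
        kept, outliers, pca_info = _gate_outliers(sub, config)
        pairs = [("DS", "IS"), ("DS", "CO"), ("IS", "CO")]
        cseeds = sseed.spawn(len(pairs))
        per_contrast: dict[str, dict] = {}
        sig_sets: dict[str, set] = {}
        for (a, b), cseed in zip(pairs, cseeds):
            c = diff.protocol_contrast(a, b, state=state)
            res = diff.differential_analysis(
                kept, c, n_perm=config.n_perm, n_boot=config.n_boot,
                alpha=config.alpha, fc_threshold=config.fc_threshold, seed=cseed,
            )
            sig_sets[c.name] = diff.significant_set(res)
            per_contrast[c.name] = {
                "results": _result_rows(res),
                "significant": sorted(sig_sets[c.name]),
            }
        cons = diff.consolidation_set(sig_sets)
        universe = kept.metabolite_ids
        enr = ora_enrich(
            [m for m in cons], library, universe, alpha=config.alpha
        ) if cons else []
        report["states"][state] = {
            "pca": pca_info,
            "outliers": outliers,
            "contrasts": per_contrast,
            "consolidation_set": sorted(cons),
            "enrichment": _enrich_rows(enr),
        }
    return report


def report_to_json(report: Mapping) -> str:
    """Canonical JSON (sorted keys) so identical seeds give identical bytes."""
    return json.dumps(report, sort_keys=True, indent=2)
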