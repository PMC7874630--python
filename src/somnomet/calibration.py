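"""Calibration runs for the resampling machinery.

These functions measure, by simulation at the study's group sizes and noise
level (two groups of 10, log-normal noise with cv 0.2), the operating
characteristics the analysis relies on: the type-I error of the permutation
fold-change test at the 0.05 threshold, the coverage of the 95% bootstrap
ratio CI, and the detectability of a planted multi-metabolite group effect
by the PLS-DA label-permutation test.
"""

from __future__ import annotations

import numpy as np

from .core_data import preprocess
from .differential import bootstrap_ci, permutation_pvalue
from .multivariate import label_permutation_test
from .synthetic import MetabolomeSimSpec, simulate_metabolome


def _child_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def permutation_type_one_error(
    n_datasets: int = 2000,
    n_per_group: int = 10,
    cv: float = 0.2,
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the permutation test under the null.

    Each dataset is one metabolite simulated with no planted effect; the
    fraction of datasets with p < alpha estimates the type-I error.
    """
    seeds = _child_seeds(seed, 2 * n_datasets)
    rejected = 0
    for i in range(n_datasets):
        table, _ = simulate_metabolome(MetabolomeSimSpec(
            n_metabolites=1, group_sizes={"REM": n_per_group, "Wake": n_per_group},
            cv_noise=cv, seed=int(seeds[2 * i]),
        ))
        a = table.abundances[:n_per_group, 0]
        b = table.abundances[n_per_group:, 0]
        p = permutation_pvalue(a, b, n_perm=n_perm, seed=int(seeds[2 * i + 1]))
        rejected += p < alpha
    return rejected / n_datasets


def bootstrap_coverage_percent(
    n_datasets: int = 2000,
    true_ratio: float = 1.5,
    n_per_group: int = 10,
    cv: float = 0.2,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> float:
    """Percent of bootstrap CIs containing the known true mean ratio."""
    seeds = _child_seeds(seed, 2 * n_datasets)
    covered = 0
    for i in range(n_datasets):
        table, _ = simulate_metabolome(MetabolomeSimSpec(
            n_metabolites=1, group_sizes={"REM": n_per_group, "Wake": n_per_group},
            planted_effects={("M0001", "REM"): true_ratio},
            cv_noise=cv, seed=int(seeds[2 * i]),
        ))
        a = table.abundances[:n_per_group, 0]
        b = table.abundances[n_per_group:, 0]
        lo, hi = bootstrap_ci(a, b, n_boot=n_boot, level=level,
                              seed=int(seeds[2 * i + 1]))
        covered += lo <= true_ratio <= hi
    return 100.0 * covered / n_datasets


def plsda_separation_pvalue(
    n_metabolites: int = 200,
    n_planted: int = 30,
    effect: float = 1.8,
    n_per_group: int = 10,
    cv: float = 0.2,
    n_components: int = 3,
    n_perm: int = 1000,
    seed: int = 42,
) -> float:
    """Label-permutation p of PLS-DA separation on a planted two-group table."""
    planted = {(f"M{j + 1:04d}", "REM"): effect for j in range(n_planted)}
    table, _ = simulate_metabolome(MetabolomeSimSpec(
        n_metabolites=n_metabolites,
        group_sizes={"REM": n_per_group, "Wake": n_per_group},
        planted_effects=planted, cv_noise=cv, seed=seed,
    ))
    proc = preprocess(table)
    return label_permutation_test(
        proc, table.annotations["state"].tolist(),
        n_components=n_components, n_perm=n_perm, seed=seed,
    )
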