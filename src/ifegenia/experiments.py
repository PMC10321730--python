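"""Simulation campaigns: release-scheme grids, sensitivity, resistance.

Desk-scale drivers over the lifecycle simulator:

* ``sweep_release_grid`` — ensembles over (number of weekly releases ×
  eggs per adult), reporting elimination probability and window of
  protection per grid cell, with common random numbers across cells;
* ``sensitivity_analysis`` — mean window of protection as genetic
  parameters (cutting rate, deposition rate, male mating weight) vary
  around a protective base scheme;
* ``resistance_experiment`` — functional-resistant allele frequency
  trajectories as the number of gRNA target sites varies at fixed
  resistant-repair probability.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .inheritance import GeneticParams, build_cube
from .lifecycle import LifeHistoryParams, calibrate, run, replicate_rng
from .metrics import ensemble_summary
from .release import ReleaseScheme, schedule

__all__ = [
    "run_scheme_ensemble",
    "sweep_release_grid",
    "sensitivity_analysis",
    "resistance_experiment",
    "DEFAULT_RELEASE_COUNTS",
    "DEFAULT_RELEASE_SIZES",
]

#: default desk-scale grid (the full 52×50 grid is config-reachable)
DEFAULT_RELEASE_COUNTS = (1, 8, 16, 23, 27, 52)
DEFAULT_RELEASE_SIZES = (10, 100, 200, 300, 400, 500)


def run_scheme_ensemble(
    scheme: ReleaseScheme,
    genetics: GeneticParams,
    life: LifeHistoryParams,
    horizon: int,
    reps: int,
    master_seed: int,
    cube=None,
    cal=None,
):
    """Stochastic replicate ensemble for one release scheme.

    Replicate ``k`` always uses the stream keyed (master_seed, k), so
    ensembles sharing a master seed are coupled by common random numbers.
    """
    cube = cube or build_cube(genetics)
    cal = cal or calibrate(life)
    sched = schedule(scheme, life.N_eq, cube, genetics)
    return [
        run(cube, cal, horizon, sched, rng=replicate_rng(master_seed, k))
        for k in range(reps)
    ]


def sweep_release_grid(
    release_counts=DEFAULT_RELEASE_COUNTS,
    release_sizes=DEFAULT_RELEASE_SIZES,
    genetics: GeneticParams | None = None,
    life: LifeHistoryParams | None = None,
    horizon: int = 6 * 365,
    reps: int = 30,
    seed: int = 1,
) -> pd.DataFrame:
    """Ensemble outcomes for every (n_releases, eggs_per_adult) grid cell."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    genetics = genetics or GeneticParams()
    life = life or LifeHistoryParams()
    cube = build_cube(genetics)
    cal = calibrate(life)
    rows = []
    for n_rel in release_counts:
        for size in release_sizes:
            trajs = run_scheme_ensemble(
                ReleaseScheme(int(n_rel), float(size)),
                genetics,
                life,
                horizon,
                reps,
                seed,
                cube=cube,
                cal=cal,
            )
            s = ensemble_summary(trajs, life.N_eq)
            rows.append(
                {
                    "n_releases": int(n_rel),
                    "eggs_per_adult": float(size),
                    "reps": reps,
                    "elimination_probability": s.elimination_probability,
                    "elimination_ci_low": s.elimination_ci[0],
                    "elimination_ci_high": s.elimination_ci[1],
                    "protected_fraction": s.protected_fraction,
                    "median_window_days": s.median_window_days,
                    "mean_final_adults": float(
                        np.mean([t.adults[-1] for t in trajs])
                    ),
                }
            )
    return pd.DataFrame(rows)


def sensitivity_analysis(
    base_scheme: ReleaseScheme,
    grids: dict[str, list[float]] | None = None,
    genetics: GeneticParams | None = None,
    life: LifeHistoryParams | None = None,
    horizon: int = 6 * 365,
    reps: int = 20,
    seed: int = 1,
) -> pd.DataFrame:
    """Mean window of protection as genetic parameters vary one at a time.

    ``grids`` maps parameter name (``cut_rate``, ``deposition_rate``,
    ``male_mating_weight_transgenic``) to the values to scan; the base
    scheme should sit inside the protective region so the window is the
    informative outcome.
    """
    genetics = genetics or GeneticParams()
    life = life or LifeHistoryParams()
    if grids is None:
        grids = {
            "cut_rate": [0.8, 0.9, 1.0],
            "deposition_rate": [0.8, 0.9, 1.0],
            "male_mating_weight_transgenic": [0.5, 0.75, 1.0],
        }
    cal = calibrate(life)
    rows = []
    for name, values in grids.items():
        for v in values:
            g = replace(genetics, **{name: float(v)})
            trajs = run_scheme_ensemble(
                base_scheme, g, life, horizon, reps, seed, cal=cal
            )
            s = ensemble_summary(trajs, life.N_eq)
            windows = s.windows
            rows.append(
                {
                    "parameter": name,
                    "value": float(v),
                    "reps": reps,
                    "mean_window_days": float(windows.mean()),
                    "window_se": float(windows.std(ddof=1) / np.sqrt(len(windows))),
                    "median_window_days": s.median_window_days,
                    "elimination_probability": s.elimination_probability,
                }
            )
    return pd.DataFrame(rows)


def resistance_experiment(
    n_sites_list=(1, 2, 3),
    rho: float = 0.01,
    scheme: ReleaseScheme | None = None,
    genetics: GeneticParams | None = None,
    life: LifeHistoryParams | None = None,
    horizon: int = 365,
    reps: int = 5,
    seed: int = 1,
) -> pd.DataFrame:
    """Resistant-allele spread versus the number of gRNA target sites.

    For each site count, runs ensembles with resistant repair at ``rho``
    and records the per-day population frequency of fully
    functional-resistant target alleles; more multiplexed sites require
    every site to repair functionally, suppressing resistance spread.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0 for a resistance experiment")
    genetics = genetics or GeneticParams()
    life = life or LifeHistoryParams()
    scheme = scheme or ReleaseScheme(8, 100.0)
    cal = calibrate(life)
    rows = []
    for n_sites in n_sites_list:
        g = replace(genetics, n_sites=int(n_sites), functional_repair=float(rho))
        cube = build_cube(g, dense=False)
        trajs = run_scheme_ensemble(
            scheme, g, life, horizon, reps, seed, cube=cube, cal=cal
        )
        for k, t in enumerate(trajs):
            alive = t.total > 0
            final_freq = float(t.resistant_fraction[alive][-1]) if alive.any() else 0.0
            rows.append(
                {
                    "n_sites": int(n_sites),
                    "replicate": k,
                    "final_resistant_frequency": final_freq,
                    "max_resistant_frequency": float(t.resistant_fraction.max()),
                    "final_adults": float(t.adults[-1]),
                }
            )
    return pd.DataFrame(rows)
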