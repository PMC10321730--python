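"""Outcome measures over trajectories and replicate ensembles.

* elimination — the population hits zero across all life stages and
  genotypes and stays there through the horizon;
* suppression — daily adult count relative to the pre-release
  equilibrium;
* window of protection — the longest contiguous run of days with the
  population suppressed by at least the threshold (90% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .lifecycle import Trajectory

__all__ = [
    "OutcomeSummary",
    "elimination_day",
    "window_of_protection",
    "ensemble_summary",
    "TWO_YEARS",
]

#: "protected for at least two years" cutoff, in days
TWO_YEARS = 730


def elimination_day(traj: Trajectory) -> int | None:
    """First day the total population is zero and remains zero.

    The census includes every life stage and genotype, so a zero-adult
    day with juveniles still developing does not count.  Pending releases
    re-seed the egg stage and therefore push elimination past the final
    release by construction.
    """
    zero = traj.total == 0.0
    if not zero[-1]:
        return None
    # last day with anybody alive
    alive = np.nonzero(~zero)[0]
    if alive.size == 0:
        first = 0
    else:
        first = int(alive[-1]) + 1
    if traj.release_days.size and first <= traj.release_days.max():
        return None
    return int(traj.days[first])


def window_of_protection(
    traj: Trajectory, baseline: float, threshold: float = 0.90
) -> int:
    """Longest contiguous run of days with adults <= (1-threshold)*baseline.

    Eliminated runs count as suppressed through the horizon end.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    suppressed = traj.adults <= (1.0 - threshold) * baseline
    best = cur = 0
    for s in suppressed:
        cur = cur + 1 if s else 0
        if cur > best:
            best = cur
    return int(best)


@dataclass
class OutcomeSummary:
    """Ensemble-level outcomes with exact binomial 95% CIs (percent)."""

    n_replicates: int
    elimination_probability: float  # percent of replicates eliminated
    elimination_ci: tuple[float, float]
    median_elimination_day: float | None
    protected_fraction: float  # percent with window of protection >= 2 years
    protected_ci: tuple[float, float]
    median_window_days: float
    windows: np.ndarray
    elimination_days: list


def _pct_ci(k: int, n: int) -> tuple[float, float]:
    ci = binomtest(k, n).proportion_ci(confidence_level=0.95)
    return (100.0 * ci.low, 100.0 * ci.high)


def ensemble_summary(
    trajectories: list[Trajectory],
    baseline: float,
    threshold: float = 0.90,
    protected_days: int = TWO_YEARS,
) -> OutcomeSummary:
    """Elimination probability and window-of-protection summary of an ensemble."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    n = len(trajectories)
    elim_days = [elimination_day(t) for t in trajectories]
    n_elim = sum(d is not None for d in elim_days)
    windows = np.array(
        [window_of_protection(t, baseline, threshold) for t in trajectories]
    )
    n_prot = int((windows >= protected_days).sum())
    observed = [d for d in elim_days if d is not None]
    return OutcomeSummary(
        n_replicates=n,
        elimination_probability=100.0 * n_elim / n,
        elimination_ci=_pct_ci(n_elim, n),
        median_elimination_day=float(np.median(observed)) if observed else None,
        protected_fraction=100.0 * n_prot / n,
        protected_ci=_pct_ci(n_prot, n),
        median_window_days=float(np.median(windows)),
        windows=windows,
        elimination_days=elim_days,
    )
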