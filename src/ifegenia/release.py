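"""Weekly egg-release schedules and release genotypes.

Releases are eggs of the trans-heterozygous system genotype (one gRNA
copy, one Cas9 copy, both target alleles fully loss-of-function), sexed
1/2 : 1/2 — eggs cannot be sexed, and released females self-remove
through the female-viability phenotype.  Release size is scaled to the
pre-release equilibrium adult count, constant across the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inheritance import GeneticParams, Genotype, InheritanceCube, lof_allele

__all__ = ["ReleaseScheme", "ifegenia_release_mix", "release_vector", "schedule"]


@dataclass(frozen=True)
class ReleaseScheme:
    """Weekly release cadence: ``n_releases`` releases of
    ``eggs_per_adult`` eggs per pre-release wild adult, starting on
    ``first_day`` and repeating every 7 days."""

    n_releases: int = 0
    eggs_per_adult: float = 0.0
    first_day: int = 0

    def __post_init__(self) -> None:
        if self.n_releases < 0:
            raise ValueError("n_releases must be >= 0")
        if self.eggs_per_adult < 0:
            raise ValueError("eggs_per_adult must be >= 0")
        if self.first_day < 0:
            raise ValueError("first_day must be >= 0")

    @property
    def last_day(self) -> int:
        if self.n_releases == 0:
            return -1
        return self.first_day + 7 * (self.n_releases - 1)


def release_genotype(params: GeneticParams) -> Genotype:
    """The released genotype: g1 c1 with both target alleles all-LOF."""
    a = lof_allele(params.n_sites)
    return Genotype(1, 1, (a, a))


def ifegenia_release_mix(params: GeneticParams) -> dict[tuple[Genotype, str], float]:
    """Distribution over (genotype, sex) of released eggs: 1/2 : 1/2 sexes
    of the trans-heterozygous all-LOF genotype (identical for pgSIT; the
    phenotype rules differ, not the released genotype)."""
    geno = release_genotype(params)
    return {(geno, "M"): 0.5, (geno, "F"): 0.5}


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` into integer parts proportional to ``weights``."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(np.int64)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(exact - base))
        base[order[:short]] += 1
    return base


def release_vector(cube: InheritanceCube, params: GeneticParams, n_eggs: int) -> np.ndarray:
    """``n_eggs`` released eggs as a per-genotype count vector.

    Eggs are unsexed in the simulator state (sex is assigned at pupation
    at 1/2 : 1/2, matching the release mix), so the mix's two sex classes
    collapse onto one genotype entry.
    """
    mix = ifegenia_release_mix(params)
    geno_weights: dict[Genotype, float] = {}
    for (geno, _sex), w in mix.items():
        geno_weights[geno] = geno_weights.get(geno, 0.0) + w
    genos = sorted(geno_weights)
    counts = _largest_remainder(
        np.array([geno_weights[g] for g in genos]), int(n_eggs)
    )
    out = np.zeros(cube.n)
    for geno, c in zip(genos, counts):
        out[cube.index[geno]] = c
    return out


def schedule(
    scheme: ReleaseScheme,
    N_eq: int,
    cube: InheritanceCube,
    params: GeneticParams,
) -> dict[int, np.ndarray]:
    """Map day → released-egg vector for a weekly scheme.

    Each release day receives ``round(eggs_per_adult * N_eq)`` eggs split
    by the release mix with largest-remainder rounding.
    """
    per_release = int(round(scheme.eggs_per_adult * N_eq))
    if scheme.n_releases == 0 or per_release == 0:
        return {}
    vec = release_vector(cube, params, per_release)
    return {
        scheme.first_day + 7 * k: vec.copy() for k in range(scheme.n_releases)
    }
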