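"""Stage-structured *Anopheles gambiae* population dynamics.

Daily-time-step egg → larva → pupa → adult dynamics with

* density-independent daily juvenile mortality ``mu_juv``, calibrated so
  that lifetime offspring production per female in the absence of density
  dependence equals the per-generation growth rate ``Rm``;
* Beverton–Holt-style density-dependent larval mortality, with the daily
  larval survival factor ``F(L) = (alpha / (alpha + L)) ** (1 / T_l)``
  applied on top of ``mu_juv`` (``alpha`` calibrated so the all-wild-type
  population is stationary at ``N_eq`` adults);
* once-mated females that retain their mate's genotype for life;
* genotype-dependent female viability, male fertility and male mating
  competitiveness taken from an :class:`~ifegenia.inheritance.InheritanceCube`;
* stochastic (binomial survival, Poisson oviposition, multinomial mating)
  or deterministic (mean-field) stepping with identical structure.

Daily step order: adult survival → pupal emergence and mating →
oviposition → egg releases → stage ageing (with unviable females removed
at the larva→pupa transition by default, after competing as larvae).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .inheritance import InheritanceCube

__all__ = [
    "LifeHistoryParams",
    "Calibration",
    "PopulationState",
    "Trajectory",
    "InfeasibleParams",
    "calibrate",
    "equilibrium_state",
    "step_day",
    "run",
    "run_ensemble",
    "replicate_rng",
]


class InfeasibleParams(ValueError):
    """Raised when no juvenile mortality in (0, 1) satisfies the growth rate."""


@dataclass(frozen=True)
class LifeHistoryParams:
    """Life-history parameters of the target population.

    beta
        Eggs laid per adult female per day.
    T_e, T_l, T_p
        Egg, larval and pupal stage durations in days.
    mu_ad
        Daily adult mortality probability.
    Rm
        Per-generation population growth rate in the absence of
        density-dependent mortality (net reproductive number).
    N_eq
        Equilibrium adult population size (both sexes) before releases.
    unviable_female_stage
        When genotypically unviable females are removed: at the
        larva→pupa transition (``"pupation"``, default — they compete for
        larval resources first) or on hatching (``"hatch"``).
    """

    beta: float = 32.0
    T_e: int = 3
    T_l: int = 7
    T_p: int = 1
    mu_ad: float = 0.123
    Rm: float = 3.0
    N_eq: int = 10_000
    unviable_female_stage: str = "pupation"

    def __post_init__(self) -> None:
        for name in ("T_e", "T_l", "T_p"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if not 0.0 < self.mu_ad < 1.0:
            raise ValueError("mu_ad must be in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.Rm < 1.0:
            raise ValueError("Rm must be >= 1")
        if self.N_eq <= 0:
            raise ValueError("N_eq must be positive")
        if self.unviable_female_stage not in ("pupation", "hatch"):
            raise ValueError("unviable_female_stage must be 'pupation' or 'hatch'")

    @property
    def juvenile_days(self) -> int:
        return self.T_e + self.T_l + self.T_p


def solve_juvenile_mortality(life: LifeHistoryParams) -> float:
    """Density-independent daily juvenile mortality consistent with ``Rm``.

    A newly emerged female lays ``beta`` eggs per day over an expected
    ``1 / mu_ad`` laying days (she lays on her emergence day), half of
    which are daughters.  Density-independent replacement at rate ``Rm``
    therefore requires total juvenile survival

        (1 - mu_juv) ** (T_e + T_l + T_p) = 2 * Rm * mu_ad / beta.
    """
    total = 2.0 * life.Rm * life.mu_ad / life.beta
    if not 0.0 < total < 1.0:
        raise InfeasibleParams(
            f"required total juvenile survival {total:.4f} outside (0, 1): "
            f"2*Rm*mu_ad/beta with Rm={life.Rm}, mu_ad={life.mu_ad}, "
            f"beta={life.beta}"
        )
    return 1.0 - total ** (1.0 / life.juvenile_days)


@dataclass(frozen=True)
class Calibration:
    """Life-history parameters plus derived mortality/density constants."""

    life: LifeHistoryParams
    mu_juv: float
    alpha: float  # larval density-dependence strength; inf = no density dependence

    #: wild-type equilibrium age profiles (single-genotype), set by calibrate()
    eq_eggs: np.ndarray = field(default=None, repr=False)
    eq_larvae: np.ndarray = field(default=None, repr=False)
    eq_pupae: np.ndarray = field(default=None, repr=False)
    eq_males: float = 0.0
    eq_females: float = 0.0


@dataclass
class PopulationState:
    """Counts per life stage, age-in-stage and genotype.

    Adult females are keyed by (own genotype, mate genotype); ``virgin``
    holds females that emerged on a day with no adult males and therefore
    never reproduce.  Eggs and larvae are unsexed; sex is assigned at the
    larva→pupa transition (1/2 : 1/2, independent of genotype).
    """

    eggs: np.ndarray  # (T_e, G)
    larvae: np.ndarray  # (T_l, G)
    pupae: np.ndarray  # (T_p, 2, G)  axis 1: 0=male, 1=female
    males: np.ndarray  # (G,)
    females: np.ndarray  # (G_own, G_mate)
    virgin: np.ndarray  # (G,)
    day: int = 0

    @staticmethod
    def empty(life: LifeHistoryParams, n_genotypes: int) -> "PopulationState":
        G = n_genotypes
        return PopulationState(
            eggs=np.zeros((life.T_e, G)),
            larvae=np.zeros((life.T_l, G)),
            pupae=np.zeros((life.T_p, 2, G)),
            males=np.zeros(G),
            females=np.zeros((G, G)),
            virgin=np.zeros(G),
        )

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.eggs.copy(),
            self.larvae.copy(),
            self.pupae.copy(),
            self.males.copy(),
            self.females.copy(),
            self.virgin.copy(),
            self.day,
        )

    @property
    def adult_females(self) -> np.ndarray:
        return self.females.sum(axis=1) + self.virgin

    @property
    def adults(self) -> float:
        return float(self.males.sum() + self.females.sum() + self.virgin.sum())

    def genotype_totals(self) -> np.ndarray:
        """Living individuals per genotype, all stages (mates not counted)."""
        return (
            self.eggs.sum(axis=0)
            + self.larvae.sum(axis=0)
            + self.pupae.sum(axis=(0, 1))
            + self.males
            + self.adult_females
        )

    @property
    def total(self) -> float:
        return float(self.genotype_totals().sum())


# ---------------------------------------------------------------------------
# sampling helpers: expectations in deterministic mode, draws otherwise


def _binom(rng, n: np.ndarray, p) -> np.ndarray:
    if rng is None:
        return n * p
    return rng.binomial(np.asarray(np.rint(n), dtype=np.int64), p).astype(float)


def _poisson(rng, lam: np.ndarray) -> np.ndarray:
    if rng is None:
        return lam
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# the daily step


def step_day(
    state: PopulationState,
    cube: InheritanceCube,
    cal: Calibration,
    rng: np.random.Generator | None = None,
    releases_today: np.ndarray | None = None,
) -> PopulationState:
    """Advance the population by one day in place; returns ``state``.

    ``rng=None`` runs the deterministic (mean-field) step; otherwise all
    survival is binomial, egg counts Poisson and mate choice multinomial.
    ``releases_today`` is a length-G vector of eggs appended to the age-0
    egg cohort.
    """
    life = cal.life
    s_juv = 1.0 - cal.mu_juv

    # (1) adult survival
    p_surv = 1.0 - life.mu_ad
    state.males = _binom(rng, state.males, p_surv)
    state.virgin = _binom(rng, state.virgin, p_surv)
    nz = state.females.nonzero()
    if nz[0].size:
        surv = _binom(rng, state.females[nz], p_surv)
        state.females = np.zeros_like(state.females)
        state.females[nz] = surv

    # (2) emergence and mating (newly emerged males join the pool first)
    emerging = _binom(rng, state.pupae[life.T_p - 1], s_juv)
    new_males, new_females = emerging[0], emerging[1]
    state.males = state.males + new_males
    weights = state.males * cube.mating_weight
    w_total = weights.sum()
    if w_total > 0.0:
        probs = weights / w_total
        if rng is None:
            state.females += np.outer(new_females, probs)
        else:
            for g in np.nonzero(new_females)[0]:
                state.females[g] += rng.multinomial(int(new_females[g]), probs)
    else:
        state.virgin = state.virgin + new_females

    # (3) oviposition (matings with infertile fathers produce nothing);
    # per-female Poisson(beta) split by the cube slice is equivalent to
    # independent Poisson egg counts per offspring genotype
    lam = state.females * (life.beta * cube.male_fertile)[np.newaxis, :]
    if cube.dense is not None:
        egg_rate = np.einsum("fm,fmg->g", lam, cube.dense)
    else:
        egg_rate = np.zeros(cube.n)
        fi, mi = lam.nonzero()
        for f, m in zip(fi, mi):
            egg_rate += lam[f, m] * cube.slice(f, m)
    new_eggs = _poisson(rng, egg_rate)

    # (4) releases join the age-0 egg cohort
    if releases_today is not None:
        new_eggs = new_eggs + releases_today

    # (5) stage ageing
    # pupae age with survival (the final juvenile draw happens at emergence)
    if life.T_p > 1:
        state.pupae[1:] = _binom(rng, state.pupae[:-1], s_juv)

    # larvae: density acts on the total larval census, transgenic included
    L_total = state.larvae.sum()
    if np.isinf(cal.alpha):
        F = 1.0
    else:
        F = (cal.alpha / (cal.alpha + L_total)) ** (1.0 / life.T_l)
    larv_surv = _binom(rng, state.larvae, s_juv * F)
    pupating = larv_surv[life.T_l - 1]
    new_pupae_m = _binom(rng, pupating, 0.5)
    new_pupae_f = pupating - new_pupae_m
    if life.unviable_female_stage == "pupation":
        new_pupae_f = new_pupae_f * cube.female_viable
    else:  # females of unviable genotypes were already removed at hatch
        unviable = cube.female_viable == 0.0
        new_pupae_m = np.where(unviable, pupating, new_pupae_m)
        new_pupae_f = np.where(unviable, 0.0, new_pupae_f)
    state.pupae[0] = np.stack([new_pupae_m, new_pupae_f])
    state.larvae[1:] = larv_surv[:-1]

    # eggs
    egg_surv = _binom(rng, state.eggs, s_juv)
    hatch = egg_surv[life.T_e - 1]
    if life.unviable_female_stage == "hatch":
        # remove the female half of hatching unviable genotypes
        unviable = cube.female_viable == 0.0
        males_only = _binom(rng, hatch, 0.5)
        hatch = np.where(unviable, males_only, hatch)
    state.larvae[0] = hatch
    state.eggs[1:] = egg_surv[:-1]
    state.eggs[0] = new_eggs

    state.day += 1
    return state


# ---------------------------------------------------------------------------
# calibration


class _WTCube:
    """Single-genotype wild-type stand-in cube used during calibration."""

    n = 1

    def __init__(self) -> None:
        self.female_viable = np.ones(1)
        self.male_fertile = np.ones(1)
        self.mating_weight = np.ones(1)
        self.dense = np.ones((1, 1, 1))
        self.is_transgenic = np.zeros(1, dtype=bool)
        self.resistant_alleles = np.zeros(1)
        self.lof_alleles = np.zeros(1)
        self.wt_index = 0


def _wt_fixed_point(
    cal: Calibration, max_days: int = 4000, tol: float = 1e-12
) -> PopulationState:
    """Deterministic wild-type fixed point of the daily step."""
    life = cal.life
    cube = _WTCube()
    state = PopulationState.empty(life, 1)
    # rough seed near the expected equilibrium scale
    A0 = float(life.N_eq)
    state.males[0] = A0 / 2
    state.females[0, 0] = A0 / 2
    eggs0 = A0 / 2 * life.beta
    state.eggs[:, 0] = eggs0
    state.larvae[:, 0] = eggs0 * (1 - cal.mu_juv) ** life.T_e / 2
    state.pupae[:, :, 0] = A0 * life.mu_ad / 2
    prev = state.adults
    for day in range(max_days):
        step_day(state, cube, cal)
        cur = state.adults
        if day > 10 * life.juvenile_days and abs(cur - prev) <= tol * max(cur, 1.0):
            break
        prev = cur
    return state


@lru_cache(maxsize=64)
def calibrate(life: LifeHistoryParams) -> Calibration:
    """Solve ``mu_juv`` and the larval density parameter ``alpha``.

    ``alpha`` is found by root-finding so that the deterministic
    wild-type fixed point of the actual daily step sits at ``N_eq``
    adults; the returned calibration carries the equilibrium age
    profiles for seeding simulations.
    """
    mu_juv = solve_juvenile_mortality(life)

    # analytic guess: stationarity needs a lifetime density factor 1/Rm,
    # i.e. alpha / (alpha + L*) = 1/Rm with L* the equilibrium larval census
    daily_eggs = life.N_eq / 2.0 * life.beta
    hatch = daily_eggs * (1.0 - mu_juv) ** life.T_e
    L_star = hatch * sum(
        ((1.0 - mu_juv) * life.Rm ** (-1.0 / life.T_l)) ** a for a in range(life.T_l)
    )
    if life.Rm == 1.0:
        cal = Calibration(life, mu_juv, np.inf)
        eq = _wt_fixed_point(cal)
    else:
        alpha0 = L_star / (life.Rm - 1.0)

        def excess(log_alpha: float) -> float:
            cal = Calibration(life, mu_juv, float(np.exp(log_alpha)))
            return _wt_fixed_point(cal).adults - life.N_eq

        lo, hi = np.log(alpha0) - 4.0, np.log(alpha0) + 4.0
        while excess(lo) > 0:
            lo -= 2.0
        while excess(hi) < 0:
            hi += 2.0
        log_alpha = brentq(excess, lo, hi, xtol=1e-12, rtol=1e-14)
        cal = Calibration(life, mu_juv, float(np.exp(log_alpha)))
        eq = _wt_fixed_point(cal)

    return replace(
        cal,
        eq_eggs=eq.eggs[:, 0].copy(),
        eq_larvae=eq.larvae[:, 0].copy(),
        eq_pupae=eq.pupae[:, :, 0].copy(),
        eq_males=float(eq.males[0]),
        eq_females=float(eq.females[0, 0]),
    )


def equilibrium_state(
    cal: Calibration, cube: InheritanceCube, integer: bool = False
) -> PopulationState:
    """Embed the calibrated wild-type equilibrium into ``cube``'s space."""
    state = PopulationState.empty(cal.life, cube.n)
    wt = cube.wt_index
    state.eggs[:, wt] = cal.eq_eggs
    state.larvae[:, wt] = cal.eq_larvae
    state.pupae[:, :, wt] = cal.eq_pupae
    state.males[wt] = cal.eq_males
    state.females[wt, wt] = cal.eq_females
    if integer:
        for arr in (state.eggs, state.larvae, state.pupae, state.males, state.females):
            np.rint(arr, out=arr)
    return state


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Daily records of one simulation run."""

    days: np.ndarray
    adults: np.ndarray  # total adults (both sexes)
    adult_females: np.ndarray
    total: np.ndarray  # all stages, all genotypes
    adults_by_genotype: np.ndarray  # (D, G)
    transgenic_adults: np.ndarray
    resistant_fraction: np.ndarray  # fully resistant alleles / all target alleles
    genotypes: list
    release_days: np.ndarray
    final_state: PopulationState

    def __len__(self) -> int:
        return len(self.days)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": self.days,
                "adults": self.adults,
                "adult_females": self.adult_females,
                "total_population": self.total,
                "transgenic_adults": self.transgenic_adults,
                "resistant_allele_fraction": self.resistant_fraction,
            }
        )


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Replicate ``k``'s stream, invariant to the total replicate count."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(replicate,))
    return np.random.default_rng(ss)


def run(
    cube: InheritanceCube,
    cal: Calibration,
    horizon: int,
    schedule: dict[int, np.ndarray] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    deterministic: bool = False,
    initial_state: PopulationState | None = None,
) -> Trajectory:
    """Simulate ``horizon`` days from the wild-type equilibrium.

    ``schedule`` maps day → length-G egg-release vector.  Exactly one of
    ``seed``/``rng`` may be given for stochastic runs; ``deterministic``
    runs the mean-field model.  Once the population is extinct and no
    releases remain, the remaining days are filled with zeros.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    schedule = schedule or {}
    if schedule and max(schedule) >= horizon:
        raise ValueError(
            f"horizon {horizon} ends before the last release day {max(schedule)}"
        )
    if deterministic:
        gen = None
    else:
        if rng is None:
            gen = np.random.default_rng(seed)
        else:
            gen = rng

    if initial_state is not None:
        state = initial_state.copy()
    else:
        state = equilibrium_state(cal, cube, integer=not deterministic)

    D = horizon
    days = np.arange(D)
    adults = np.zeros(D)
    adult_females = np.zeros(D)
    total = np.zeros(D)
    adults_by_geno = np.zeros((D, cube.n))
    transgenic_adults = np.zeros(D)
    resistant_fraction = np.zeros(D)
    last_release = max(schedule) if schedule else -1

    for t in range(D):
        step_day(state, cube, cal, rng=gen, releases_today=schedule.get(t))
        geno_tot = state.genotype_totals()
        pop = float(geno_tot.sum())
        adults_g = state.males + state.adult_females
        adults[t] = adults_g.sum()
        adult_females[t] = state.adult_females.sum()
        total[t] = pop
        adults_by_geno[t] = adults_g
        transgenic_adults[t] = adults_g[cube.is_transgenic].sum()
        if pop > 0:
            resistant_fraction[t] = float(
                (geno_tot * cube.resistant_alleles).sum() / (2.0 * pop)
            )
        if pop == 0.0 and t >= last_release:
            break  # extinction is absorbing; remaining days stay zero

    return Trajectory(
        days=days,
        adults=adults,
        adult_females=adult_females,
        total=total,
        adults_by_genotype=adults_by_geno,
        transgenic_adults=transgenic_adults,
        resistant_fraction=resistant_fraction,
        genotypes=list(cube.genotypes) if hasattr(cube, "genotypes") else [],
        release_days=np.array(sorted(schedule), dtype=int),
        final_state=state,
    )


def run_ensemble(
    cube: InheritanceCube,
    cal: Calibration,
    horizon: int,
    schedule: dict[int, np.ndarray] | None,
    reps: int,
    master_seed: int,
) -> list[Trajectory]:
    """Independent stochastic replicates with substreams of ``master_seed``.

    Replicate ``k`` always receives the same stream regardless of
    ``reps``, enabling common-random-number comparisons across scenarios.
    """
    return [
        run(cube, cal, horizon, schedule, rng=replicate_rng(master_seed, k))
        for k in range(reps)
    ]
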