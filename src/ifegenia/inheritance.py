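"""Inheritance model for binary CRISPR female-killing and pgSIT systems.

The genetic system consists of two independently segregating autosomal
transgenes — a gRNA cassette targeting a female-essential gene
(*femaleless*, ``fle``) and a Cas9 source — plus the endogenous target
locus carrying 1–3 gRNA cut sites per allele.  Individuals carrying at
least one copy of each transgene cut wild-type target sites in their
germline; mothers carrying both transgenes additionally deposit Cas9
into embryos, where remaining wild sites can be cut zygotically.  A cut
site repairs either to a loss-of-function (LOF) lesion or, with a small
probability, to a functional sequence-changed site that can no longer be
cut ("functional-resistant").

The central object is the inheritance cube: for every (mother, father)
genotype pair, the probability distribution over offspring genotypes,
together with genotype→phenotype vectors (female viability, male
fertility, male mating weight) used by the population simulator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import lru_cache

import numpy as np

__all__ = [
    "System",
    "GeneticParams",
    "TargetAllele",
    "Genotype",
    "Phenotype",
    "InheritanceCube",
    "enumerate_target_alleles",
    "enumerate_genotypes",
    "gamete_distribution",
    "apply_maternal_deposition",
    "offspring_distribution",
    "phenotype_of",
    "build_cube",
]

# Site states: wild (cuttable), loss-of-function, functional-resistant.
WILD = "W"
LOF = "L"
RESISTANT = "R"
_STATE_RANK = {WILD: 0, LOF: 1, RESISTANT: 2}

SEXES = ("M", "F")


class System(str, Enum):
    """Which binary CRISPR system the phenotype rules describe."""

    IFEGENIA = "ifegenia"
    PGSIT = "pgsit"


@dataclass(frozen=True)
class GeneticParams:
    """Parameters of the CRISPR inheritance model.

    Parameters
    ----------
    n_sites
        Number of gRNA target sites per target-gene allele (1–3).
    cut_rate
        Probability ``c`` that a given wild site on a given allele is cut
        during one germline (or deposition-affected embryonic) pass, in an
        individual carrying at least one gRNA and one Cas9 copy.
    deposition_rate
        Probability ``d`` that an embryo of a mother carrying both
        transgenes receives enough maternal Cas9 for zygotic cutting.
    functional_repair
        Probability ``rho`` that a cut site repairs to a functional,
        uncuttable (resistant) state rather than a loss-of-function lesion.
    zygotic_deposition_enabled
        If true, embryos carrying >=1 gRNA copy whose mother carries Cas9
        but no gRNA are also subject to embryonic cutting (lethal-mosaicism
        pathway), at rate ``zygotic_deposition_rate``.
    system
        ``IFEGENIA`` (female-killing, fertile males) or ``PGSIT``
        (additionally sterilises males carrying the full system).
    male_mating_weight_transgenic
        Mating competitiveness of transgene-bearing males relative to
        wild-type males.
    """

    n_sites: int = 1
    cut_rate: float = 0.90
    deposition_rate: float = 0.90
    functional_repair: float = 0.0
    zygotic_deposition_enabled: bool = False
    zygotic_deposition_rate: float = 0.90
    system: System = System.IFEGENIA
    male_mating_weight_transgenic: float = 0.75

    def __post_init__(self) -> None:
        if not 1 <= self.n_sites <= 3:
            raise ValueError(f"n_sites must be in 1..3, got {self.n_sites}")
        for name in (
            "cut_rate",
            "deposition_rate",
            "functional_repair",
            "zygotic_deposition_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.male_mating_weight_transgenic < 0:
            raise ValueError("male_mating_weight_transgenic must be >= 0")
        # accept plain strings in configs
        if not isinstance(self.system, System):
            object.__setattr__(self, "system", System(str(self.system).lower()))

    @property
    def allow_resistance(self) -> bool:
        return self.functional_repair > 0.0


@dataclass(frozen=True, order=True)
class TargetAllele:
    """One copy of the target gene: a multiset of per-site states.

    Sites within an allele are statistically exchangeable, so an allele is
    identified by how many of its sites are wild / LOF / resistant; states
    are stored in canonical (W < L < R) order.
    """

    states: tuple[str, ...]

    @staticmethod
    def make(states) -> "TargetAllele":
        return TargetAllele(tuple(sorted(states, key=_STATE_RANK.__getitem__)))

    @property
    def n_sites(self) -> int:
        return len(self.states)

    @property
    def n_wild(self) -> int:
        return self.states.count(WILD)

    @property
    def functional(self) -> bool:
        """An allele is functional iff no site carries a LOF lesion."""
        return LOF not in self.states

    @property
    def fully_resistant(self) -> bool:
        """All sites resistant: functional and no longer cuttable."""
        return all(s == RESISTANT for s in self.states)

    def __str__(self) -> str:
        return "".join(self.states)

    @staticmethod
    def from_string(s: str) -> "TargetAllele":
        if not s or any(ch not in _STATE_RANK for ch in s):
            raise ValueError(f"invalid target allele {s!r}")
        return TargetAllele.make(tuple(s))


def wild_allele(n_sites: int) -> TargetAllele:
    return TargetAllele((WILD,) * n_sites)


def lof_allele(n_sites: int) -> TargetAllele:
    return TargetAllele((LOF,) * n_sites)


@dataclass(frozen=True, order=True)
class Genotype:
    """gRNA copy number, Cas9 copy number and the unordered target-allele pair.

    Sex is carried separately where it matters (offspring distributions,
    cross tables); all loci are autosomal so the genetic state is
    sex-independent.
    """

    g: int
    cas: int
    pair: tuple[TargetAllele, TargetAllele]

    def __post_init__(self) -> None:
        if self.g not in (0, 1, 2) or self.cas not in (0, 1, 2):
            raise ValueError("transgene copy numbers must be 0, 1 or 2")
        a, b = self.pair
        if a.n_sites != b.n_sites:
            raise ValueError("target alleles must have equal site counts")
        if b < a:
            object.__setattr__(self, "pair", (b, a))

    @property
    def n_sites(self) -> int:
        return self.pair[0].n_sites

    @property
    def has_system(self) -> bool:
        """Carries at least one copy of each transgene."""
        return self.g >= 1 and self.cas >= 1

    @property
    def transgenic(self) -> bool:
        return self.g >= 1 or self.cas >= 1

    def __str__(self) -> str:
        return f"g{self.g}c{self.cas}|{self.pair[0]}/{self.pair[1]}"

    def to_string(self, sex: str | None = None) -> str:
        """Serialise, optionally with a trailing ``|M`` / ``|F`` sex field."""
        s = str(self)
        if sex is not None:
            if sex not in SEXES:
                raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
            s += f"|{sex}"
        return s

    @staticmethod
    def from_string(s: str) -> "Genotype":
        geno, _ = parse_genotype(s)
        return geno


def parse_genotype(s: str) -> tuple[Genotype, str | None]:
    """Parse ``g<k>c<k>|<allele>/<allele>[|<M|F>]`` into (Genotype, sex)."""
    parts = s.strip().split("|")
    if len(parts) not in (2, 3):
        raise ValueError(f"cannot parse genotype {s!r}")
    head, alleles = parts[0], parts[1]
    sex: str | None = None
    if len(parts) == 3:
        sex = parts[2]
        if sex not in SEXES:
            raise ValueError(f"invalid sex field {sex!r} in {s!r}")
    if not head.startswith("g") or "c" not in head:
        raise ValueError(f"cannot parse transgene field {head!r}")
    g_str, cas_str = head[1:].split("c")
    a_str, b_str = alleles.split("/")
    geno = Genotype(
        int(g_str),
        int(cas_str),
        (TargetAllele.from_string(a_str), TargetAllele.from_string(b_str)),
    )
    return geno, sex


def wildtype(n_sites: int) -> Genotype:
    return Genotype(0, 0, (wild_allele(n_sites), wild_allele(n_sites)))


@dataclass(frozen=True)
class Phenotype:
    """Deterministic genotype→phenotype map used by the simulator."""

    female_viable: int
    male_fertile: int
    mating_weight: float


# ---------------------------------------------------------------------------
# enumeration


def enumerate_target_alleles(n_sites: int, allow_resistance: bool = False):
    """All distinct target alleles for ``n_sites`` sites, in canonical order.

    Sites are exchangeable, so alleles are multisets over {W, L} (or
    {W, L, R} when resistant repair is modelled).
    """
    if not 1 <= n_sites <= 3:
        raise ValueError(f"n_sites must be in 1..3, got {n_sites}")
    states = (WILD, LOF, RESISTANT) if allow_resistance else (WILD, LOF)
    combos = itertools.combinations_with_replacement(states, n_sites)
    return sorted(TargetAllele.make(c) for c in combos)


def enumerate_genotypes(n_sites: int, allow_resistance: bool = False):
    """All distinct genotypes (without sex), in canonical order."""
    alleles = enumerate_target_alleles(n_sites, allow_resistance)
    pairs = list(itertools.combinations_with_replacement(alleles, 2))
    return [
        Genotype(g, cas, pair)
        for g in (0, 1, 2)
        for cas in (0, 1, 2)
        for pair in pairs
    ]


# ---------------------------------------------------------------------------
# cutting / gametes / deposition


def _cut_pass(allele: TargetAllele, c: float, rho: float) -> dict[TargetAllele, float]:
    """Distribution of an allele after one Cas9 exposure.

    Each wild site is cut independently with probability ``c``; a cut site
    becomes LOF with probability 1-rho and resistant with probability rho.
    LOF and resistant sites are never re-cut.
    """
    w = allele.n_wild
    if w == 0 or c == 0.0:
        return {allele: 1.0}
    base = tuple(s for s in allele.states if s != WILD)
    out: dict[TargetAllele, float] = {}
    for k_lof in range(w + 1):
        for k_res in range(w - k_lof + 1):
            stay = w - k_lof - k_res
            p = (
                math.comb(w, k_lof)
                * math.comb(w - k_lof, k_res)
                * (c * (1.0 - rho)) ** k_lof
                * (c * rho) ** k_res
                * (1.0 - c) ** stay
            )
            if p == 0.0:
                continue
            new = TargetAllele.make(
                base + (WILD,) * stay + (LOF,) * k_lof + (RESISTANT,) * k_res
            )
            out[new] = out.get(new, 0.0) + p
    return out


def gamete_distribution(parent: Genotype, params: GeneticParams):
    """Distribution over gametes ``(g_allele, cas_allele, target_allele)``.

    The two transgene loci segregate Mendelianly, independently of each
    other and of the target locus.  If the parent carries the full system,
    both parental target alleles undergo a germline cut pass before one is
    transmitted (whole-germline mutagenesis).
    """
    if parent.has_system:
        target: dict[TargetAllele, float] = {}
        for allele in parent.pair:
            for cut, p in _cut_pass(
                allele, params.cut_rate, params.functional_repair
            ).items():
                target[cut] = target.get(cut, 0.0) + 0.5 * p
    else:
        target = {}
        for allele in parent.pair:
            target[allele] = target.get(allele, 0.0) + 0.5

    g_probs = {0: 1.0 - parent.g / 2.0, 1: parent.g / 2.0}
    cas_probs = {0: 1.0 - parent.cas / 2.0, 1: parent.cas / 2.0}
    dist: dict[tuple[int, int, TargetAllele], float] = {}
    for (ga, pg), (ca, pc) in itertools.product(g_probs.items(), cas_probs.items()):
        pgc = pg * pc
        if pgc == 0.0:
            continue
        for t, pt in target.items():
            dist[(ga, ca, t)] = dist.get((ga, ca, t), 0.0) + pgc * pt
    return dist


def _deposition_rate(mother: Genotype, params: GeneticParams, embryo_g: int) -> float:
    if mother.has_system:
        return params.deposition_rate
    if (
        params.zygotic_deposition_enabled
        and mother.cas >= 1
        and mother.g == 0
        and embryo_g >= 1
    ):
        return params.zygotic_deposition_rate
    return 0.0


def apply_maternal_deposition(
    embryo_dist: dict[Genotype, float],
    mother: Genotype,
    params: GeneticParams,
) -> dict[Genotype, float]:
    """Act maternally deposited Cas9 on a distribution of embryo genotypes.

    With probability ``d`` per embryo the deposited Cas9 performs a cut
    pass on every remaining wild site of both embryo target alleles; with
    probability ``1-d`` the embryo is untouched.  See
    :class:`GeneticParams` for the Cas9-only-mother (zygotic) variant.
    """
    out: dict[Genotype, float] = {}
    for geno, p in embryo_dist.items():
        d = _deposition_rate(mother, params, geno.g)
        if d > 0.0:
            untouched = (1.0 - d) * p
            if untouched > 0.0:
                out[geno] = out.get(geno, 0.0) + untouched
            cut_a = _cut_pass(geno.pair[0], params.cut_rate, params.functional_repair)
            cut_b = _cut_pass(geno.pair[1], params.cut_rate, params.functional_repair)
            for (a, pa), (b, pb) in itertools.product(cut_a.items(), cut_b.items()):
                new = Genotype(geno.g, geno.cas, (a, b))
                out[new] = out.get(new, 0.0) + d * p * pa * pb
        else:
            out[geno] = out.get(geno, 0.0) + p
    return out


@lru_cache(maxsize=50_000)
def _offspring_genotype_distribution(
    mother: Genotype, father: Genotype, params: GeneticParams
) -> tuple[tuple[Genotype, float], ...]:
    mg = gamete_distribution(mother, params)
    fg = gamete_distribution(father, params)
    embryos: dict[Genotype, float] = {}
    for (mga, mca, mt), pm in mg.items():
        for (fga, fca, ft), pf in fg.items():
            geno = Genotype(mga + fga, mca + fca, (mt, ft))
            embryos[geno] = embryos.get(geno, 0.0) + pm * pf
    embryos = apply_maternal_deposition(embryos, mother, params)
    return tuple(sorted(embryos.items()))


def offspring_distribution(
    mother: Genotype,
    father: Genotype,
    params: GeneticParams,
    with_sex: bool = True,
):
    """Offspring distribution of a (mother, father) cross.

    Returns a dict over ``(Genotype, sex)`` with sex assigned 1/2 : 1/2
    independently of genotype, or over ``Genotype`` alone when
    ``with_sex=False``.  Results are memoised per (mother, father, params).
    """
    geno_dist = dict(_offspring_genotype_distribution(mother, father, params))
    if not with_sex:
        return geno_dist
    return {
        (geno, sex): 0.5 * p for geno, p in geno_dist.items() for sex in SEXES
    }


def phenotype_of(geno: Genotype, params: GeneticParams) -> Phenotype:
    """Viability, fertility and mating weight of a genotype.

    Females are unviable iff both target alleles are non-functional (each
    carries at least one LOF site) — the target gene is haplosufficient.
    Under pgSIT, males carrying the full system are additionally sterile.
    Transgene-bearing males mate at reduced competitiveness.
    """
    both_broken = not geno.pair[0].functional and not geno.pair[1].functional
    female_viable = 0 if both_broken else 1
    male_fertile = 1
    if params.system is System.PGSIT and geno.has_system:
        male_fertile = 0
    weight = params.male_mating_weight_transgenic if geno.transgenic else 1.0
    return Phenotype(female_viable, male_fertile, weight)


# ---------------------------------------------------------------------------
# the cube


class InheritanceCube:
    """Offspring-genotype distributions for every parental genotype pair.

    Slices are computed lazily and memoised; for small genotype spaces a
    dense ``(G, G, G)`` array can be tabulated eagerly with
    :meth:`build_dense`.  Sex is independent of genotype (1/2 : 1/2) and is
    therefore not part of the indexed state.
    """

    #: dense tabulation allowed up to this many array entries
    DENSE_ENTRY_CAP = 40_000_000

    def __init__(self, params: GeneticParams, allow_resistance: bool | None = None):
        self.params = params
        if allow_resistance is None:
            allow_resistance = params.allow_resistance
        self.allow_resistance = allow_resistance
        self.genotypes: list[Genotype] = enumerate_genotypes(
            params.n_sites, allow_resistance
        )
        self.index: dict[Genotype, int] = {g: i for i, g in enumerate(self.genotypes)}
        self.n = len(self.genotypes)
        phen = [phenotype_of(g, params) for g in self.genotypes]
        self.female_viable = np.array([p.female_viable for p in phen], dtype=float)
        self.male_fertile = np.array([p.male_fertile for p in phen], dtype=float)
        self.mating_weight = np.array([p.mating_weight for p in phen], dtype=float)
        self.wt_index = self.index[wildtype(params.n_sites)]
        # per-genotype count of fully resistant / non-functional target alleles
        self.resistant_alleles = np.array(
            [sum(a.fully_resistant for a in g.pair) for g in self.genotypes],
            dtype=float,
        )
        self.lof_alleles = np.array(
            [sum(not a.functional for a in g.pair) for g in self.genotypes],
            dtype=float,
        )
        self.is_transgenic = np.array(
            [g.transgenic for g in self.genotypes], dtype=bool
        )
        self._slices: dict[tuple[int, int], np.ndarray] = {}
        self.dense: np.ndarray | None = None

    def slice(self, mother_idx: int, father_idx: int) -> np.ndarray:
        """P(offspring genotype | mother, father) as a length-G vector."""
        if self.dense is not None:
            return self.dense[mother_idx, father_idx]
        key = (mother_idx, father_idx)
        out = self._slices.get(key)
        if out is None:
            dist = offspring_distribution(
                self.genotypes[mother_idx],
                self.genotypes[father_idx],
                self.params,
                with_sex=False,
            )
            out = np.zeros(self.n)
            for geno, p in dist.items():
                out[self.index[geno]] = p
            out.setflags(write=False)
            self._slices[key] = out
        return out

    def build_dense(self) -> np.ndarray:
        """Tabulate the full (mother, father, offspring) array eagerly."""
        if self.dense is None:
            if self.n**3 > self.DENSE_ENTRY_CAP:
                raise ValueError(
                    f"dense cube would need {self.n ** 3:,} entries "
                    f"(cap {self.DENSE_ENTRY_CAP:,}); use lazy slices"
                )
            cube = np.zeros((self.n, self.n, self.n))
            for mi in range(self.n):
                for fi in range(self.n):
                    cube[mi, fi] = self.slice(mi, fi)
            self.dense = cube
        return self.dense


def build_cube(params: GeneticParams, dense: bool | None = None) -> InheritanceCube:
    """Construct the inheritance cube for ``params``.

    ``dense=None`` tabulates eagerly when the genotype space is small
    enough and falls back to lazy memoised slices otherwise.
    """
    cube = InheritanceCube(params)
    if dense is None:
        dense = cube.n <= 64
    if dense:
        cube.build_dense()
    return cube
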