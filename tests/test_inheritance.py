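"""Inheritance model: gametes, deposition, offspring distributions, the cube."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifegenia.inheritance import (
    GeneticParams,
    Genotype,
    System,
    TargetAllele,
    apply_maternal_deposition,
    build_cube,
    enumerate_genotypes,
    enumerate_target_alleles,
    gamete_distribution,
    lof_allele,
    offspring_distribution,
    parse_genotype,
    phenotype_of,
    wild_allele,
    wildtype,
)

from .oracles import brute_force_offspring, mendelian_offspring

W1, L1 = wild_allele(1), lof_allele(1)


def geno(g, cas, a, b, n=1):
    return Genotype(g, cas, (TargetAllele.from_string(a), TargetAllele.from_string(b)))


# ---------------------------------------------------------------------------
# enumeration and serialisation


@pytest.mark.parametrize(
    "n_sites,allow_res,expected",
    [(1, False, 2), (2, False, 3), (3, False, 4), (2, True, 6), (3, True, 10)],
)
def test_allele_enumeration_counts(n_sites, allow_res, expected):
    alleles = enumerate_target_alleles(n_sites, allow_res)
    assert len(alleles) == expected
    assert len(set(alleles)) == expected  # duplicate-free
    assert alleles == sorted(alleles)  # deterministic canonical order


@pytest.mark.parametrize("bad", [0, 4, -1])
def test_allele_enumeration_range(bad):
    with pytest.raises(ValueError):
        enumerate_target_alleles(bad)


def test_genotype_space_size_one_site():
    # 3 gRNA x 3 Cas9 x 3 unordered target pairs; x2 sexes = 54 sexed classes
    genos = enumerate_genotypes(1)
    assert len(genos) == 27
    assert len(genos) * 2 == 54


def test_genotype_string_roundtrip():
    for g in enumerate_genotypes(2, allow_resistance=True):
        for sex in ("M", "F"):
            parsed, psex = parse_genotype(g.to_string(sex))
            assert parsed == g and psex == sex
    # canonical pair order is independent of construction order
    assert geno(1, 1, "L", "W") == geno(1, 1, "W", "L")
    assert str(geno(1, 1, "L", "W")) == str(geno(1, 1, "W", "L"))


# ---------------------------------------------------------------------------
# gametes


def test_certain_cutting_gametes():
    p = GeneticParams(cut_rate=1.0)
    dist = gamete_distribution(geno(1, 1, "W", "W"), p)
    # every transmitted target allele is LOF; transgenes segregate 1/2
    assert dist[(1, 1, L1)] == pytest.approx(0.25)
    assert sum(v for (g, c, t), v in dist.items() if t == L1) == pytest.approx(1.0)


def test_no_cas9_means_no_cutting():
    p = GeneticParams(cut_rate=0.99)
    dist = gamete_distribution(geno(1, 0, "W", "W"), p)
    assert sum(v for (g, c, t), v in dist.items() if t == W1) == pytest.approx(1.0)


def test_partial_cutting_joint_probability():
    p = GeneticParams(cut_rate=0.9)
    dist = gamete_distribution(geno(1, 1, "W", "W"), p)
    assert sum(v for (g, c, t), v in dist.items() if t == L1) == pytest.approx(0.9)
    assert dist[(1, 1, L1)] == pytest.approx(0.225)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


def test_lof_sites_never_recut_to_resistant():
    p = GeneticParams(cut_rate=1.0, functional_repair=0.5)
    dist = gamete_distribution(geno(1, 1, "L", "L"), p)
    assert dist == {(g, c, L1): v for (g, c, _), v in dist.items()}


# ---------------------------------------------------------------------------
# maternal deposition


def test_no_deposition_source_is_identity():
    p = GeneticParams(deposition_rate=1.0)
    embryos = {geno(1, 1, "W", "W"): 0.5, geno(0, 0, "W", "W"): 0.5}
    out = apply_maternal_deposition(embryos, wildtype(1), p)
    assert out == embryos


def test_certain_deposition_cuts_everything():
    p = GeneticParams(cut_rate=1.0, deposition_rate=1.0)
    embryos = {geno(0, 0, "W", "W"): 1.0}
    out = apply_maternal_deposition(embryos, geno(1, 1, "W", "W"), p)
    assert out == {geno(0, 0, "L", "L"): pytest.approx(1.0)}


def test_zygotic_deposition_per_allele_independence():
    # Cas9-only mother, gRNA-carrying embryo: each allele cut independently
    p = GeneticParams(
        cut_rate=0.9, zygotic_deposition_enabled=True, zygotic_deposition_rate=1.0
    )
    out = apply_maternal_deposition(
        {geno(1, 0, "W", "W"): 1.0}, geno(0, 1, "W", "W"), p
    )
    assert out[geno(1, 0, "L", "L")] == pytest.approx(0.81)
    assert out[geno(1, 0, "L", "W")] == pytest.approx(0.18)
    assert out[geno(1, 0, "W", "W")] == pytest.approx(0.01)


def test_zygotic_deposition_skips_gRNA_free_embryos():
    p = GeneticParams(
        cut_rate=0.9, zygotic_deposition_enabled=True, zygotic_deposition_rate=1.0
    )
    embryos = {geno(0, 1, "W", "W"): 1.0}
    out = apply_maternal_deposition(embryos, geno(0, 1, "W", "W"), p)
    assert out == embryos


# ---------------------------------------------------------------------------
# offspring distributions


def test_het_cross_mendelian_quarters():
    # gRNA/+ father x Cas9/+ mother: the four transgene classes at 1/4 each
    p = GeneticParams()
    dist = offspring_distribution(
        geno(0, 1, "W", "W"), geno(1, 0, "W", "W"), p, with_sex=False
    )
    classes = {}
    for g, pr in dist.items():
        classes[(g.g, g.cas)] = classes.get((g.g, g.cas), 0.0) + pr
    assert classes == {
        (0, 0): pytest.approx(0.25),
        (1, 0): pytest.approx(0.25),
        (0, 1): pytest.approx(0.25),
        (1, 1): pytest.approx(0.25),
    }


def test_wt_cross_identity_and_sex_split():
    p = GeneticParams()
    dist = offspring_distribution(wildtype(1), wildtype(1), p)
    assert dist == {
        (wildtype(1), "M"): pytest.approx(0.5),
        (wildtype(1), "F"): pytest.approx(0.5),
    }


def test_homozygous_lof_father_loads_one_broken_allele():
    p = GeneticParams(cut_rate=0.9)
    dist = offspring_distribution(
        wildtype(1), geno(1, 1, "L", "L"), p, with_sex=False
    )
    target_lw = geno(0, 0, "L", "W").pair
    assert sum(pr for g, pr in dist.items() if g.pair == target_lw) == pytest.approx(1.0)
    assert sum(pr for g, pr in dist.items() if g.g == 1 and g.cas == 1) == pytest.approx(0.25)


@pytest.mark.parametrize("n_sites", [1, 2])
def test_brute_force_oracle_equivalence(n_sites):
    """Exhaustive enumeration over cut/repair/deposition outcomes agrees."""
    p = GeneticParams(
        n_sites=n_sites,
        cut_rate=0.7,
        deposition_rate=0.6,
        functional_repair=0.1,
        zygotic_deposition_enabled=True,
        zygotic_deposition_rate=0.5,
    )
    W = wild_allele(n_sites)
    L = lof_allele(n_sites)
    parents = [
        (Genotype(1, 1, (W, W)), Genotype(1, 1, (W, W))),
        (Genotype(1, 1, (L, W)), Genotype(0, 0, (W, W))),
        (Genotype(0, 1, (W, W)), Genotype(1, 0, (W, W))),  # zygotic pathway
        (Genotype(2, 1, (W, L)), Genotype(1, 2, (W, W))),
        (Genotype(0, 0, (W, W)), Genotype(1, 1, (L, L))),
    ]
    for mother, father in parents:
        expected = brute_force_offspring(mother, father, p)
        got = offspring_distribution(mother, father, p, with_sex=False)
        assert set(got) == set(expected)
        for g in got:
            assert got[g] == pytest.approx(expected[g], abs=1e-10)


def test_mendelian_limit_exact():
    p = GeneticParams(cut_rate=0.0, deposition_rate=0.0)
    mother, father = geno(1, 1, "L", "W"), geno(2, 1, "W", "W")
    expected = mendelian_offspring(mother, father)
    got = offspring_distribution(mother, father, p, with_sex=False)
    assert set(got) == set(expected)
    for g in got:
        assert got[g] == pytest.approx(expected[g], abs=1e-12)


def test_allele_conservation_without_cutting():
    # c = d = 0: expected offspring allele frequency equals the parental mean
    p = GeneticParams(cut_rate=0.0, deposition_rate=0.0)
    mother, father = geno(1, 2, "L", "W"), geno(2, 0, "L", "L")
    dist = offspring_distribution(mother, father, p, with_sex=False)
    for locus, parent_mean in [
        (lambda g: g.g, (mother.g + father.g) / 4.0),
        (lambda g: g.cas, (mother.cas + father.cas) / 4.0),
        (
            lambda g: sum(a == L1 for a in g.pair),
            sum(a == L1 for a in mother.pair + father.pair) / 4.0,
        ),
    ]:
        mean = sum(locus(g) / 2.0 * pr for g, pr in dist.items())
        assert mean == pytest.approx(parent_mean, abs=1e-12)


@pytest.mark.parametrize("n_sites,c", [(1, 0.9), (2, 0.9), (3, 0.9), (3, 0.5)])
def test_multiplexing_increases_knockout_rate(n_sites, c):
    """P(transmitted allele non-functional) = 1 - (1-c)^n after one pass."""
    p = GeneticParams(n_sites=n_sites, cut_rate=c)
    parent = Genotype(1, 1, (wild_allele(n_sites), wild_allele(n_sites)))
    dist = gamete_distribution(parent, p)
    p_broken = sum(v for (g, cc, t), v in dist.items() if not t.functional)
    assert p_broken == pytest.approx(1.0 - (1.0 - c) ** n_sites, abs=1e-12)


# ---------------------------------------------------------------------------
# phenotypes


@pytest.mark.parametrize(
    "g,system,viable,fertile,weight",
    [
        (geno(0, 0, "L", "L"), System.IFEGENIA, 0, 1, 1.0),
        (geno(0, 0, "L", "W"), System.IFEGENIA, 1, 1, 1.0),
        (geno(1, 1, "L", "L"), System.IFEGENIA, 0, 1, 0.75),
        (geno(1, 0, "W", "W"), System.IFEGENIA, 1, 1, 0.75),
        (geno(1, 1, "W", "W"), System.PGSIT, 1, 0, 0.75),
        (geno(1, 0, "W", "W"), System.PGSIT, 1, 1, 0.75),
        (geno(1, 1, "L", "L"), System.PGSIT, 0, 0, 0.75),
    ],
)
def test_phenotype_rules(g, system, viable, fertile, weight):
    p = GeneticParams(system=system)
    ph = phenotype_of(g, p)
    assert (ph.female_viable, ph.male_fertile, ph.mating_weight) == (
        viable,
        fertile,
        weight,
    )


def test_resistant_alleles_are_functional():
    p = GeneticParams(functional_repair=0.01)
    rr = Genotype(1, 1, (TargetAllele.from_string("R"), TargetAllele.from_string("R")))
    assert phenotype_of(rr, p).female_viable == 1


# ---------------------------------------------------------------------------
# the cube


def test_cube_counts_and_normalisation(default_cube):
    assert default_cube.n == 27
    sums = default_cube.dense.sum(axis=2)
    assert np.allclose(sums, 1.0, atol=1e-12)


def test_cutting_free_cube_is_mendelian():
    p = GeneticParams(cut_rate=0.0, deposition_rate=0.0)
    cube = build_cube(p)
    for mi, fi in itertools.product(range(cube.n), repeat=2):
        expected = mendelian_offspring(cube.genotypes[mi], cube.genotypes[fi])
        got = cube.slice(mi, fi)
        for g, pr in expected.items():
            assert got[cube.index[g]] == pytest.approx(pr, abs=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)


def test_dense_cap_enforced():
    p = GeneticParams(n_sites=3, functional_repair=0.01)
    cube = build_cube(p, dense=False)
    assert cube.n == 495  # 9 transgene combos x 55 unordered allele pairs
    with pytest.raises(ValueError):
        cube.build_dense()


# ---------------------------------------------------------------------------
# property tests


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    c=st.floats(0, 1),
    d=st.floats(0, 1),
    rho=st.floats(0, 1),
    n_sites=st.integers(1, 2),
    seed=st.integers(0, 10**6),
)
def test_offspring_distributions_normalised(c, d, rho, n_sites, seed):
    p = GeneticParams(
        n_sites=n_sites, cut_rate=c, deposition_rate=d, functional_repair=rho
    )
    genos = enumerate_genotypes(n_sites, allow_resistance=True)
    rng = np.random.default_rng(seed)
    mother, father = rng.choice(len(genos), 2)
    dist = offspring_distribution(genos[mother], genos[father], p)
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
    # sex marginal is exactly half
    males = sum(v for (g, s), v in dist.items() if s == "M")
    assert males == pytest.approx(0.5, abs=1e-12)


def _p_daughter_unviable(c, d):
    p = GeneticParams(cut_rate=c, deposition_rate=d)
    mother = father = geno(1, 1, "W", "W")
    dist = offspring_distribution(mother, father, p, with_sex=False)
    return sum(
        pr for g, pr in dist.items() if phenotype_of(g, p).female_viable == 0
    )


def test_daughter_killing_monotone_in_cut_and_deposition():
    grid = np.linspace(0.0, 1.0, 6)
    for d in (0.0, 0.5, 1.0):
        vals = [_p_daughter_unviable(c, d) for c in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    for c in (0.3, 0.9):
        vals = [_p_daughter_unviable(c, d) for d in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
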