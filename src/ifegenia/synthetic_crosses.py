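"""Synthetic cross-table generator.

Emulates the study's single-pair cross experiments: multinomial
genotype×sex offspring counts drawn from the inheritance model, plus the
F2 target-allele census obtained by backcrossing a trans-heterozygous F1
male to wild-type females and genotyping his offspring for disrupted
target alleles.  Everything is reproducible from an integer seed, so the
statistics module is testable without any external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inheritance import (
    GeneticParams,
    Genotype,
    offspring_distribution,
    wildtype,
    wild_allele,
    lof_allele,
)
from .cross_stats import CrossTable, expected_adult_ratios

__all__ = [
    "simulate_cross_table",
    "simulate_f2_allele_census",
    "fixture_suite",
]


def simulate_cross_table(
    mother: Genotype,
    father: Genotype,
    n_offspring: int,
    params: GeneticParams,
    seed: int | np.random.Generator,
    stage: str = "adult",
    by: str = "genotype",
) -> CrossTable:
    """Draw one cross's offspring counts from the inheritance model.

    A single multinomial of size ``n_offspring`` over the expected
    class×sex proportions (post-viability when ``stage="adult"``).
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exp = expected_adult_ratios(mother, father, params, by=by, stage=stage)
    keys = sorted(exp)
    probs = np.array([exp[k] for k in keys])
    draws = rng.multinomial(n_offspring, probs)
    counts = {k: int(n) for k, n in zip(keys, draws) if n > 0}
    return CrossTable(mother, father, counts, by=by, provenance="synthetic")


def simulate_f2_allele_census(
    f1_father: Genotype,
    n_f2: int,
    params: GeneticParams,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Backcross a system-carrying F1 male to wild-type females and genotype F2.

    Returns one row per transgene class with the number of F2 individuals
    and the fraction carrying at least one disrupted (LOF-bearing)
    target allele — the enzyme-digest census that brackets the germline
    cutting rate.
    """
    if not f1_father.has_system:
        raise ValueError("the F1 father must carry both transgenes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mother = wildtype(params.n_sites)
    dist = offspring_distribution(mother, f1_father, params, with_sex=False)
    genos = sorted(dist)
    probs = np.array([dist[g] for g in genos])
    draws = rng.multinomial(n_f2, probs)
    rows = []
    agg: dict[tuple[int, int], list[int]] = {}
    for geno, n in zip(genos, draws):
        if n == 0:
            continue
        carrier = int(any(not a.functional for a in geno.pair))
        key = (geno.g, geno.cas)
        tot, car = agg.get(key, [0, 0])
        agg[key] = [tot + int(n), car + carrier * int(n)]
    for (g, cas), (tot, car) in sorted(agg.items()):
        rows.append(
            {
                "transgene_class": f"g{g}c{cas}",
                "n_transgenes": g + cas,
                "n": tot,
                "n_lof_carriers": car,
                "lof_carrier_fraction": car / tot if tot else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fixture_suite(
    params: GeneticParams | None = None,
    n_offspring: int = 2000,
    seed: int = 0,
    by: str = "genotype",
) -> tuple[list[CrossTable], pd.DataFrame]:
    """The default synthetic cross designs mirroring the study's crosses.

    1. het gRNA father × het Cas9 mother (maternal-deposition scoring);
    2. homozygous gRNA father × homozygous Cas9 mother and the reciprocal
       (complete genetic sexing censuses);
    3. trans-heterozygous F1 male × wild-type female (F2 loading);
    4. F2 male carrying both transgenes and one LOF allele × wild-type
       female (F3 loading).

    Returns the tables and a manifest of designs, seeds and parameters.
    """
    params = params or GeneticParams(zygotic_deposition_enabled=True)
    n = params.n_sites
    W, L = wild_allele(n), lof_allele(n)
    wt = wildtype(n)
    designs = [
        ("f1_het", Genotype(0, 1, (W, W)), Genotype(1, 0, (W, W))),
        ("gss_maternal_cas9", Genotype(0, 2, (W, W)), Genotype(2, 0, (W, W))),
        ("gss_paternal_cas9", Genotype(2, 0, (W, W)), Genotype(0, 2, (W, W))),
        ("f2_loading", wt, Genotype(1, 1, (W, W))),
        ("f3_loading", wt, Genotype(1, 1, (L, W))),
    ]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(designs))
    tables = []
    manifest_rows = []
    for (name, mother, father), child in zip(designs, children):
        rng = np.random.default_rng(child)
        t = simulate_cross_table(
            mother, father, n_offspring, params, rng, stage="adult", by=by
        )
        tables.append(t)
        manifest_rows.append(
            {
                "design": name,
                "mother": str(mother),
                "father": str(father),
                "n_offspring": n_offspring,
                "seed": seed,
                "spawn_index": len(manifest_rows),
                "n_sites": params.n_sites,
                "cut_rate": params.cut_rate,
                "deposition_rate": params.deposition_rate,
                "zygotic_deposition_enabled": params.zygotic_deposition_enabled,
                "zygotic_deposition_rate": params.zygotic_deposition_rate,
            }
        )
    return tables, pd.DataFrame(manifest_rows)
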