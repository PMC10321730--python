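"""Independent oracles used by the test suite.

Everything here is deliberately written as direct enumeration or
closed-form computation, independent of the package's implementation
paths, so agreement is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import brentq

from ifegenia.inheritance import Genotype, TargetAllele


def _site_outcomes(state: str, c: float, rho: float):
    """Per-site outcome distribution of one Cas9 exposure (ordered states)."""
    if state != "W" or c == 0.0:
        return [(state, 1.0)]
    out = [("L", c * (1.0 - rho)), ("R", c * rho), ("W", 1.0 - c)]
    return [(s, p) for s, p in out if p > 0.0]


def _cut_allele_ordered(states: tuple, c: float, rho: float):
    """All cut outcomes of one ordered allele, by product enumeration."""
    per_site = [_site_outcomes(s, c, rho) for s in states]
    for combo in itertools.product(*per_site):
        yield tuple(s for s, _ in combo), float(np.prod([p for _, p in combo]))


def brute_force_offspring(mother: Genotype, father: Genotype, params):
    """Exhaustive enumeration over every cut/repair/deposition sequence.

    Returns a dict over canonical Genotype (no sex) → probability.
    """
    c, rho, d = params.cut_rate, params.functional_repair, params.deposition_rate

    def gametes(parent: Genotype):
        """(g, cas, ordered target states) → prob."""
        cutting = parent.g >= 1 and parent.cas >= 1
        out = {}
        for which in (0, 1):  # which target allele is transmitted
            src = parent.pair[which].states
            allele_dist = (
                list(_cut_allele_ordered(src, c, rho)) if cutting else [(src, 1.0)]
            )
            for g_allele in (0, 1):
                pg = parent.g / 2.0 if g_allele else 1.0 - parent.g / 2.0
                for cas_allele in (0, 1):
                    pc = parent.cas / 2.0 if cas_allele else 1.0 - parent.cas / 2.0
                    for states, pa in allele_dist:
                        key = (g_allele, cas_allele, states)
                        out[key] = out.get(key, 0.0) + 0.5 * pg * pc * pa
        return out

    mg, fg = gametes(mother), gametes(father)
    result: dict[Genotype, float] = {}
    mother_deposits = mother.g >= 1 and mother.cas >= 1
    zygotic = (
        params.zygotic_deposition_enabled and mother.cas >= 1 and mother.g == 0
    )
    for (mga, mca, mt), pm in mg.items():
        for (fga, fca, ft), pf in fg.items():
            p_embryo = pm * pf
            g_total, cas_total = mga + fga, mca + fca
            if mother_deposits:
                dep = d
            elif zygotic and g_total >= 1:
                dep = params.zygotic_deposition_rate
            else:
                dep = 0.0
            branches = [((mt, ft), (1.0 - dep) * p_embryo)]
            if dep > 0.0:
                for amt, pa in _cut_allele_ordered(mt, c, rho):
                    for aft, pb in _cut_allele_ordered(ft, c, rho):
                        branches.append(((amt, aft), dep * p_embryo * pa * pb))
            for (a, b), p in branches:
                if p == 0.0:
                    continue
                geno = Genotype(
                    g_total,
                    cas_total,
                    (TargetAllele.make(a), TargetAllele.make(b)),
                )
                result[geno] = result.get(geno, 0.0) + p
    return result


def mendelian_offspring(mother: Genotype, father: Genotype):
    """Three-locus independent segregation with no cutting (closed form)."""
    out: dict[Genotype, float] = {}
    for mg in (0, 1):
        pmg = mother.g / 2.0 if mg else 1.0 - mother.g / 2.0
        for fg in (0, 1):
            pfg = father.g / 2.0 if fg else 1.0 - father.g / 2.0
            for mc in (0, 1):
                pmc = mother.cas / 2.0 if mc else 1.0 - mother.cas / 2.0
                for fc in (0, 1):
                    pfc = father.cas / 2.0 if fc else 1.0 - father.cas / 2.0
                    for ma in mother.pair:
                        for fa in father.pair:
                            p = pmg * pfg * pmc * pfc * 0.25
                            if p == 0.0:
                                continue
                            geno = Genotype(mg + fg, mc + fc, (ma, fa))
                            out[geno] = out.get(geno, 0.0) + p
    return out


def euler_lotka_growth(life, mu_juv: float) -> float:
    """Daily growth factor of the density-independent model.

    A female emerging on day 0 lays ``beta`` eggs on each day ``a`` she
    is alive (survival ``(1-mu_ad)**a``); eggs take ``T`` days and
    survive ``(1-mu_juv)**T``.  The renewal equation is

        (beta/2) * s^T * lam^-T * sum_a ((1-mu_ad)/lam)^a = 1.
    """
    T = life.T_e + life.T_l + life.T_p
    sT = (1.0 - mu_juv) ** T
    k = life.beta / 2.0 * sT

    def f(lam):
        return k * lam ** (-T) / (1.0 - (1.0 - life.mu_ad) / lam) - 1.0

    return brentq(f, 1.0 + 1e-9, 4.0, xtol=1e-12)
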