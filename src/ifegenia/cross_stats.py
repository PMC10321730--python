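"""Statistics over transgenic-cross genotype×sex count tables.

Observables from a single cross — counts of adult offspring per genotype
class and sex — are compared with the proportions the inheritance model
predicts: fold-reduction of females within a class, exact binomial tests
of the 50:50 sex ratio, Pearson goodness of fit against Mendelian (or
cut-modified) expectations, and maximum-likelihood estimation of the
cutting and deposition rates from one or more tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .inheritance import (
    GeneticParams,
    Genotype,
    SEXES,
    offspring_distribution,
    phenotype_of,
)

__all__ = [
    "CrossTable",
    "expected_adult_ratios",
    "fold_reduction",
    "sex_ratio_test",
    "gof_chisq",
    "estimate_rates",
    "RateEstimate",
]


@dataclass
class CrossTable:
    """Genotype×sex offspring counts from one cross.

    ``counts`` maps ``(class_key, sex)`` → non-negative integer count.
    ``by`` records the class granularity: ``"genotype"`` (full genotype
    string without sex) or ``"transgene"`` (``g<k>c<k>`` copy-number
    class, the resolution of a fluorescence-scored cross).
    """

    mother: Genotype
    father: Genotype
    counts: dict[tuple[str, str], int]
    by: str = "genotype"
    provenance: str = "observed"

    def __post_init__(self) -> None:
        for (cls, sex), n in self.counts.items():
            if sex not in SEXES:
                raise ValueError(f"invalid sex {sex!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"counts must be non-negative integers, got {n}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def sex_counts(self, cls: str) -> tuple[int, int]:
        """(males, females) within one class."""
        return (self.counts.get((cls, "M"), 0), self.counts.get((cls, "F"), 0))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mother": str(self.mother),
                "father": str(self.father),
                "class": cls,
                "sex": sex,
                "count": n,
            }
            for (cls, sex), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)

    @staticmethod
    def from_frame(df: pd.DataFrame, by: str = "genotype", provenance: str = "observed"):
        tables = []
        for (mo, fa), grp in df.groupby(["mother", "father"], sort=False):
            counts = {
                (cls, sex): int(n)
                for cls, sex, n in grp[["class", "sex", "count"]].itertuples(
                    index=False, name=None
                )
            }
            tables.append(
                CrossTable(
                    Genotype.from_string(mo),
                    Genotype.from_string(fa),
                    counts,
                    by=by,
                    provenance=provenance,
                )
            )
        return tables


def _class_key(geno: Genotype, by: str) -> str:
    if by == "genotype":
        return str(geno)
    if by == "transgene":
        return f"g{geno.g}c{geno.cas}"
    raise ValueError(f"unknown class granularity {by!r}")


def expected_adult_ratios(
    mother: Genotype,
    father: Genotype,
    params: GeneticParams,
    by: str = "genotype",
    stage: str = "adult",
) -> dict[tuple[str, str], float]:
    """Expected offspring class×sex proportions under the inheritance model.

    ``stage="adult"`` removes unviable females and renormalises (the
    pupal/adult census the crosses scored); ``stage="embryo"`` keeps the
    pre-viability distribution.
    """
    dist = offspring_distribution(mother, father, params, with_sex=True)
    out: dict[tuple[str, str], float] = {}
    for (geno, sex), p in dist.items():
        if stage == "adult" and sex == "F":
            p *= phenotype_of(geno, params).female_viable
        if p == 0.0:
            continue
        key = (_class_key(geno, by), sex)
        out[key] = out.get(key, 0.0) + p
    total = sum(out.values())
    if total <= 0.0:
        raise ValueError("no viable offspring classes for this cross")
    return {k: v / total for k, v in out.items()}


def fold_reduction(n_males: int, n_females: int) -> float:
    """Male : female ratio within a genotype class.

    Returns ``inf`` when females are absent entirely; both counts zero is
    undefined.
    """
    if n_males < 0 or n_females < 0:
        raise ValueError("counts must be non-negative")
    if n_males == 0 and n_females == 0:
        raise ValueError("fold reduction undefined for an empty class")
    if n_females == 0:
        return math.inf
    return n_males / n_females


def sex_ratio_test(n_males: int, n_females: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value for a sex-ratio distortion."""
    n = n_males + n_females
    if n < 1:
        raise ValueError("need at least one individual")
    return float(stats.binomtest(n_males, n, p0).pvalue)


def gof_chisq(
    table: CrossTable, expected: dict[tuple[str, str], float]
) -> tuple[float, int, float]:
    """Pearson chi-square of observed class×sex counts against expectations.

    Expected proportions are renormalised over the keys present in either
    the table or the expectation; an expected zero facing a nonzero
    observation is an error (the model rules the class out entirely).
    """
    keys = sorted(set(table.counts) | set(expected))
    obs = np.array([table.counts.get(k, 0) for k in keys], dtype=float)
    exp_p = np.array([expected.get(k, 0.0) for k in keys], dtype=float)
    bad = (exp_p == 0.0) & (obs > 0)
    if bad.any():
        raise ValueError(
            f"observed counts in classes with zero expectation: "
            f"{[keys[i] for i in np.nonzero(bad)[0]]}"
        )
    keep = exp_p > 0.0
    obs, exp_p = obs[keep], exp_p[keep]
    exp_p = exp_p / exp_p.sum()
    exp = exp_p * obs.sum()
    statistic = float(((obs - exp) ** 2 / exp).sum())
    df = int(len(obs) - 1)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p


# ---------------------------------------------------------------------------
# maximum-likelihood rate estimation

_FREE_PARAM_FIELDS = {
    "c": "cut_rate",
    "d": "deposition_rate",
    "d_z": "zygotic_deposition_rate",
    "rho": "functional_repair",
}


@dataclass
class RateEstimate:
    """MLE of inheritance-model rates from cross tables."""

    estimates: dict[str, float]
    ci: dict[str, tuple[float, float]]
    log_likelihood: float
    n_tables: int
    n_offspring: int


def _with_params(params: GeneticParams, free: list[str], theta) -> GeneticParams:
    return replace(
        params, **{_FREE_PARAM_FIELDS[name]: float(v) for name, v in zip(free, theta)}
    )


def _log_likelihood(
    theta, free, tables: list[CrossTable], params: GeneticParams, stage: str
) -> float:
    ll = 0.0
    for t in tables:
        p = _with_params(params, free, theta)
        exp = expected_adult_ratios(t.mother, t.father, p, by=t.by, stage=stage)
        for key, n in t.counts.items():
            if n == 0:
                continue
            pk = exp.get(key, 0.0)
            if pk <= 0.0:
                return -np.inf  # observed class impossible under theta
            ll += n * math.log(pk)
    return ll


def estimate_rates(
    tables: list[CrossTable],
    free_params: list[str],
    params: GeneticParams | None = None,
    stage: str = "adult",
    start: dict[str, float] | None = None,
    ci_level: float = 0.95,
) -> RateEstimate:
    """Maximise the multinomial likelihood of cross tables over chosen rates.

    ``free_params`` is a subset of ``{"c", "d", "d_z", "rho"}``; all other
    rates stay at their values in ``params``.  Identifiability is checked
    through the rank of the observed Fisher information at the start
    value; profile-likelihood confidence intervals are returned per
    parameter.
    """
    if not tables:
        raise ValueError("need at least one cross table")
    unknown = [p for p in free_params if p not in _FREE_PARAM_FIELDS]
    if unknown:
        raise ValueError(f"unknown free parameters {unknown}")
    params = params or GeneticParams()
    free = list(free_params)
    x0 = np.array([(start or {}).get(name, 0.5) for name in free])
    eps = 1e-4
    bounds = [(eps, 1.0 - eps)] * len(free)

    def nll(theta):
        return -_log_likelihood(theta, free, tables, params, stage)

    # identifiability: observed information must have full rank at x0
    h = 1e-4
    k = len(free)
    hess = np.zeros((k, k))
    f0 = nll(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h
            ej = np.eye(k)[j] * h
            hess[i, j] = hess[j, i] = (
                nll(x0 + ei + ej) - nll(x0 + ei) - nll(x0 + ej) + f0
            ) / h**2
    rank = np.linalg.matrix_rank(hess, tol=1e-6 * max(1.0, abs(f0)))
    if rank < k:
        _, _, vt = np.linalg.svd(hess)
        flat = vt[-1]
        direction = " + ".join(
            f"{w:+.2f}*{name}" for w, name in zip(flat, free) if abs(w) > 0.1
        )
        raise ValueError(
            f"parameters {free} not jointly identifiable from these tables "
            f"(flat direction {direction})"
        )

    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-8}
    )
    theta_hat = res.x
    ll_hat = -res.fun

    # profile-likelihood CIs: 2*(ll_hat - ll_profile) <= chi2_{1,level}
    cutoff = stats.chi2.ppf(ci_level, df=1) / 2.0
    ci: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(free):
        def profile_excess(v):
            if k == 1:
                return (ll_hat - -nll(np.array([v]))) - cutoff
            fixed = list(range(k))
            fixed.remove(i)

            def nll_sub(sub):
                theta = np.empty(k)
                theta[i] = v
                theta[fixed] = sub
                return nll(theta)

            sub0 = theta_hat[fixed]
            r = optimize.minimize(
                nll_sub,
                sub0,
                method="L-BFGS-B",
                bounds=[bounds[j] for j in fixed],
                options={"ftol": 1e-8},
            )
            return (ll_hat - -r.fun) - cutoff

        lo, hi = bounds[i]
        est = theta_hat[i]
        if profile_excess(lo) <= 0:
            lower = lo
        else:
            lower = optimize.brentq(profile_excess, lo, est, xtol=1e-6)
        if profile_excess(hi) <= 0:
            upper = hi
        else:
            upper = optimize.brentq(profile_excess, est, hi, xtol=1e-6)
        ci[name] = (float(lower), float(upper))

    return RateEstimate(
        estimates={name: float(v) for name, v in zip(free, theta_hat)},
        ci=ci,
        log_likelihood=float(ll_hat),
        n_tables=len(tables),
        n_offspring=sum(t.total for t in tables),
    )
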