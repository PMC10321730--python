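# Methods

This note documents the model implemented by the package, its
assumptions and defaults, the calibration procedure, and the design
choices made where the design was genuinely open. Nothing here states a
result the test suite or `scripts/acceptance.py` does not itself
compute.

## Genetic model

### State space

A genotype consists of the gRNA-cassette copy number (0–2), the Cas9
copy number (0–2), and an unordered pair of target-gene alleles. Each
allele carries `n_sites` (1–3) gRNA target sites, each in one of three
states: wild (cuttable), loss-of-function (LOF), or
functional-resistant (sequence-changed, functional, uncuttable). Sites
within an allele are treated as statistically exchangeable, so an
allele is a multiset of site states; this compresses 3^n ordered states
to at most 10 alleles at n = 3. With one target site and no resistant
class the space has 27 genotypes (54 sexed classes). All loci are
autosomal and unlinked; sex is assigned 1/2 : 1/2 independently of
genotype. The observed partial linkage of the two transgenes on
chromosome 2 is deliberately not modelled: released individuals carry
exactly one copy of each transgene, and no recombination fraction is
available for the cross designs that would expose linkage, so
field-scale outcomes are insensitive to it.

### Cutting, deposition, resistance

* **Germline cutting.** In a parent carrying at least one copy of each
  transgene, every wild site on *both* parental alleles is cut
  independently with probability `c` (default 0.90) before segregation
  — whole-germline mutagenesis, consistent with disrupted-allele
  carriage being observed at roughly the cutting rate among offspring
  that inherit no transgenes. A cut site repairs to LOF with
  probability 1−ρ and to functional-resistant with probability ρ
  (default 0; 0.01 is the suggested value for resistance experiments).
  LOF and resistant sites are never re-cut.
* **Maternal deposition.** If the mother carries both transgenes, each
  embryo is affected with probability `d` (default 0.90); in an
  affected embryo every remaining wild site on both alleles is cut at
  the same per-site rate `c`. Re-using `c` inside affected embryos is
  the minimal extra assumption — only the embryo-level rate is
  empirically anchored.
* **Zygotic (Cas9-only-mother) deposition.** Mothers carrying Cas9 but
  no gRNA deposit Cas9 protein that can act together with a
  *paternally inherited* gRNA in the embryo. This pathway — needed to
  reproduce the strong deficit of gRNA-carrying daughters of Cas9/+
  mothers — is implemented with its own embryo-level rate `d_z` but is
  **off by default**: the field-release simulations condition
  deposition on mothers carrying both transgenes, and the zygotic
  pathway matters only for cross-table statistics, where it is an
  explicit switch.

### Phenotypes

Females are unviable iff both target alleles are non-functional (each
carries ≥1 LOF site); the target gene is haplosufficient, so one intact
allele suffices. "Reduced viability" is implemented as viability
exactly 0. Under pgSIT, males carrying ≥1 gRNA and ≥1 Cas9 copy are
additionally sterile. Transgene-bearing males mate with relative
competitiveness 0.75 (configurable); there are no other fitness costs.
Fully resistant alleles are functional: females homozygous for them are
viable, which is what lets resistance undermine suppression.

## Population model

Daily time steps over egg (T_E = 3 d), larva (T_L = 7 d), pupa
(T_P = 1 d) and adult stages. Adults die at μ_ad = 0.123/day. Females
mate exactly once, on their emergence day, choosing a mate by
multinomial over (male count × mating weight); they retain the mate's
genotype for life, and a female emerging on a male-free day stays
unmated permanently. Mated females lay β = 32 eggs/day (Poisson in
stochastic mode), distributed over offspring genotypes by the
inheritance-cube slice of the (mother, mate) pair; matings with sterile
fathers yield nothing. Sex is drawn at the larva→pupa transition.
Unviable females are removed at that same transition by default — they
compete for larval resources first, matching the observation that
female death occurs predominantly in the larval stage (an at-hatch
switch exists). Released eggs join the age-0 egg cohort and face the
full juvenile gauntlet.

Step order within a day: adult survival → pupal emergence (newly
emerged males join the pool before that day's females choose mates) →
oviposition → releases → stage ageing. Juvenile cohorts experience one
density-independent survival draw per day (the final pupal draw happens
at emergence), giving exactly T_E + T_L + T_P draws from laying to
adulthood.

### Calibration

Two derived constants:

* μ_juv solves `(1−μ_juv)^(T_E+T_L+T_P) = 2·Rm·μ_ad/β`: a female lays β
  eggs on each of an expected 1/μ_ad days from her emergence day, half
  daughters, so density-independent lifetime replacement equals Rm.
  Infeasible combinations (right side outside (0,1)) raise an error
  naming the violated bound.
* The larval density factor `F(L) = (α/(α+L))^(1/T_L)` (a
  Beverton–Holt form spread over the larval duration, applied to the
  total larval census including transgenic and doomed-female larvae)
  uses α found by root-finding so that the deterministic fixed point of
  the *actual* daily step sits at N_eq adults. Calibrating against the
  implemented step, rather than a closed form, makes the equilibrium
  self-consistent to round-off; the wild-type drift observed over a
  simulated year is ~1e-11 relative. At Rm = 1 density dependence is
  unnecessary and α = ∞.

With density dependence disabled the deterministic model grows at the
Euler–Lotka root λ of
`(β/2)·s^T·λ^−T / (1 − (1−μ_ad)/λ) = 1` (s = 1−μ_juv,
T = T_E+T_L+T_P); the test suite checks the simulated growth factor
against this independently solved root. Note that λ^T_g does not equal
Rm for any simple generation-time T_g in an overlapping-generations
model; Rm is a per-generation net reproductive number, not a daily
rate.

### Life-history defaults

The source study's parameter table is not reproduced in the available
text, so defaults are the package's own choice from the *A. gambiae*
modelling literature, all configurable: β = 32 eggs/female/day,
T_E/T_L/T_P = 3/7/1 days, μ_ad = 0.123/day, N_eq = 10,000 adults, and
Rm = 3 per generation. Rm is the one parameter the release-response
curve is genuinely sensitive to; published net reproductive numbers for
*A. gambiae* span roughly 2–12. Rm = 3, from the low-to-mid part of
that range, places the two contour edges where the study's simulations
put them — elimination in ≥90% of replicates appearing between 23 and
27 weekly releases of 300 eggs/adult, and two-year protection of the
median replicate appearing between 20 and 23 — and is therefore adopted
as the default; at Rm = 6 both edges sit 3–4 weekly releases higher.
Because the exact source table is unavailable, the headline outcomes
are scaled/qualitative reproductions, not digit-level ones.

### Stochastics and reproducibility

Stochastic mode uses binomial survival, Poisson oviposition and
multinomial mate choice. Oviposition exploits Poisson thinning:
per-female Poisson(β) split multinomially over a cube slice equals
independent Poisson counts per offspring genotype, so a day's egg
production is one vector draw. Replicate k of a campaign always draws
from the stream keyed (master seed, k), so replicate streams are
invariant to the replicate count and ensembles sharing a master seed
are coupled by common random numbers across scenarios (the coupling is
approximate — draws desynchronise as trajectories diverge — which is
why grid-monotonicity checks allow one replicate of slack).

## Outcome metrics

* **Elimination**: the first day the census over *all* stages and
  genotypes reaches zero and stays there through the horizon, with no
  releases pending. A zero-adult day with juveniles developing is not
  elimination.
* **Window of protection**: the longest contiguous run of days with
  adults ≤ 10% of the pre-release equilibrium (threshold and the
  adults/females denominator configurable); eliminated runs count
  through the horizon end, so in deeply protective schemes the window
  is bounded by the simulation horizon rather than by rebound.
  "Protected ≥2 years" uses 730 days. Ensemble summaries attach exact
  Clopper–Pearson 95% intervals to the elimination and protection
  percentages.

## Cross statistics

Expected class×sex proportions come from the offspring distribution
with unviable females removed and the rest renormalised (the
pupal/adult census the crosses scored; an embryo-stage mode skips the
viability filter). Fold reduction is the male:female count ratio; the
sex-ratio test is the exact two-sided binomial test (no normal
approximation); goodness of fit is Pearson chi-square with
df = classes−1. Rate estimation maximises the multinomial
log-likelihood over any subset of {c, d, d_z, ρ} with L-BFGS-B inside
(0,1) bounds, checks identifiability via the rank of the observed
information at the start value (naming the flat direction on failure),
and profiles the likelihood for 95% intervals. Boundary estimates
(e.g. c → 1 when no cut-prone females survive) pin the adjacent
interval end at the bound.

## Synthetic data

The generator draws one multinomial of the requested size from the
model's expected class×sex proportions per cross — it emulates
genotype×sex census tables and the F2 disrupted-allele census, at the
study's default rates (c = d = d_z = 0.90). It does not emulate
overdispersion across families, genotyping error, partial transgene
linkage, or the rare sex-phenotype anomalies (feminised XY
individuals) seen in real censuses; passing recovery and coverage tests
therefore demonstrate correctness of the estimator under the model, not
robustness to those real-data features.

## Problem sizes used in the checks

Headline scheme outcomes use 30 stochastic replicates at
N_eq = 10,000 over a six-year horizon. Structural property checks run
at reduced scale chosen once: grid monotonicity on a 3×3 grid at
N_eq = 2,000 (30 replicates, 3 years), sensitivity at N_eq = 2,000 (10
replicates per parameter value, 4 years), resistance ordering at
N_eq = 1,000 with ρ = 0.1 (5 replicates, 1 year), estimator coverage
over 200 synthetic replicates of 2,000 offspring. Dense cube
tabulation is automatic up to 64 genotypes; larger spaces (multi-site
with resistance, up to 495 genotypes) use lazy memoised slices.

## Known limitations

Single randomly mixing population: no space, migration, seasonality,
multiple mating or adult density dependence. Transgene linkage,
X-linkage and intersex phenotypes are out of scope. The model kills
females only through inherited or deposition-derived LOF alleles; it
does not represent somatic mosaic self-cutting in trans-heterozygotes
(lethal mosaicism from the embryo's own transgenes), which is why the
paternal-Cas9 genetic-sexing cross kills all daughters in the
laboratory but requires the zygotic-deposition switch (maternal-Cas9
direction) to do so in the model.
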