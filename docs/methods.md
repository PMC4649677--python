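# Methods

## Model and assumptions

The unit of analysis is a cohort: every individual of one strain × host
treatment, followed daily from first-instar larva to juvenile death or
adult emergence. Age 0 is entry into observation; the egg stage is
outside the model, so absolute generation times omit egg incubation but
all rates remain comparable across treatments. Events are integer days
(survival was scored once daily), and the data model assumes no
censoring: every non-adult has a recorded death day. Under no censoring
the Kaplan–Meier estimator equals the empirical survival function
S(t) = #{alive after day t}/n, which is what the survivorship module
computes (and what the lifelines cross-check in the test suite
verifies).

The life table assigns:

- **l_x** — the cohort survival curve at juvenile ages, held at the
  adult plateau across the reproductive window. No adult mortality is
  modelled inside the fixed pre-oviposition + oviposition window; the
  experiment recorded none.
- **m_x** — each adult female with development time T, fecundity F and
  offspring sex ratio s contributes F·s/ω daughters per day at ages
  T + π … T + π + ω − 1, where π is the pre-oviposition period
  (default 3 days) and ω the oviposition window (default 6 days).
  Contributions are averaged over the adult females of the cohort, so
  juvenile deaths affect l_x only. The within-window laying profile is
  uniform by default; `oviposition_shape` reweights it for sensitivity
  analysis. Σ_x m_x always equals the female mean of F·s (mass
  conservation, tested to 1e-9).

Whether "cohort survival" means the full curve or only the terminal
survival-to-adulthood proportion is ambiguous in principle; both are
implemented (`survival_mode='curve'` default, `'terminal'` as a
sensitivity switch). They coincide whenever all juvenile deaths precede
the first reproductive age, which holds for every preset configuration.

**R₀ = Σ l_x m_x** is evaluated as a plain dot product. **r_m** solves
the discrete Euler–Lotka equation Σ e^(−r·x) l_x m_x = 1 on the integer
age grid, matching the daily scoring; no continuous-time correction is
applied. φ(r) = Σ e^(−r·x) l_x m_x − 1 is strictly decreasing whenever
reproduction occurs at positive ages, so the root is unique. It is
found by Brent's method on a bracket (default [−1, 2] per day, doubled
outward up to 60 times when the root lies outside), to a residual
tolerance |φ| ≤ 1e-10. Zero lifetime reproduction is an error (no
root); a zero-fecundity female's individual r_m is reported as NaN
rather than −∞ and excluded from correlations, with a warning.

Per-individual rates give each female her own maternity schedule with
l_x equal to the cohort survival at reproductive ages, so
R₀ᵢ = survival·Fᵢ·sᵢ; these feed the pupal-weight correlations
(Pearson by default, Spearman as the rank-based option — the choice is
an open convention, so both are exposed).

## Inference

The jackknife leaves out each individual in turn — by default every
individual, males and juvenile deaths included, because their removal
changes the survival curve; `jackknife_unit='females'` restricts to
adult females. Pseudo-values p_i = n·θ − (n−1)·θ₍₋ᵢ₎ give
mean = p̄, se = sd(p)/√n and CI = p̄ ± t(1−α/2, n−1)·se (Student-t is
the common jackknife convention; a normal-quantile option exists). For
any linear statistic the pseudo-values equal the observations, so the
jackknife reproduces the classical mean and SE exactly — a machine-
precision identity the tests assert. Leave-one-out replicates on which
the estimator fails (e.g. the last reproductive female removed) are
reported; more than 10% failures aborts. On preset cohorts of n = 50
the 95% CI covers the generating R₀ in ~94% of replicates (the test
band is 90–99%).

Treatments differ significantly when their CIs are disjoint; touching
endpoints count as overlap (conservative). Compact letters are a
maximal-clique cover of the interval overlap graph: each maximal set of
mutually overlapping CIs (the intervals covering some CI left endpoint)
receives one letter, so two estimates share a letter iff their CIs
overlap — exact for intervals, unlike greedy coloring. Cliques are
lettered in descending order of point estimate (ties broken by
treatment label), making the output deterministic and permutation-
invariant.

The weight–fecundity relation fecundity = exp(a + b·weight) is fitted
by Poisson IRLS; standard errors follow the quasi-Poisson convention,
scaled by the Pearson χ²/df dispersion, which widens the SEs without
moving the point estimates. Reported alongside: dispersion and
deviance explained (1 − residual/null deviance). The implementation is
cross-checked against statsmodels GLM (`scale="X2"`) in the tests.

## Synthetic-cohort generator

Per individual: sex ~ Bernoulli(0.5); survival to adulthood ~
Bernoulli(p) with death day uniform on a configured window (sex is
recorded as unknown for juvenile deaths, as in the experiment);
development ~ round(Normal(μ_sex, σ)) truncated at 5 days; pupal weight
~ Normal(μ_sex, σ_w) truncated positive by resampling; adult-female
fecundity ~ Poisson(κ·exp(a + b·w)), with a Gamma–Poisson
(negative-binomial) option `fecundity_dispersion` > 1 because the
original quasi-Poisson fit implies possible overdispersion of unknown
magnitude; offspring sex ratio ~ Beta with mean 0.5 and concentration
200. All randomness flows from one seed through `SeedSequence`
substreams, one per treatment.

The paper-like preset fixes a = 5.95 and b = 2.37 and solves the
fecundity multipliers in closed form — E[F] = κ·exp(a + b·μ_w + b²σ_w²/2)
for lognormal-mixed Poisson counts — so that expected mean fecundity is
1425 (guava strain) and 1047 (eucalyptus strain) on guava, pooling to
the reported 1236 on a guava diet, and 915 for both strains on
eucalyptus. Female weight μ_w = 0.35 g, σ_w = 0.04 g (the scale of the
reported pupal weights); female development means 38 / 42 / 44 / 44
days (guava×guava / eucalyptus×guava / both × eucalyptus) put
generation time (development + 3-day pre-oviposition + oviposition
midpoint) at 43–49.5 days, inside the reported 41–51 day range.
Survival is 0.8 in every cell and treatment effects enter only through
development means and fecundity multipliers, mirroring the finding
that juvenile survival did not differ between treatments. This yields
the qualitative four-treatment pattern — both strains better on guava;
the eucalyptus strain significantly worse than the guava strain on
guava; the strains matched on eucalyptus — which the pipeline recovers
with non-overlapping CIs in ≥95% of seeded replicates at n = 200 per
treatment.

What the generator does *not* emulate: parent-pair and leaf-tree
random effects (individuals are exchangeable within a cohort), adult
mortality, egg fertility, death-time clustering, or any
weight–development correlation. Passing tests therefore demonstrate
correctness of the estimators and calibration of the generator, not
robustness of the original biological conclusions to those real-data
features.

## Numerical and design choices

- Root finder: Brent on a monotone bracket, residual tolerance 1e-10;
  deterministic. The original analysis does not state its solver, so
  the tests compare against an independent naive grid-scan + bisection
  oracle (agreement to 1e-8 on 1,000 random schedules).
- The oviposition window is the closed set of exactly ω integer days
  starting at T + π.
- Weight truncation at zero is ignored in the calibration closed form
  (the truncated mass is ~1e-18 at μ/σ ≈ 9).
- Problem sizes in the test suite (10,000-individual calibration
  cohorts, 500 coverage cohorts of n = 50, 100 pattern-recovery
  replicates at n = 200, 2,000-female regression recoveries) were
  chosen so Monte-Carlo error is well below the tested tolerances
  while the full suite runs in about a minute.
- CSV reports are written with fixed float formatting and the run
  manifest contains no wall-clock state, so a fixed (inputs, config,
  seed) triple reproduces every report byte for byte.

## Limitations

- No censoring support: lost individuals cannot be represented.
- No Cox / mixed-effects survival or trait models; the CI-overlap rule
  is the only comparison criterion (no GLM confirmation, no multiple-
  testing correction).
- The fixed 3 + 6 day reproductive window is a strong simplification;
  conclusions sensitive to adult lifespan are out of reach.
- Jackknife CIs are approximate for the strongly nonlinear r_m at
  small n; the coverage test characterises R₀ only.
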