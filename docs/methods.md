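# Methods

## The problem

Standardized gill-net surveys of six large northern-Minnesota border
lakes (Lake of the Woods, Lake Vermilion, Lake Kabetogama, Namakan Lake,
Rainy Lake, Sand Point Lake) index the relative abundance of Walleye,
Northern Pike and Yellow Perch as catch per unit effort (CPUE): fish
caught per standardized gill-net set.  In 2000 the rules governing
reservoir water levels in the Rainy-Namakan complex changed ("2000 Rule
Curves"), affecting four of the lakes (the impact lakes: Kabetogama,
Namakan, Rainy, Sand Point) and leaving two unaffected (the control
lakes: Lake of the Woods, Vermilion).  The package implements a
before-after, control-impact (BACI) analysis of these counts: estimate
the change in mean catch per set between the decade before the change
(1990-1999) and a lagged decade after it (2005-2014), per lake and
species, and ask whether any impact lake's change is distinguishable
from the changes observed at the control lakes.

## Data rules

One row of the canonical table is one gill-net set x species: lake,
station, year, species, count, role.  Three inclusion filters apply:

* **Station consistency.**  Sampling locations drifted over the decades;
  only stations sampled in every year their lake was sampled within the
  1990-2014 window are retained (strict mode, the default).  A looser
  mode (sampled in at least one year of each period) is available for
  sensitivity.  The required-year set for a lake discounts years removed
  by the lake exclusions below.
* **Lake exclusions.**  Namakan Lake before 1993 (methodology change)
  and Sand Point Lake 1992 (no data) are dropped by default; the rule
  list is configurable.
* **Period assignment.**  Records are labelled Pre (1990-1999) or Post
  (2005-2014); 2000-2004 is dropped.  The five-year lag reflects that
  adults recruit to the gear at age 2-3, so post-change year classes
  only dominate catches several years after the change.  A 2006-2014
  "after" variant is reachable via configuration.

Each filter is split into a *plan* (the keep/drop decision context,
computed once from the raw table) and a pure row predicate that applies
it.  With a shared plan the three filters commute, so the pipeline result
does not depend on filter order; this is asserted by property tests.  The
provenance log records records-in/removed/out per filter, and
input = retained + removed always holds.

## The model

Counts are non-negative integers, but fish are not randomly dispersed:
schooling (Yellow Perch) and habitat affinity (Northern Pike) make
catches "clumped", i.e. overdispersed relative to Poisson.  Within one
lake x species x period group, set *i*'s count is modelled
hierarchically:

    c_i | lambda_i ~ Poisson(lambda_i)
    log lambda_i   ~ Normal(mu, sigma)

The log-normal layer carries among-set variation (sigma = 0 collapses to
pure Poisson; sigma is the "clumping" parameter), the Poisson layer the
sampling variation.  The reported group quantity is the expected catch of
a fresh gill-net set,

    M = exp(mu + sigma^2 / 2),

the lognormal-layer mean.  This is a deterministic function of (mu,
sigma) per posterior draw.  The alternative summary — the average of the
realized latent set means — is available via `mean_kind="latent"` for
sensitivity; the population mean is the default because it is the
model's prediction for a new set rather than a summary of the sets
already observed.

Priors default to mu ~ Normal(0, 100^2) and sigma ~ Uniform(0, 10]:
deliberately diffuse relative to group sizes in the tens-to-hundreds of
sets.  Both are configurable; note the caveat about diffuse priors and
tiny groups below.  sigma = 0 exactly is allowed in `derived_mean` (the
Poisson limit) but lies outside the sampler's support.

## Inference

`fit_group` runs Metropolis-within-Gibbs:

1. **Latent log-means**: elementwise random-walk Metropolis (the
   conditionals are independent across sets given mu, sigma).
2. **mu**: exact conjugate normal Gibbs draw given the latents and sigma.
3. **sigma**: random-walk Metropolis on log sigma with the Jacobian
   correction, rejecting proposals outside (0, upper].
4. **Scale move**: a joint proposal sigma' = e^u sigma,
   l_i' = mu + e^u (l_i - mu).  The standardized residuals are invariant
   under this map, so the hierarchy terms cancel against the Jacobian and
   the acceptance ratio reduces to the Poisson terms plus u.  This move
   travels along the (sigma, latents) "funnel" that elementwise updates
   traverse slowly; without it, groups whose posterior concentrates near
   sigma = 0 (near-Poisson data) mix an order of magnitude slower.

Step sizes adapt toward a 0.44 acceptance rate during burn-in only, so
every retained draw comes from a fixed, valid kernel.  Defaults are 3
chains x 30,000 iterations, 5,000 burn-in, thin 5.  Chains are seeded by
spawning a `numpy.random.SeedSequence` from the configured seed; a run
is bit-reproducible from (data, priors, config, seed).  The inner loop
is compiled with numba; all randomness flows through the numpy Generator
passed into the kernel.

Diagnostics attached to every fit: the classic Gelman-Rubin potential
scale reduction factor (between/within variance form; the pipeline flags
a group when PSRF > 1.05 for mu, sigma or M) and an effective sample
size from FFT autocorrelations with Geyer's initial-positive-sequence
truncation.  Note the classic PSRF equals sqrt((N-1)/N) ~ 0.999, not
exactly 1, for identical chains.

## The brute-force oracle

`grid_posterior` computes the posterior of M without Monte Carlo: for
each point of a dense (mu, sigma) grid the latent log-mean of every set
is integrated out by Gauss-Hermite quadrature (the marginal likelihood
factorizes over sets), the prior is applied, and the grid is normalized
with trapezoid weights.  Cost is linear in the number of *distinct*
count values, so both toy groups and homogeneous larger groups are
cheap.  The sigma grid edges coincide with the prior's support
boundaries, where finite density is legitimate; mass on the mu edges (or
on a sigma top cut short of the prior bound) raises an error demanding
wider bounds.  All-zero counts leave the likelihood flat as mu -> -inf,
so the default bounds then extend to cover the prior's left tail.

The oracle-equivalence test battery fixes twelve count vectors (n = 2-4,
counts <= 10) and compares MCMC against the grid under moderately
diffuse priors (mu ~ N(0, 10^2), sigma ~ U(0, 2]).  Under the pipeline's
fully diffuse defaults the posterior *mean* of M for an n = 2 group is
dominated by the sigma -> 10 prior-bound corner — the marginal
likelihood decays only like sigma^-n while M grows like
exp(sigma^2 / 2) — so that mean is a prior artifact with enormous
Monte-Carlo error and is not a meaningful comparison target; the
battery's priors keep the comparison sharp while remaining diffuse
relative to the data.  Agreement is asserted within 2% for well-resolved
quantities; where the Monte-Carlo error of a heavy-tailed mean or a tail
quantile exceeds that (posterior sd of M can be 2-3x its mean at n = 2),
the tolerance is the larger of 2%, 0.05 absolute, and 3.5x the per-chain
standard error of the quantity, with at least 10,000 retained draws.

## BACI decision rules

For each lake x species with both period fits, the before-after effect
is D = M_post - M_pre, formed by pairing the two independent posteriors
by retained-draw index (any pairing is statistically equivalent; the
fixed one is reproducible) after truncating to the shorter run.
Summaries are the posterior mean, the equal-tailed 95% credible interval
(numpy's linear interpolation between order statistics), and P(D > 0).

Decisions use closed intervals: an endpoint exactly at zero does not
exclude zero, and touching intervals overlap.  An impact lake is
*distinct-from-all-controls* for a species when its 95% interval for D
overlaps no control lake's interval; otherwise
*consistent-with-some-control*.  The full pairwise overlap matrix is
reported rather than only the verdicts, because with two control lakes
that themselves disagree, which control is consulted can reverse the
conclusion — the per-control overlap flags make that visible.  No
multiple-testing correction is applied across the 18 lake x species
rows, matching the monitoring analysis this package reimplements.

## Synthetic data

`simulate_group` draws exactly from the fitted model's data-generating
process; `simulate_study` assembles groups into the canonical table with
a stations x years layout that passes every default filter unchanged.
Defaults mimic the monitoring program: 10 stations x 10 years per period
per lake, 2 control + 4 impact lakes, true mean catch 8 fish/set and
sigma = 0.6 (counts mostly 0-60, matching the Walleye/Yellow Perch CPUE
scale).  Seeding is counter-based — one study seed expands into a
substream per (lake, species, period) keyed by a CRC32 of the group name
— so adding a group never perturbs another group's counts.

What the generator does *not* emulate, and the fitted model does not
assume: temporal autocorrelation across years, spatial correlation
between stations, species interactions, and any year-within-period
effect (sets are pooled within a period).  Passing recovery and
calibration tests on this generator therefore validates the machinery
under the model's own assumptions, not robustness to their violation in
real surveys.

## Validation experiments (sizes as run by the test suite)

* **Oracle equivalence** — 12 toy vectors, 4 chains x 60,000 iterations
  (43,200 retained draws), tolerances as above.
* **Parameter recovery** — 200 groups of n = 100 sets with mu ~ U(-1, 2),
  sigma ~ U(0.2, 1.5): the 95% interval for M must cover the truth in
  90-98% of replicates.  Bias of the posterior mean of M is measured at
  mu = 1, sigma = 0.8 over 200 replicate groups.  Under the diffuse
  defaults the posterior mean of M carries a positive small-sample bias
  (the sigma^2/2 exponent amplifies posterior sigma uncertainty), which
  is part of what this experiment quantifies.
* **Null calibration** — 200 no-effect studies at the default scale
  (1,200 lake rows, 2,400 group fits; 2 chains x 5,000 iterations per
  fit): the zero-exclusion rate must sit in the binomial 95% band around
  5%, and distinct-from-all-controls verdicts must be rarer still.
* **Plumbing** — filter outcomes on hand-built toy tables, and the
  interval logic against an exhaustive independent oracle on 1,000
  random interval pairs.

Chain lengths in the simulation experiments (2 chains, 4,000-5,000
iterations) were chosen so that quantile Monte-Carlo noise does not
distort the calibration rates: with ~1,400 retained draws the estimated
interval endpoints are noisy enough to inflate the null zero-exclusion
rate from ~5% to ~8%; at ~4,000 retained draws (ESS of M above ~2,000)
the inflation is negligible.

## Reproducing the published six-lake table

The published analysis deposited its raw data as a supplementary
workbook that is not redistributable inside this package, so the
end-to-end numeric reproduction runs only when that workbook (or its CSV
export) is placed at `data/deposited_gillnet_catch.xlsx` /
`data/deposited_gillnet_catch.csv`.  The published 18 difference
estimates and credible intervals are embedded in
`bacipln.reference` and the decision-rule layer is validated against
them directly: the zero-exclusion flags, the Vermilion-overlaps-all-
impacts statement for Walleye, and the Kabetogama Yellow Perch
distinct-from-both-controls finding are all recomputed from those
intervals by the package's own interval logic.

## Known limitations

* Verdicts inherit the credible-interval-overlap rule's conservatism:
  two posteriors can overlap while the posterior of their difference
  excludes zero.  The rule is implemented as published; the overlap
  matrix output lets users apply stricter contrasts downstream.
* The posterior mean of M is not a finite-variance summary for very
  small groups under the diffuse default priors (see the oracle section);
  for n below ~10 sets, report the median or tighten the sigma prior.
* Counts are assumed complete and correctly keyed; there is no effort
  standardization beyond "per gill-net set" and no georeferencing.
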