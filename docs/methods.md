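# Methods

## Demographic model and conventions

The model is a single-sex, discrete-time, birth-pulse life cycle. An
individual of age x produces on average b_x offspring — counted as recruits
surviving to age 1 — and survives to age x+1 with probability v_x; cumulative
survivorship is l_x with l_1 = 1. A constant population with N₁ recruits per
cohort has census sizes N_x = round(N₁ l_x) and requires Σ l_x b_x = 2 in
single-sex accounting with an even primary sex ratio. `stabilize_fecundity`
pins any relative fecundity schedule to that identity with a single
multiplicative constant, so stabilization is idempotent and
shape-preserving.

A terminal "plus-group" pools all ages beyond the last tracked age. It
carries a *pooled* survivorship (supplied, not chained from v), is exempt
from the monotonicity check, enters the ANOVA as a single group, and uses its
nominal first age in generation-length and longevity arithmetic. Because a
pooled class can outnumber the preceding single-age class, age-at-death
counts from successive census differences are undefined for such tables;
`cohort_structure` returns no death structure in that case rather than a
negative count.

Generation length is computed as the mean age of parents of newborns in the
stable population, T = Σ x l_x b_x / Σ l_x b_x.

## Sampling intensity and rescaling

Q = Σ l_x k̄_x / 2 (annual) or mean LRS / 2 (lifetime) indexes the sampling
effort relative to the 2N₁ offspring a stable population produces. Q is
carried at full precision everywhere; printed values such as 0.05 are display
rounding (the black bear table only reproduces with Q ≈ 0.0499). One common
Q, estimated from the total offspring sampled, rescales every group of a
dataset:

    b̂ = k̄ / Q,        σ̂² = b̂ · [1 + (s²/k̄ − 1)/Q].

The rescaled variance is the expected variance had sampling been at the
stable level. It is exact at Q = 1 and maps Poisson dispersion (s² = k̄) to
σ̂² = b̂ at any Q. Underdispersed raw data can drive it negative; the two
estimators resolve this differently (below). A zero raw mean leaves the
dispersion ratio undefined and yields σ̂² = 0 with a flag.

## Annual estimator

With per-age statistics rescaled, the estimators are

    SSE-hat = Σ N_x σ̂²_kx
    SSB-hat = Σ N_x (b̂_x − b̄̂)² − (n−1)/n · Σ_x σ̂²_kx

where b̄̂ = k̄·/Q is the rescaled size-weighted grand mean and the correction
sums the rescaled variances **unweighted** over the n observed age groups
(the degrees-of-freedom factor reflects the constraint that the age means
average to the grand mean). Two Poisson references for SSE are exposed: the
default uses age-varying means (Σ N_x b̂_x), the alternative the constant
Wright–Fisher mean (b̄̂ N_A); they differ only through rounding of the census
vector.

**Negative rescaled variances.** The annual estimator by default *drops* an
age whose rescaled variance is negative, removing it from every sum and from
n (flagged, overridable with `drop_negative_variance=False`, which clamps to
0 and keeps the group). Rationale: a negative value means the raw data are
less dispersed than subsampling any stable-scale distribution could produce,
so the rescaling model is inconsistent for that group; keeping it with a
clamped zero variance leaves its between-age term uncorrected, which
measurably biases the partition upward in SSB under sparse sampling. In the
package's own simulations (increasing fecundity, φ = 1, N₁ = 100, Q = 0.2)
dropping gives a mean within-age share near 0.77 and an SSB recovery within
~2% at N₁ = 500, whereas clamp-and-keep pushes the mean share below 0.70.
Ages with a zero raw mean are retained (they are data, not model failures).

Parametric variance conventions are kept explicit and never mixed: the
population variance is σ²_k = SST/N (denominator N), while per-group sample
variances use n−1. Sums of squares scale linearly in N₁, so the
within/between split is independent of population size.

## Lifetime estimator

Groups are ages-at-death q with sizes D_q; the age-at-death of an individual
is the oldest age with an *observation* (an observed zero is a breeding
attempt; a missing year neither extends the lifespan nor adds offspring).
The rescaled group mean estimates cumulative fecundity Σ_{x≤q} b_x, compared
against the stable-population grand mean of 2 lifetime offspring:

    SSE•-hat = Σ D_q σ̂²•_q
    SSB•-hat = Σ D_q (Σb̂_x − 2)² − (n−1)/n · Σ_q σ̂²•_q
    SSB•-longevity = Σ D_q (q b̄̂ − 2)²,   b̄̂ = 2N₁ / Σ q D_q

The random correction is unweighted by default, matching the estimator's
worked-example arithmetic; a D_q-weighted variant is available
(`weighted_correction=True`) since the two readings of the estimator differ
and the weighted one removes more at large groups. Here negative rescaled
variances are **clamped to 0 and the group kept** — a death group still
carries irreplaceable between-group information (its members' cumulative
LRS), and this is the convention the framework's published lifetime analyses
use. The Poisson reference for SSE• accumulates the constant rescaled mean
over the years lived, D_q · q · b̄̂ per group (the per-group convention of the
reference tables); its total equals 2N₁ under either the constant-mean or
group-mean convention.

The closed parametric forms assume an individual's reproduction at one age
is independent of its survival and reproduction later. Persistent individual
differences or skip breeding violate this; they do not bias the empirical
SSE• computation but load entirely on the within component. The
`rho_alpha_plus` index (product-moment correlation between reproduction at
maturity and the summed remainder of life, two-tailed t-approximation
p-value) screens for such effects; missing maturity-age entries are treated
as zero offspring with a flag, since the individual demonstrably recruited
later.

## Effective size and opportunity for selection

Annual N_b uses the discrete-generation inbreeding formula with the overall
variance assembled through Σk²_i = N(σ² + k̄²) age by age — the route is
numerically identical to a direct variance but lets published per-age tables
drive it. Per-generation N_e uses the 4N₁T/(σ²_LRS + 2) approximation; a
two-sex N_b combines per-sex values as 4ab/(a+b).

Annual I and ΔI = I − 1/k̄ are computed on the **rescaled** scale (they are
sampling-dependent otherwise); lifetime I• and
ΔI• = I• − 1/mean_LRS − C are deliberately computed on the **raw** scale,
where the longevity expectation C = Σ D_q (q − q̄)² / (q̄² Σ D_q) is
sampling-independent. Reductions of N_b/N_A below the Wright–Fisher value of
1, and ΔI, are apportioned between within-age and between-age effects in
proportion to the greater-than-random components SSE-hat − SSE_null and
SSB-hat.

## Simulator

Annual replicates allocate a fixed total of round(Q·2N₁) offspring among the
standing N_A parents by weighted multinomial draw (fixed totals, matching
the conditional design of the validation study, rather than Poisson totals).
Overdispersion uses mean-1 gamma parental weights. The weight variance has a
closed form: with CV² = (φ_x − 1)/b_x, a parent's count is Poisson-gamma
with raw dispersion 1 + Q(φ_x − 1), which the Crow–Morton rescaling maps
back to exactly φ_x — so the calibration is analytic, and a test confirms
realized rescaled dispersion tracks the target within Monte Carlo error.
Weights cannot produce φ < 1. Survival is an independent Bernoulli(v_x) per
individual-year.

Lifetime replicates follow one cohort from maturity to death, drawing yearly
counts as Poisson(Q b_x w); embedded in a large stable population the
cohort's draws are effectively unconstrained, so no fixed yearly total is
imposed. Persistence retains each individual's latent uniform rank for life
and pushes it through the age-specific gamma quantile each year, creating
positive temporal correlations in reproductive success with unchanged
yearly marginals — hence inflated SSE• at unchanged SSB•. Offspring
subsampling is multivariate-hypergeometric thinning (expected total Q·total,
Poisson shape preserved).

What the simulator does *not* emulate: two-sex mating and sex-ratio
dynamics, density-dependent vital rates, year (environmental) effects shared
across individuals, skip-breeding dynamics, and reproduction-survival
trade-offs. Passing validation therefore shows the estimators recover the
parametric partition under independent, stationary reproduction — not that
real datasets are free of those confounds (the annual SSE of any multi-year
field dataset, for instance, absorbs a year effect of unknown size).

## Bootstrap

The resampling unit is the individual (whole lifetime row); Q, the groups,
the rescaling and the partition are re-derived within each replicate, since
Q is itself data-derived. Intervals are empirical percentiles (2.5/50/97.5);
bias-corrected variants were not implemented. Replicates collapsing to a
single age-at-death group are skipped and counted, except when the original
cohort already has a single group (then every resample does, and the
statistic is degenerate but well-defined). Interval width shrinks with
cohort size; with very few long-lived, high-LRS individuals the intervals
are wide and dominated by how often those rows are resampled.

## Problem sizes and numerics

Validation runs use 5 age classes, 50% survival, N₁ = 100–500, and
2000–4000 replicates (standard error of the mean within-share ≈ 0.002 at
4000), which keeps the full test suite near ten seconds; estimator
recoveries are asserted at 2% (SSE) and 5% (SSB) relative tolerance against
parametric values. Assertions against published table values run at 1%
relative tolerance because the driving inputs are printed at 2–3 decimals.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical scenario + seed is bit-reproducible.
Census rounding uses round-half-to-even via `numpy.rint`, with the
plus-group's pooled survivorship taken as given.

## Known limitations

* The annual drop-vs-clamp choice for underdispersed groups changes sparse-
  sampling results; both paths are exposed, and analyses of data with many
  underdispersed ages should report both.
* Lifetime closed forms ignore temporal covariances of individual
  reproduction; use the simulator's persistence mode and `rho_alpha_plus` to
  gauge sensitivity.
* The bootstrap covers the lifetime pipeline only; annual analyses driven by
  per-age summary statistics carry no resampling-based uncertainty (raw
  per-individual annual data would be required).
* Probabilistic age at maturity is handled only implicitly, by averaging
  vital rates over mature and immature individuals in the input table.
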