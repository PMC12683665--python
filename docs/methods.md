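# Methods

## The analysis problem

A salinity-screening trial observes each petri dish at a few fixed
inspection days (here 1, 2, 3 and 6 days after sowing, DAS) and records how
many seeds germinated since the previous visit. A seed's germination time is
therefore *interval-censored*: it is only known to lie in (D_{t-1}, D_t],
with D_0 = 0 at sowing, and seeds that never germinate within the trial are
right-censored on (6, inf). Treating the interval midpoint or the count day
as an exact event time biases timing statistics, especially under stress
where germination is delayed; the package instead works on the censoring
intervals throughout.

## Nonparametric time-to-event model

The cumulative germination probability F is estimated by the Turnbull
nonparametric maximum-likelihood estimator (NPMLE). All NPMLE mass lives on
the *innermost* (maximal-intersection) intervals: candidate (q, p] where q
is an observed left endpoint, p an observed right endpoint, and no other
endpoint falls strictly between them. Masses w_j on those intervals maximize

    L(w) = prod_i  sum_{j : (q_j, p_j] subset (L_i, R_i]} w_j ,

a concave objective over the probability simplex, solved by the
self-consistency EM update from a uniform start. Numerical policy:

- convergence when the largest mass change drops below 1e-8
  (cap 10 000 iterations), **or** when the certified optimality gap
  n (max_j d_j - 1) — d_j the EM multiplier — falls below 1e-6. The second
  criterion matters when the optimum has a mass exactly 0: such boundary
  solutions are approached only sublinearly in the masses, while concavity
  certifies the attained log-likelihood long before. Non-convergence is
  flagged on the fit and warned about, never silent.
- F is exact at Turnbull right endpoints and on the plateaus between
  intervals. Inside a Turnbull interval any non-decreasing path maximizes
  the likelihood; the package's declared representation is linear
  interpolation, and `cdf_at` flags such points as indeterminate (the region
  a germination curve would shade as censoring uncertainty).
- With only exact events and right censoring the estimator reduces to
  Kaplan-Meier; the test suite cross-checks this against lifelines, and
  checks global optimality against a brute-force simplex grid search on
  small instances.

**T50.** The reported T50 is the time to reach 50% of the *germinated*
seeds — the target is 0.5 F(final), so the statistic estimates the median
latent germination time of viable seeds and is invariant to the
non-germinating share. The generic `quantile_time(fit, p)` works on the
absolute (sown-seed) scale and reports the quantile as undefined when the
attainable F stays below p. Crossings are linearly interpolated, which is
what makes sub-day values like 0.8 DAS possible on a day-1-first schedule.

**SE of T50.** A nonparametric bootstrap (default B = 500; B = 200 in the
pipeline drivers) resamples seeds with replacement *within* dishes —
respecting the experimental design — refits the NPMLE and re-extracts the
quantile; the SE is the standard deviation across replicates. Replicates
with an undefined quantile are dropped and counted; if more than half are
undefined the SE is reported undefined. A simulation test checks the
bootstrap SE against the Monte-Carlo sd of T50 over fresh datasets.

**Group comparison.** Per-seed generalized Wilcoxon scores are computed
against the *pooled* NPMLE over all groups entering a comparison:
u_i = S(L_i) + S(R_i) - 1 with S = 1 - F and S(inf) = 0. Scores sum to ~0
over the pool; a positive group sum means earlier-than-pooled germination.
The equality test uses the statistic sum_g (group score)^2 / n_g and
permutes group labels; the p-value uses the add-one estimator
(1 + #{permuted >= observed}) / (1 + n_perm), so p = 0 is impossible.

**Permutation unit.** The default unit is the dish — the experimental unit,
robust to within-dish correlation. A caveat discovered while validating the
type-I error: with only 3 dishes per group and 2 groups there are just 20
distinct label assignments, and the statistic is invariant under swapping
the two group labels, so the smallest attainable p-value is about 0.10 and
a test at alpha = 0.05 can never reject. The type-I calibration simulation
therefore runs at seed level (`unit="seed"`), which is exact under its null
(independent seeds, no dish effect); with realistically many dishes the
dish-level test is the one to use, and both are exposed.

## Germination indices

Per dish, with N_t new germinations at day D_t, G the final germinated
count, Ntot sown and Nnorm normal seedlings: TG = G/Ntot x 100,
VC = G / sum(N_t D_t), GI = sum(N_t / D_t), MGT = sum(N_t D_t)/Ntot,
GSI = sum(N_t (N_t - 1)) / (G (G - 1)), NR = Nnorm/G x 100. Two
conventions are worth flagging:

- MGT divides by the *sown* count, exactly as the trial protocol defines
  it, even though the field's conventional MGT divides by germinated seeds;
  `mgt_denominator="germinated"` selects the conventional variant. With the
  default, MGT x VC = G/Ntot holds algebraically and is enforced to 1e-12
  in tests.
- GSI is undefined for G <= 1 and NR for G = 0 (division by zero in the
  formulas); undefined values propagate as NaN and are column-mean imputed
  only at the multivariate stage, with a logged count.

**STIs.** A stress tolerance index is the ratio of an index at 200 mM NaCl
to its control value. Aggregation is per-dish indices -> mean over
replicates within accession x treatment -> ratio of means (stabler than
mean-of-ratios near zero denominators; the alternative is available via
``aggregation="mean_of_ratios"``). STI is undefined (not 0) when the
control value is 0. The seedling vigor index is
SVI = germinability(%) x (mean shoot + main-root + lateral-root length, mm);
germinability stays on its printed percentage scale since any scale cancels
in STI_SVI.

## Multivariate screening

The accession x STI matrix is standardized to zero mean, unit variance
(indices live on different scales) before PCA and clustering. PCA signs
follow a largest-loading-positive convention so outputs are stable.
Clustering is hierarchical k-means: a Ward-linkage cut at k seeds Lloyd's
refinement, which can only lower the within-cluster sum of squares —
making the partition deterministic given (features, k, seed). Labels are
renumbered 1..k by descending size. k defaults to 3 and is a parameter;
automatic k selection is out of scope. Clustering operates on the six STI
columns, with PC1/PC2 attached for display.

Cluster contrasts use Kruskal-Wallis (tie-corrected) with Dunn's test,
z = (mean-rank difference)/sqrt((N(N+1)/12 - tie term)(1/n_a + 1/n_b)),
Bonferroni-adjusted over pairs. The gradient experiment's static endpoints
(TG%, abnormality%) use one-way ANOVA with all-pairs contrasts on the
pooled error variance and Sidak adjustment 1 - (1-p)^m (Tukey's HSD behind
a flag); the two rank/parametric paths both emit compact letter displays
built by the insert-and-absorb algorithm.

## The synthetic-trial generator

The generator exists so every stage is testable without the deposited raw
data. Its model: a seed is viable with probability pi (pi0 under control,
pi0 * rho under salt); viable seeds draw a latent time
T ~ lognormal(mu_dish + log(delta) under salt, sigma), with a dish random
effect mu_dish ~ N(mu_acc, tau) and a small accession effect
(sd 0.04 log-DAS) inside each archetype; counts are T binned by the
schedule; abnormality is Bernoulli(alpha) among germinated. Seedling
lengths are Gamma (cv 0.25) with archetype control means and salt
multipliers. Parameters are anchored at the 200 mM screening concentration
and interpolate linearly in concentration for the 0-300 mM gradient.

Default archetypes mirror the three screening phenotypes:

| archetype | n  | median (DAS) | delta | pi0  | rho  | trait STIs (shoot/main/lateral) |
|-----------|----|--------------|-------|------|------|--------------------------------|
| C1 slow-but-complete | 32 | 0.85 | 1.75 | 0.97 | 0.90 | 0.53 / 0.29 / 0.17 |
| C2 germination-susceptible | 9 | 0.80 | 2.00 | 0.95 | 0.60 | 0.47 / 0.23 / 0.07 |
| C3 fast-but-frail | 14 | 0.65 | 1.35 | 0.98 | 0.90 | 0.24 / 0.15 / 0.04 |

Choices and why:

- **Log-normal latent times**: right-skewed, positive, and a delay that
  multiplies the median is a single shift on the log scale — the simplest
  two-parameter family matching the delay mechanism.
- **sigma = 0.6 log-DAS**: germination in these trials continues across the
  whole 1-6 DAS window; a much smaller sigma would put nearly all
  germination into one inspection interval, which the recorded multi-day
  counts contradict.
- **sigma_salt_mult = 0.6**: stress synchronizes germination in this
  system; the salt arm's log-sd shrinks accordingly. Limitation: because
  the control distribution is itself concentrated in the first inspection
  interval, the synthetic synchrony ratio STI_GSI lands near 1 rather than
  above it as observed in real screens — the generator reproduces the
  viability and timing structure of the clusters, not the synchrony gain.
- **tau = 0.05 log-DAS** gives realistic replicate-to-replicate
  overdispersion relative to pure binomial noise.
- The archetype counts are the printed per-cluster sizes (32/9/14, summing
  to 55; the trial description's headline accession count disagrees with
  its own cluster sizes, and the per-cluster counts are what the recovery
  tests anchor on). Likewise the seedling design uses the printed 7/3/4
  cluster representatives (14 genotypes).
- Ground-truth tables (archetype, per-accession latent median, delta, rho)
  are always emitted beside the data: the testable surface is parameter
  recovery, and the acceptance checks measure exactly that (T50 ratio vs
  delta, STI_TG vs rho, Rand index vs archetype membership).

What the generator does *not* emulate: dose-specific ion-toxicity
mechanisms (treatment acts only through delta, rho, alpha and the length
multipliers), seed-lot heterogeneity beyond a log-median shift, secondary
dormancy, or the synchrony gain noted above. Passing recovery tests
demonstrates the *estimators* are consistent under the assumed data
mechanism, not that the mechanism captures everything in real trials.

## Problem sizes used in tests and the acceptance script

Simulation sizes match the trial design (3 dishes x 50 seeds per
accession x treatment; 5 boxes x 11 seedlings): the statistical behaviour
being checked is at-design-size behaviour. The type-I calibration uses
1000 simulations x 199 permutations; the grid-search oracle checks 200
random instances at step 0.01 with at most 4 Turnbull intervals; the
large-n consistency check pools 10 dishes of 3000 seeds on a 0.2-day
inspection grid, since on the coarse 1/2/3/6 schedule the
binning-plus-interpolation bias in T50 (a few percent) does not vanish
with n — that bias is a property of the schedule, shared by any method
that interpolates within inspection intervals.

## Known limitations

- The NPMLE inside Turnbull intervals is representationally undefined;
  quantiles inherit the linear-interpolation convention, so T50 values that
  fall inside a wide first interval are convention-dependent.
- Wilcoxon score magnitudes depend on the pooled-fit scope (all groups of a
  comparison are pooled here); orderings and signs are the robust surface.
- Dish-level permutation needs enough dishes per group to resolve small
  p-values (see above).
- STIs with near-zero control denominators are unstable; ratio-of-means
  mitigates but does not remove this, and undefined STIs are imputed only
  for clustering, never for the univariate contrasts.
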