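# Methods

This note documents the statistical procedures, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the known
limitations.

## Study design assumed

All procedures assume a nested layout: regions ⊃ sites ⊃ fields ⊃ plot pairs,
with one intensively and one extensively managed field per site, paired
drought/control plots within fields, and two sampling timepoints (day 0 =
immediately post-drought, day 60 = post-recovery). The default dimensions are
3 regions × 5 sites × 2 fields × 3 pairs × 2 treatments = 180 samples per
timepoint. Metadata validation enforces the nesting (each site in one region,
each field in one site) and drought/control pairing within
(field, pair, timepoint) cells.

## Rarefaction

Each sample is subsampled without replacement (multivariate hypergeometric,
`numpy.random.Generator.multivariate_hypergeometric`) to a fixed depth
(default 9000 reads). Samples with fewer total reads than the depth cannot be
rarefied and are dropped and reported; this generalizes removal of zero-read
samples to all sub-depth samples, which is standard practice. One draw per
explicit seed; no hidden global RNG state. Whether to rarefy once or average
over repeated draws is an open choice in the field; a single seeded draw keeps
every downstream number exactly reproducible.

## Dominance screen

A taxon is dominant when it is (a) present (≥ 1 read in ≥ 1 sample) in every
occupancy unit — sites by default, regions as an alternative — and (b) within
the top `floor(q·n)` of the `n` taxa with nonzero reads, ranked by relative
abundance summed over all samples (q defaults to 0.10). Occupancy pools all
treatments and timepoints. Ties at the rank boundary are broken by
lexicographic taxon id so results are deterministic. Summed (equivalently
mean) relative abundance is used as the ranking statistic because it is
invariant to the number of samples at equal depths. The two filters commute;
the screen reports both intermediate sets.

## Per-taxon drought test

The model of record for one taxon at one timepoint is a count regression with
log link: treatment fixed effect plus one intercept per field, with
`log(library size)` as offset (constant `log(depth)` after rarefaction, making
the treatment coefficient a log relative-abundance effect). Field intercepts
absorb site and region, so the treatment effect is a within-field contrast —
a consistent approximation to nested random intercepts on a balanced design.

Three families are supported:

- **Negative binomial (NB2)**, `Var = mu + alpha·mu²`. The dispersion `alpha`
  is estimated by Cox–Reid adjusted profile likelihood inside an iterated GLM
  (MASS `glm.nb` style). The adjustment (subtracting `½ log det(XᵀWX)`)
  removes the downward bias caused by the ~30 nuisance field intercepts;
  without it the Wald test's type-I error at α = 0.05 was ≈ 0.10 in null
  simulations, with it ≈ 0.05. Estimated `alpha` below 1e-8 collapses the fit
  to Poisson (NB nests Poisson; the family label stays NB).
- **Poisson**, the equidispersed limit.
- **Binomial** on presence/absence. Inference uses conditional logistic
  regression grouped by field (statsmodels `ConditionalLogit`), which
  eliminates the per-field intercepts exactly; the unconditional logistic Wald
  test was anticonservative (~8%) with 30 nuisance parameters on 180 binary
  observations.

P-values for the treatment coefficient are two-sided on a t reference with
`df = n_obs − n_params`, a standard small-sample correction when nuisance
parameters are numerous.

### Family selection

Simulation-based quantile-residual diagnostics in the DHARMa tradition: fit a
candidate family, simulate m = 250 replicate response vectors from the fitted
model, compute each observation's randomized ECDF residual
`P(sim < obs) + U·P(sim = obs)` with U ~ Uniform(0,1) (a fixed jitter seed
keeps fits reproducible), and test uniformity with a one-sample KS test.
Families are tried in the order NB → Poisson → binomial; the first whose
uniformity test is not rejected at 0.05 is selected, otherwise the family with
the largest uniformity p-value. Randomized rather than mid-p residuals are
essential: mid-p residuals are non-uniform by construction for heavily
discrete (sparse) counts, and using them made the KS test reject correct NB
fits for low-abundance taxa, routing genuinely overdispersed taxa to an
anticonservative Poisson fit. Data whose counts never exceed 1 go directly to
the binomial family (a count family cannot be informed by binary data).

### Permutation fallback

The design-respecting oracle: statistic = mean of drought-minus-control
differences in per-sample relative abundance over (field, pair) strata; the
null is generated by independently swapping treatment labels within each
stratum (a sign flip of its difference). Two-sided Monte-Carlo p with the
add-one rule `(1 + #{|T*| ≥ |T|})/(1 + n_perm)`, or exact enumeration of all
2^S sign patterns on request (S ≤ 20). Any taxon whose model fit fails to
converge is routed here automatically. With a single stratum the two-sided
exhaustive p is identically 1 (|−T| = |T|); an error is raised only when no
complete drought/control stratum exists.

## Strategy and resilience rules

At day 0: opportunistic iff `p < α` and coefficient > 0; sensitive iff
`p < α` and coefficient < 0; resistant otherwise (α = 0.05, per-taxon, no
multiple-testing correction by default — an optional BH-FDR switch would be a
one-liner on the output table but is deliberately not applied, matching the
per-taxon α convention of the analysis this package implements). Resistant
taxa are not tested for resilience. Non-resistant taxa are re-tested on the
day-60 samples with the family re-selected (day-0 and day-60 fits use disjoint
sample subsets); resilient iff `p ≥ α`. A taxon with zero day-60 reads is
classified not-resilient directly. Taxa with zero day-0 reads are untestable
and excluded from the batch output.

## Group indices and management tests

Standardization divides each taxon's per-sample relative abundance by its
across-sample mean, giving every taxon mean 1, so a group's index sums
member-standardized abundances and its across-sample mean equals the group
size exactly. Mean-division (rather than z-scoring) keeps indices positive,
which the strictly positive group ratios require; z-score and max-division
standardizers are available as alternatives. Ratios with a zero denominator
are undefined for that sample and excluded pairwise (counted in the test
output).

The management test restricts to control plots across both timepoints,
averages ratios to the field level, forms each site's intensive-minus-
extensive contrast, and applies a one-sample t-test to the contrasts:
`df = n_sites − 1` (14 for the full 15-site design), with effect size = mean
contrast and its 95% CI. Sites missing one management are dropped with a
warning. Per-plot ratios are retained for display; testing is at the
field/site level where the pairing lives.

## Synthetic generator

The generator emulates: the full nested layout; a lognormal rank-abundance
baseline (sd 1.2) with a boosted "dominant pool" (25% of taxa, 20× baseline)
so a dominance screen has structure to find; per-taxon lognormal random
effects at site and field level (sd 0.3) creating the nested correlation the
models must absorb; multiplicative drought effects on expected relative
abundances (4× for opportunistic, 0.25× for sensitive taxa at day 0;
persistent same-direction 4-fold effects at day 60 for the not-resilient 22%
of affected taxa); optional per-group multiplicative shifts in intensive
fields; and NB2 counts (dispersion α = 0.5) around `depth × proportion`.
Strategy proportions default to 0.68/0.20/0.12 (resistant/opportunistic/
sensitive), the dominant-bacteria split for this kind of grassland drought
experiment, renormalized.

Because mean total reads equal to the rarefaction depth would put half the
samples below depth (and have them dropped), simulated sequencing depth is
`depth_margin × depth` with margin 2.0 — a realistic raw depth subsequently
rarefied down — so all 180 samples per timepoint survive rarefaction in
practice.

What it does **not** emulate: taxonomic structure, phylogenetic correlation of
responses, zero-inflation beyond what NB sampling produces, pH or other
covariates, plot-level random effects, or sequence-level artifacts. A green
recovery test therefore establishes that the pipeline recovers planted
log-scale effects under NB noise and nested random effects — not that it is
robust to every feature of real amplicon data.

### Compositional contamination is real and intended

Effects are planted on absolute expected abundances and proportions are then
renormalized per sample. When ~20% of taxa bloom 4-fold under drought, the
*relative* abundance of every unaffected taxon falls by a factor ≈ 1/1.5, so
planted-resistant taxa are legitimately detected as (relatively) sensitive.
This mirrors real relative-abundance data and is why recovery criteria are
stated over planted *affected* taxa. The null configuration (all multipliers
1) has no such contamination and is the right world for type-I-error checks.

## Numerical choices

- NB dispersion bounds: alpha ∈ [1e-8, e^5]; profile convergence at 1e-4 on
  the log scale; at most 8 GLM/dispersion iterations.
- Diagnostics: m = 250 simulation replicates; KS at 0.05; jitter seed derived
  from the model seed.
- Permutation: n_perm ≥ 99 enforced; tail comparison uses a 1e-12 tolerance so
  exact ties count as extreme.
- Dominance tie-break: (descending share, ascending taxon id).
- Group-index mean identity is exact to float accumulation (< 1e-9 in tests).
- Batch classification draws one sub-seed per taxon from a seeded generator,
  so per-taxon results are independent of which other taxa are in the batch
  only up to seed order; a fixed taxon list plus seed is fully reproducible.

## Limitations

- Field fixed effects approximate the nested random-intercept structure; for
  severely unbalanced designs a true NB-GLMM would differ.
- Wald-type inference with profiled dispersion ignores dispersion uncertainty
  (as does MASS `glm.nb`); the permutation engine is the assumption-light
  alternative (`engine="permutation"`).
- The binomial branch models presence/absence only; other binary reductions
  are out of scope.
- No compositional (log-ratio) transformations; conclusions are about relative
  abundances, with the contamination effect described above.
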