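# droughtstrat

Classification of dominant soil microbial taxa by drought-response strategy
under nested grassland field designs.

## The problem

In situ drought experiments on grassland soils typically follow a nested
layout: geographic regions containing sites, each site holding a pair of
differently managed fields (intensive vs extensive), each field holding paired
drought/control plots sampled immediately after the drought (day 0) and after a
recovery period (day 60). Given an OTU count table and this design, the
questions are:

1. Which taxa are **dominant** — present in every site (or region) *and* in the
   top 10% of taxa by relative abundance?
2. For each dominant taxon, did drought change its relative abundance at day 0
   — is it **resistant** (no detectable response), **opportunistic** (increase)
   or **sensitive** (decrease)?
3. Did affected taxa recover by day 60 (**resilient**) or not?
4. Does land management shift the balance of these groups?

`droughtstrat` implements this pipeline end to end, plus a synthetic-data
generator that reproduces the design with planted per-taxon effects, so every
stage is testable against a known ground truth.

## Models and statistics

**Per-taxon test.** For taxon *i* with counts `y_ij` in samples *j* of one
timepoint, the model of record is a count regression with a log link,

    log E[y_ij] = log(depth) + field_f(j) + beta * drought_j

where the field intercepts absorb the region/site/field nesting (a within-field
contrast) and `beta` is the log fold-change of relative abundance under
drought. The family — negative binomial NB2 (`Var = mu + alpha mu^2`, with
dispersion `alpha` estimated by Cox–Reid adjusted profile likelihood), Poisson,
or binomial on presence/absence (inference via conditional logistic
regression) — is chosen by simulation-based quantile-residual diagnostics:
simulate replicates from the fitted model, form randomized ECDF residuals, and
test uniformity (Kolmogorov–Smirnov), trying NB, then Poisson, then binomial.
A taxon is opportunistic if `p < alpha` and `beta > 0`, sensitive if `p <
alpha` and `beta < 0`, resistant otherwise (default `alpha = 0.05`,
two-sided). Resistant taxa are not tested for resilience; the rest are
re-tested on day-60 samples and called resilient iff that test is
non-significant. A stratified sign-flip permutation test on paired
drought-minus-control differences serves as a design-respecting fallback and
cross-check.

**Group indices.** For every taxon in a labelled group, its per-sample
relative abundance is divided by its mean across all samples (so each taxon
has mean 1), and these standardized abundances are summed per sample — one
index per group per sample. Management effects on index ratios
(opportunistic:sensitive, resilient:not-resilient) are tested by averaging
control-plot ratios to the field level and testing the per-site
intensive-minus-extensive contrast with a paired t-test (`df = n_sites - 1`).
Log response ratios `ln(intensive / extensive)` are available for any paired
field-level variable.

## Worked example

```python
from droughtstrat import (SimulationConfig, simulate_experiment,
                          run_pipeline, PipelineConfig)

cfg = SimulationConfig(n_taxa=300, management_shift={"opportunistic": 2.0})
table, meta, truth = simulate_experiment(cfg, seed=1)
result = run_pipeline(table, meta, PipelineConfig(seed=2))
print(result.report())
```

```
droughtstrat pipeline report
==============================
samples analysed: 360
dominant taxa: 30 of 300 ranked
strategy counts: sensitive=18, opportunistic=10, resistant=2
resilience counts: resilient=20, not_resilient=8, not_tested=2

Management effect on opportunistic_sensitive ratio (paired across sites)
  t(14) = 9.54, P = 1.678e-07
  effect size = 0.228, 95% CI = [0.177, 0.280]  (n_sites = 15)

Management effect on resilient_not_resilient ratio (paired across sites)
  t(14) = -4.84, P = 0.0002612
  effect size = -1.377, 95% CI = [-1.987, -0.767]  (n_sites = 15)
```

The simulated community plants a 2-fold boost of opportunistic taxa in
intensively managed fields; the paired-site test recovers it as a positive
management effect on the opportunistic:sensitive ratio with 14 degrees of
freedom (15 sites). Planted opportunistic and sensitive effects (4-fold up,
4-fold down under drought) are recovered for 100% of affected dominant taxa in
this run. Note the abundant "sensitive" calls among planted-resistant taxa:
when opportunists bloom 4-fold under drought, every other taxon's *relative*
abundance falls — a compositional effect inherent to relative-abundance data,
not a classifier defect (see `docs/methods.md`).

The same stages are available from a shell:

```sh
droughtstrat simulate --seed 1 --out fixtures/
droughtstrat rarefy --depth 9000 --seed 2 --in fixtures/otu_table.tsv --out rare.tsv
droughtstrat dominance --in rare.tsv --meta fixtures/metadata.tsv --out dominant.tsv
droughtstrat classify --in rare.tsv --meta fixtures/metadata.tsv \
    --dominant dominant.tsv --out labels.tsv --seed 3
droughtstrat run --in fixtures/otu_table.tsv --meta fixtures/metadata.tsv --out results/
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic experiment from the
given seed, runs the complete pipeline (rarefaction, dominance screen,
strategy and resilience classification, group indices, management tests),
prints the run report, and writes its target values as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
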