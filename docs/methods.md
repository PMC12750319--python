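# Methods

## Model structure

The package implements a two-arm decision model for the diagnostic workup
of suspected CNS infection. The observed arm is standard-of-care
microbiological testing, summarized per etiology category as mean lumbar
punctures (LPs), mean etiologic tests and mean days to outcome. The
counterfactual arm applies mNGS at presentation: every expected concordant
patient follows a fixed simplified pathway (positive result: 1 LP, 1
confirmatory test, 2 days; negative result: 1 LP, 0 further tests,
2 days). The model's outputs are the floored, summed differences between
the arms.

Assumptions worth keeping in view:

- The standard-of-care diagnoses are treated as ground truth (the
  reference workup has, in effect, 100% PPV), so the cohort prevalences
  are usable as pretest priors.
- A concordant mNGS result fully truncates the observed workup; clinicians
  order nothing beyond the scenario allowance. Savings are therefore an
  idealized upper bound.
- Discordant patients (false negatives in the infection arm, false
  positives in the autoimmune arm) are assumed to follow the observed
  pathway unchanged; the model assigns them neither savings nor penalty.
- Category-level, not pathogen-level, priors: all DNA viruses share one
  prevalence, and the assay's Se/Sp are constant across categories.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| sensitivity | 0.86 | probability | CSF direct-detection mNGS performance reported in the validation literature |
| specificity | 0.99 | probability | with Se=0.86 gives LR+ = 86, inside the 82.9–93.4 band of LR+ values back-solved (via `implied_lr_positive`) from the published category PPV/prevalence pairs |
| infection_prior | 0.10 | probability | overall pretest probability of infection in the suspected-autoimmune arm; the published NPV of 0.984 back-solves to ≈0.103 under the default Se/Sp, and 0.10 is kept as a round, transparent default |
| positive scenario | 1 LP, 1 test, 2 d | — | the early-mNGS true-positive pathway |
| negative scenario | 1 LP, 0 tests, 2 d | — | a negative result precludes further microbiological workup |
| replication_mode | off (on for table replication) | flag | carries observed means at printed 1-decimal precision instead of full precision, so arithmetic done from a published table is reproducible cell by cell |

All three probability parameters are config-overridable
(`ModelConfig` / YAML); every run logs its resolved configuration.

## Rounding conventions

Expected concordant patients are `floor(predictive_value * n)` and every
savings column is `floor(n_concordant * (mean − scenario))` clamped at 0.
Floor (rather than half-up) at both stages is the only convention that
reproduces the published days-saved cells (145.2→145, 61.8→61, 11.2→11,
9.2→9) and LP cells (2.2→2, 0.8→0, 2.7→2) from printed means; half-up
would break the RNA-virus LP cell (0.8→1≠0). Floored products are
computed as `floor(x + 1e-9)` so a product that is mathematically integral
cannot land an ulp below it in binary floating point. Display rounding of
means is half-up to 1 decimal and happens only at rendering.

## Known replication discordances

These cells of the published impact tables cannot be recovered from the
printed aggregates under any simple rounding, and the package does not
force agreement (the model computes its own value and the discrepancy is
logged where relevant):

- Tests avoided, DNA virus: computed 103 (22 × 4.7) vs published 88.
- Tests avoided, RNA virus: computed 3 (4 × 0.8) vs published 4.
- Tests avoided, bacteria: computed 33 (15 × 2.2) vs published 30.
- Tests avoided, parasite: computed 8 vs published 9 (from printed or
  unrounded means alike). The fungus cell (29) matches only when the
  unrounded mean 41/7 is used.
- Autoimmune concordant count: `floor(0.984 × 29) = 28` vs published
  "∼27". Replication mode accepts an explicit `autoimmune_n_concordant`
  so table replication never silently fabricates agreement; the override
  is logged.
- The parasite row's back-solved LR+ (≈93.4) sits apart from the other
  categories (82.9–89.0), suggesting a rounding or denominator difference
  in the original arithmetic; the package records, and does not resolve,
  the discrepancy.

These differences most likely reflect patient-level arithmetic in the
original analysis that printed aggregates cannot reconstruct.

## Uncertainty analysis

The PSA draws Se and Sp from Beta distributions (defaults Beta(86, 14)
and Beta(99, 1), matching the default point values in mean) and each
category prevalence from Beta(k+1, n−k+1) — the posterior under a uniform
prior, proper even for small or zero k (the parasite category has k = 3).
Each joint draw runs the full Bayes + counterfactual pipeline; intervals
are 2.5/50/97.5 percentiles. Percentile rather than normal-approximation
intervals because the savings are floored integers and strongly
non-normal; flooring is applied per draw, not to the summaries, so every
draw remains an interpretable table row. Any parameter can be pinned to a
point mass, which collapses the PSA exactly onto the deterministic
pipeline. The tornado sweep perturbs one parameter at a time over a
(low, high) range, holding the rest at base, and ranks parameters by the
absolute width of their effect on a chosen savings column; prevalence
sweeps rediscretize k to the nearest integer count, so very narrow
prevalence ranges can quantize to zero effect.

## Synthetic cohort generator

The generator emulates the study conditions: 54 included
infection-confirmed patients (23 DNA virus, 5 RNA virus, 16 bacteria, 7
fungus, 3 parasite), 29 autoimmune patients, and excluded strata for
48-hour diagnoses and incomplete records. Per included patient: LPs are
1 + Poisson(mean−1) (every included workup had at least one CSF sample,
so support starts at 1), tests are Poisson (zero is legal), days are
Gamma, shape 4 by default, left-truncated at 2.01 days so no included
record violates the 48-hour exclusion rule. The underlying Gamma mean is
recalibrated (Brent root-finding on the truncated-mean identity) so the
truncated mean equals the configured target; without this the generator
would overshoot low day-means, and large-sample parameter recovery would
fail. Category means default to the published 1-decimal aggregates. The
autoimmune arm's mean days to infection rule-out is never printed in the
source tables; 13.0 days is the value implied by its aggregate savings
(297 saved over ∼27 patients + the 2-day scenario) and is used as the
default, flagged here as inference rather than a printed value.

What the generator does not emulate: correlation between LPs, tests and
days within a patient (all independent), pathogen identities within a
category, over/under-dispersion of the count variables (only means are
published; dispersion knobs are documented as arbitrary), and the true
composition of the excluded strata (the published flow diagrams are not
machine-readable, so `excluded_fraction_48h = 0.2` and
`incomplete_fraction = 0.05` are nominal). Passing tests therefore show
that the pipeline is correct under these stated distributions — not that
the distributions match the real cohort.

## Problem sizes in the test suite

The deterministic table replications are desk-scale (milliseconds). The
Monte-Carlo confusion-matrix oracle uses 10^6 simulated subjects per
parameter triple (10^7 for the two frozen spot checks); generator
recovery runs at 100× the study size; PSA tests use 2 000–30 000 draws
and the coverage study 200 replicates × 400 draws. These sizes hold every
Monte-Carlo standard error well below the tolerances asserted while
keeping the whole suite around a few seconds on one CPU.

## Degenerate inputs and numerical choices

- `prevalence = 0` ⇒ PPV 0, NPV 1 by definition, no division performed;
  `prevalence = 1` symmetric. Se = 0 with Sp = 1 makes a positive result
  impossible; PPV is defined as 0 with a warning rather than an
  exception.
- `specificity = 1` makes LR+ infinite; it is reported as `math.inf`
  with a warning. Boundary Se/Sp values must be flagged `ideal=True`
  at construction, keeping accidental 0/1 inputs loud.
- An empty etiology category raises rather than emitting a zero-filled
  summary row.
- A PSA draw that fails aborts the whole analysis with the seed and draw
  index, since silently dropping draws would bias the percentiles.
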