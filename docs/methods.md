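# Methods

## The observation-scale model

The central object is the normalized synaptic efficacy of a single
synapse, expressed as percent of its own baseline. Baseline efficacies are
Gaussian, 𝒩(μ_b, σ²_b); post-depolarization efficacies follow a
two-component Gaussian mixture in which a synapse is *regulated* with
probability *f* = 0.36 and *unregulated* otherwise. The two standard
parameter sets are

| scenario | baseline | regulated | unregulated | test tail |
|---|---|---|---|---|
| DSE (depression) | 100 ± 61 % | 52 ± 16.3 % | 116 ± 43 % | left |
| eSP (potentiation) | 100 ± 58 % | 130 ± 12 % | 89 ± 8 % | right |

all in percent of baseline (mean ± SD). An ensemble experiment is the
arithmetic mean of *N*_total = 12 independent baseline draws paired with
the mean of 12 independent mixture draws; linear summation is justified by
the near-linear EPSC summation of CA1 pyramidal neurons. A field
experiment averages 100 cells on a 180 μm disc. The zone boundaries at 60
and 120 μm give exact area fractions 1/9, 3/9, 5/9; rounded to integer
percentages with the outer zone absorbing the remainder they are 11/33/56,
and the cell counts are fixed deterministically at 11/33/56 of 100.
Proximal cells carry the DSE mixture, intermediate cells the eSP mixture,
distal cells are unmodulated.

Assumptions worth making explicit:

- **Marginals only.** Baseline and post draws are independent within a
  synapse; the model specifies no within-synapse correlation. Pairing
  exists only at the experiment level, where the paired *t*-test operates.
- **Regulated membership** is an independent Bernoulli(0.36) per synapse
  per experiment, not a fixed 4-of-12 split. A fixed-count variant
  (`membership="fixed"`) is available for sensitivity analysis; it reduces
  the between-experiment variance slightly.
- **Unmodulated field cells draw fresh post-window values** from their
  baseline distribution rather than reusing their baseline draws. The
  alternative (treating "no change" as literally frozen values) would make
  unmodulated cells cancel out of the paired difference and predict
  implausibly small sample sizes (≈7 for the DSE-only field scenario,
  against ≈61–63 from both the experiment-calibrated expectation and this
  implementation).
- **Negative efficacy draws are retained.** The Gaussians are used as
  specified; truncation at zero would bias the means and SDs away from
  their stated values.
- **Zone baselines**: the proximal zone uses the depression-experiment
  baseline (σ = 61), the intermediate and distal zones the
  potentiation-experiment baseline (σ = 58), i.e. each zone follows the
  experiment that characterized it. Results are insensitive to this choice
  (the two σ differ by 5%).

## n₀.₀₅ estimation

For each candidate sample size *n* on a grid (default 2…500), `reps`
replicate studies of *n* experiments are simulated (1000 for ensemble
scenarios, 100 for field scenarios) and each is scored with a paired
*t*-test on (post − baseline) with the scenario's tail. The per-replicate
*p*-values are aggregated by their **mean**; n₀.₀₅ is the smallest grid
*n* whose aggregate falls below α = 0.05, reported as `None` when the
grid is exhausted without a crossing. The median is available as a config
switch but the mean is the default (the DSE ensemble scenario lands on
n₀.₀₅ ≈ 53–57 across seeds with it); the median, being smaller than the
mean for the right-skewed p-value distributions that arise under an
effect, would systematically shift all crossings earlier.
Because n₀.₀₅ only depends on the first crossing, the scan can stop there
(`stop_when_significant=True`, used by the acceptance script); the full
curve is computed when the curve itself is wanted.

The replicate machinery is vectorized (replicates × experiments ×
synapses arrays, *t* computed from the closed formula) and is tested
against both `scipy.stats.ttest_rel` and the scalar `run_study` path. A
mixture draw uses one uniform (component membership) and one standard
normal (shared by both components), which is distributionally exact.

Monte Carlo variability of n₀.₀₅ at the default replicate counts is a few
grid steps for the ensemble scenarios (e.g. 53–57 for DSE) and somewhat
larger for field scenarios (100 replicates), e.g. 23–27 for the eSP-only
field scenario.

## Synthetic recordings

The generator emulates the minimal-stimulation protocol: stimuli at
0.33 Hz (`floor(duration × rate)` per window, the first at each window's
start — 59 baseline and 39 post stimuli at the defaults), a 3-min
baseline, a step modulation at the depolarization instant that persists
through the 2-min post window. Per stimulus a synapse releases with
probability Pr (scaled by the modulation's `pr_factor` after ND), success
amplitudes are Gaussian around the potency (scaled by `potency_factor`),
failures are 0 pA, and Gaussian electrode noise is added once per
stimulus — for bulk trains a single shared noise term, since recording
noise lives at the electrode, not at individual synapses. Success
amplitudes are not truncated at zero; the default potency SD (1 pA
against a 9 pA mean) makes negative draws negligible while keeping the
moments exact. Paired-pulse structure is not modeled (one response per
stimulus); no analysis here uses a second pulse.

Parameters the underlying recordings do not pin down are package
defaults chosen once: electrode noise SD 0.5 pA and potency SD 1 pA,
typical of low-noise whole-cell EPSC data with ~9 pA quantal amplitude.

What the generator does **not** emulate: EPSC kinetics (amplitudes are
scalars), stimulus-artifact contamination, slow drifts in access
resistance or release probability, and any within-train correlation.
Passing tests therefore validate the analysis chain and the statistical
model, not robustness to those real-world nuisances.

## Trace analysis and the 2-SD rule

Pr is the success fraction, potency the mean success amplitude, efficacy
their product (zero-success windows report potency 0 so the product
identity holds; such windows are degenerate and flagged by their Pr = 0).
Success detection thresholds amplitudes at `k × noise_sd` (default
k = 3); ground-truth flags are also available from the generator so the
analysis can be run truth-conditioned.

The classifier compares the pooled post-window efficacy against the mean
± 2 SD of the **three 1-min baseline-bin efficacies**. The sampling unit
of that SD is genuinely ambiguous (bin-level vs trial-bootstrap); the
bin-level choice was made because the time course is conventionally
presented in 1-min bins, and it is stated here rather than hidden.

A consequence, derivable in closed form, is that the rule's sensitivity
at the 59-stimulus protocol depends strongly on Pr: with ~20 stimuli per
bin the binomial SD of a bin's efficacy is potency × √(Pr(1−Pr)/20), and
the 2-SD threshold built from only three bins (2 degrees of freedom) is
itself noisy — its 90th percentile is ≈1.5× the true bin SD. Reliable
(≥90%) recovery of a 52% depression or 130% potentiation therefore
requires (1−Pr)/Pr ≲ 0.45, i.e. a high-Pr synapse. The recovery tests use
Pr = 0.9 with potency 9 pA (potency SD 0.5, noise SD 0.2); at the lower
Pr of typical minimal-stimulation data (0.3–0.5) single recordings of
this length are too variable for the rule to be reliable — which is the
variability the Monte Carlo model exists to quantify. In those tests the
potentiation is injected through the potency factor because scaling
Pr = 0.9 by 1.3 would exceed 1; the classifier sees only efficacy, so the
route of the injected change is immaterial to what is being tested.

## Recruitment arithmetic

The number of synapses active per bulk stimulus is binomial with mean
N̄_active = Pr × N_total. N̄_active is estimated as ensemble potency /
single-synapse potency, rounded to the nearest integer (47.9/9.0 → 5);
N_total = N̄_active / Pr is **truncated** toward zero (5/0.4 = 12.5 → 12)
— truncation, not rounding, reproduces the pool size used everywhere else
in the model, and the unrounded quotient is returned alongside for
transparency. Pr defaults to 0.4, the pooled minimal-stimulation value.

## Statistical primitives

Paired *t*-tests are evaluated on differences with n−1 degrees of
freedom; 'left' tests for depression, 'right' for potentiation. The
sample-size formula is the one-sample normal approximation
n = ⌈((z₁₋α + z₁₋β) σ/δ)²⌉ (z₁₋α/₂ two-sided); the noncentral-*t*
refinement is deliberately out of scope. The formula's calibration is
checked by simulation (empirical power within 0.05 of nominal at the
returned n).

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.Generator`; entry points
  accept an integer seed, a `SeedSequence` or a Generator. Generators that
  need independent substreams (per synapse, per cell, electrode noise)
  spawn `SeedSequence` children, so a bulk train with one synapse is
  bit-identical to the corresponding single-synapse train under the same
  seed, and full scenario runs are bit-reproducible.
- Ties at the classifier boundary (post exactly at mean ± 2 SD) are
  `unchanged` — the inequalities are strict.
- The pool truncation adds a 1e-9 epsilon before flooring so that exact
  quotients (4.8/0.4) are not pushed down by floating representation.
- Grid validation requires strictly increasing n ≥ 2 (a paired *t*-test
  needs two pairs).

## Known limitations

- At 100 replicates the field n₀.₀₅ first-crossing estimator inherits a
  few grid steps of jitter (e.g. ~23–27 for the eSP-only scenario). The
  model's internal consistency can be checked by linearity: the expected
  field effect is the zone-weighted mixture means, and all three field
  predictions agree with that arithmetic combined with the
  variance-of-means calculation.
- The model is purely statistical: no eCB diffusion, astrocyte calcium
  dynamics or receptor-level mechanism is represented, and the
  experimental pA-scale values cannot be regenerated from it — only the
  normalized-efficacy behavior.
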