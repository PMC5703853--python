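# synscale

Synapse-specific short-term plasticity — such as endocannabinoid-mediated
depolarization-induced suppression of excitation (DSE) and
astrocyte-mediated lateral potentiation (eSP) at hippocampal CA3–CA1
synapses — affects only a subset (~36%) of synapses. A change that is
obvious when a single synapse is monitored by minimal stimulation can be
statistically invisible when many synapses are recorded together, whether
as a whole-cell synapse ensemble (bulk stimulation) or as a field
population (fEPSP). `synscale` is a simulation and analysis toolkit for
quantifying exactly when that concealment happens and how many experiments
(n₀.₀₅) would be needed to overcome it.

It is aimed at synaptic electrophysiologists and modelers planning or
interpreting minimal-stimulation, bulk-stimulation and field experiments.

## Model

Each synapse *i* has a normalized synaptic efficacy (percent of baseline)
with baseline value

&nbsp;&nbsp;&nbsp;&nbsp;*X*ᵢ ~ 𝒩(μ_baseline, σ²_baseline)

and post-depolarization value drawn from a bimodal regulated/unregulated
mixture

&nbsp;&nbsp;&nbsp;&nbsp;*Y*ᵢ ~ *f* · 𝒩(μ_reg, σ²_reg) + (1 − *f*) · 𝒩(μ_unreg, σ²_unreg),&nbsp;&nbsp; *f* = 0.36.

A simulated whole-cell **ensemble** experiment averages *N*_total = 12
independent *X* draws and 12 independent *Y* draws (CA1 pyramidal neurons
sum EPSCs linearly); a **field** experiment averages 100 such cells laid
out on a 180 μm disc — 11 proximal cells (≤60 μm) carrying the DSE
mixture, 33 intermediate cells (60–120 μm) the eSP mixture, 56 distal
cells unmodulated. A study of *n* experiments is scored with a paired
*t*-test (left-tailed for DSE, right-tailed for eSP, two-tailed for
field); for each candidate *n*, replicate studies (1000 ensemble / 100
field) give a mean *p*-value, and **n₀.₀₅** is the smallest *n* at which
that mean drops below 0.05.

*N*_total itself comes from a binomial recruitment argument: the mean
number of synapses active per bulk stimulus is N̄_active = ensemble
potency / single-synapse potency = 47.9 / 9.0 ≈ 5, and
*N*_total = N̄_active / *P*r = 5 / 0.4 → 12.

The package also generates synthetic stimulus-locked EPSC trains (0.33 Hz,
3-min baseline, 2-min post window) with known ground truth, and analyzes
them with the standard quantal parameters — *P*r (successes / stimuli),
potency (mean success amplitude), efficacy = *P*r × potency — plus a 2-SD
classifier that labels a synapse depressed/potentiated/unchanged by
comparing the post-window efficacy against the spread of the three 1-min
baseline bins.

## Worked example

```sh
$ synscale recruit
n_active_bar = 5
exact quotient n_active_bar / pr = 12.5
n_total = 12
```

Five synapses are active per bulk stimulus on average; with Pr = 0.4 the
total available pool is 12 synapses per cell — the ensemble size used in
all simulations.

```sh
$ synscale simulate --scenario dse_ensemble --seed 0 --out simout
{
  "scenario": "dse_ensemble",
  "n005": 54,
  ...
}
```

With the DSE parameter set (baseline 100 ± 61%, regulated 52 ± 16.3%,
unregulated 116 ± 43%, 36% regulated), roughly 54 whole-cell ensemble
experiments would be needed before the mean left-tailed paired-*t*
*p*-value over 1000 replicate studies drops below 0.05 — an order of
magnitude more than a typical experimental *n* of ~11, which is why the
depression is concealed in practice. `simout/` receives the *p*-vs-*n*
curve as CSV and a JSON summary recording every parameter and the seed.

Generating and analyzing a synthetic single-synapse recording:

```sh
$ synscale generate --pr 0.9 --potency 9 --noise-sd 0.2 --mod dse --seed 4 --out train.csv
wrote 98 stimuli to train.csv
$ synscale analyze train.csv --noise-sd 0.2
window,pr,potency_pA,efficacy_pA,label
baseline,0.8644,9.0279,7.8038,depressed
post,0.5641,9.2047,5.1924,depressed
```

The injected DSE (Pr scaled by 0.52 after the depolarization) is recovered
by the 2-SD rule: efficacy falls from 7.8 pA to 5.2 pA, more than two
baseline-bin standard deviations below baseline.

The same functionality is available as a library
(`synscale.generate`, `synscale.traces`, `synscale.montecarlo`,
`synscale.recruitment`, `synscale.stats`, `synscale.scenarios`).

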