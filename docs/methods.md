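# Methods

## Model

`ednaocc` implements a two-stage (multi-scale) site-occupancy model for
replicated eDNA qPCR data with false positives and false negatives at both
stages. Latent variables: site occupancy z_i ~ Bernoulli(ψ_i) and
per-sample eDNA capture a_ij ~ Bernoulli(θ₁₁ if z_i = 1 else θ₁₀).
Observed: y_ij ~ Binomial(K_ij, p₁₁ if a_ij = 1 else p₁₀), the number of
amplifying replicates. Complement rates (θ₀₁ = 1−θ₁₁ etc.) are always
derived, never stored. Heterogeneous K across samples is supported (real
datasets drop failed wells) even though standard protocols use a constant
K.

Two model variants share one code path:

- **full** — all five probabilities free;
- **no_false_positives** — θ₁₀ = p₁₀ = 0. Any amplification then implies
  eDNA capture and any capture implies occupancy, which the sampler
  enforces exactly (forced latent states rather than soft conditionals).

Probabilities may be constant or logistic functions of site covariates;
with every covariate at zero the intercepts define the "baseline site" on
which all probability-scale summaries are reported.

## Priors and identifiability

With a single sample per site (M = 1) and constant probabilities, the
likelihood depends on (ψ, θ₁₁, θ₁₀) only through the mixture weight
ψθ₁₁ + (1−ψ)θ₁₀, so ψ is not separately identified. Three devices help:
replication (M ≥ 2), confirmed presences (direct observations pin z = 1),
and informative priors. Defaults:

| parameter | prior | rationale |
|---|---|---|
| ψ, θ₁₁, p₁₁ | Beta(1, 1) | no strong prior knowledge assumed |
| θ₁₀, p₁₀ | Beta(1, 19) (mean 0.05) | false positive rates believed small |
| covariate slopes | Normal(0, 1.5²) | weakly informative on the logit scale |
| intercepts (ψ, θ₁₁, p₁₁) | Normal(0, 1.5²) | matches the near-flat Beta above |
| intercepts (θ₁₀, p₁₀) | Normal(logit 0.05, 1²) | carries the informative FP prior into the covariate parameterisation |

All of these are configurable through `PriorSpec`. Fitting an M = 1
dataset without covariates or confirmed presences emits an
`IdentifiabilityWarning` and proceeds on the strength of the priors alone.

The identifiable orientation θ₁₁ > θ₁₀ and p₁₁ > p₁₀ (the "true" signal is
the stronger one) is enforced: by joint rejection sampling in the
conjugate updates, and by rejecting Metropolis proposals whose intercepts
violate the ordering. `ModelParams` construction permits equality so that
degenerate no-information limits remain expressible for analysis.

## Sampler

MCMC with latent-state data augmentation, alternating

1. a | z, θ, p, y — independent Bernoulli full conditionals (vectorised);
2. z | a, ψ, θ — independent Bernoulli full conditionals (y ⊥ z given a);
3. parameters:
   - covariate-free: conjugate Beta draws from sufficient counts;
   - covariate designs: per-parameter blocked random-walk Metropolis on
     the coefficient vector, with a Robbins–Monro step-size adaptation
     toward 30% acceptance during burn-in only (preserving detailed
     balance afterwards). Pólya-Gamma augmentation would be the natural
     alternative but is not available in the supported environment; the
     Metropolis path is validated against an importance-sampling oracle.

Per stored draw, per-site occupancy probabilities are Rao-Blackwellised
(P(z_i = 1 | y_i, current parameters), marginalising a) rather than saving
binary z draws, giving smooth site posteriors even from short chains.
Confirmed-presence sites report exactly 1.

Defaults mirror the short runs used in the simulation study this package
reproduces — 1 chain, 1000 burn-in, 2000 iterations, thinning 10 (200
stored draws) — and are deliberately small; for final inference run
several chains and more iterations, and check the reported effective
sample size and split-R̂ (computed via ArviZ). All randomness flows from a
single seed; fits are bit-reproducible given (data, settings, seed).

## Synthetic data

`simulate_dataset` draws from exactly the generative process above.
Defaults encode the simulation study's stated world: ψ = 0.1, θ₁₁ = 0.85,
θ₁₀ = 0.01, p₁₁ = 0.9, p₁₀ = 0.01, and per site one continuous covariate
(standard normal — "centred at zero" is stated, unit variance matches the
downstream standardise-to-SD-1 convention) and one binary covariate with
occurrence probability 0.5. When parameters are given on the probability
scale the covariates carry **zero effects** — they exist to mirror the
study design, where covariates were included purely as an identifiability
device; non-zero effects require `CovariateModelParams`. No confirmed
presences are generated by default (the study does not state that any
were simulated).

What a green calibration test establishes: the generator's event
frequencies match the analytic model (law-of-large-numbers checks at
S = 10⁵ within 3 Monte-Carlo SEs). What it does not: real eDNA surveys
have spatial correlation, inhibition/degradation artefacts, operator
effects and continuous DNA-concentration dynamics, none of which are
simulated.

Grid seeds derive from `SeedSequence([base_seed, S, M, K, repeat])`, so
any cell/repeat can be regenerated independently, in any order, on any
worker, with identical results.

## Design study

`run_design_grid` sweeps (S, M, K), runs `repeats` simulate-and-fit cycles
per cell, and reports per parameter the mean bias (posterior mean − truth;
positive = over-estimation) and mean 95% credible-interval width.
Completed repeats are checkpointed to a JSON-lines ledger so the full
4×3×6×10 grid can run incrementally; failed repeats are recorded and
skipped rather than aborting the grid.

Covariates are fitted exactly where they are needed for identifiability
(M = 1 or K = 1 cells, `fit_covariates="auto"`); elsewhere the exact
conjugate sampler is used. Rationale: with the weakly-informative
coefficient priors above, a 15-coefficient logistic fit at S = 20 is
prior-dominated and its interval widths measure the prior, not the
design. Forcing either mode everywhere remains available.

## Derived quantities

- `conditional_absence_probability(params, x, K)` — P(site unoccupied |
  x of K replicates amplified) for a single-sample baseline site, the
  Bayes ratio of the two likelihood addends. Non-increasing in x under
  the identifiable orientation; equals 1−ψ for every x when both stages
  are uninformative (θ₁₁ = θ₁₀, p₁₁ = p₁₀). The posterior-averaged
  version (`posterior_absence_curve`, the default reading of a
  "posterior conditional probability") averages the plug-in ratio over
  posterior draws; both modes are exposed. A multi-sample generalisation
  is available via `site_occupancy_given_data` (an extension beyond the
  single-sample definition).
- `naive_occupancy(dataset, threshold)` — fraction of sites with at least
  one sample reaching the threshold; the error-blind summary the model is
  meant to replace.
- `replicate_count_spectrum` — frequency table of y; at realistic
  parameters it is bimodal (mass at y = 0/1 and near y = K), the
  empirical signature that motivates modelling false positives.

## Numerical choices

- All dataset-level likelihoods accumulate in log space; per-site values
  may be returned on the probability scale.
- Degenerate probabilities (0 or 1) are handled explicitly in the latent
  conditionals (0·log 0 → 0 conventions), so constrained-model forcing is
  exact rather than relying on floating-point -inf arithmetic.
- 95% intervals are the 2.5%/97.5% empirical quantiles of stored draws.
- Beta orientation rejection retries up to 1000 times, then keeps the
  previous state (never observed in practice with the default priors).
- Covariate standardisation uses the sample SD (ddof = 1), recorded for
  back-transformation; binary (values ⊆ {0,1}) columns are exempt.

## Known limitations

- Single-sample (M = 1) designs with decoy covariates are only weakly
  identified: the ψ posterior spreads along the mixture-weight ridge and
  is strongly prior-sensitive. Credible-interval widths for ψ at M = 1,
  and anything derived from them, should be interpreted as prior+data
  statements, not data statements.
- The no-false-positive variant applied to contaminated single-sample
  data inflates occupancy (that is the point of the comparison), but at
  M = 1 the full model's ψ is itself ridge-biased upward under flat θ₁₁
  priors; model comparisons are most meaningful at M ≥ 2.
- Short default chains are faithful to the reproduced study but can yield
  effective sample sizes in the tens for weakly identified parameters;
  diagnostics are reported so this is visible.
- The model consumes binary replicate outcomes only; Cq values, standard
  curves, and inhibition screening are out of scope (an `inconclusive`
  flag column is honoured on ingestion).
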