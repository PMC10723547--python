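# Methods

This note documents the models implemented in `sharederr`, the choices made
where the design was genuinely open, the numerical machinery, and the limits of
what the simulation study can show.

## Dose-error model

Individuals are permanently assigned to one of five dose groups with central
dose estimates `D_cent = (0.01, 0.1, 0.5, 1.5, 2) Gy` and person counts
`(2591, 334, 438, 102, 6)` (3471 persons in total), a grouped design modelled
on a leukaemia cohort's person-year distribution.  Collapsing always uses the
original group membership; realized doses never trigger regrouping.

True and surrogate doses are multiplicative lognormal perturbations of the
central dose.  Within one realization `r` every individual shares one standard
normal draw (`ε_r` for Berkson, `μ` for classical error) and receives one
individual draw (`δ_ir`, `κ_i`).  The four log-scale standard deviations
("GSDs": 0.2 means σ = 0.2) are the scenario knobs; the factor
`exp(-(σ²_sh+σ²_un)/2)` makes every dose's theoretical mean equal its central
estimate.  Setting the Berkson pair to zero leaves a pure classical model and
vice versa.  Two distinct same-group individuals' true doses have correlation

```
ρ = (e^{σ²_sh} − 1) / (e^{σ²_sh+σ²_un} − 1)
```

across realizations (0.49 at 20%/20%, 0.84 at unshared 20%/shared 50%), which
`shared_dose_correlation` estimates by pooling disjoint within-group pairs,
scaled by the group mean dose so that pairs from different groups are
identically distributed.

Each replication draws `n_realizations` true-dose columns (default 1000) and a
*single* surrogate vector — the unadjusted method is defined to use one sampled
dose per individual.  Randomness is split into six named, independently seeded
streams per replication (Berkson shared/unshared, classical shared/unshared,
outcome, MCMC), keyed `SeedSequence([master_seed, replication, stream])`.
Consequently varying the classical-error settings leaves the true doses, the
cases, and every dose-error-adjusted fit bit-identical — the repeated-row
structure of the study tables — and any scenario or method can be re-run in
isolation.  Components with σ = 0 skip their stream entirely; a zero-Berkson
ensemble is a lazy broadcast of the central doses.

## Outcome model

Cases follow the linear-quadratic excess-relative-risk model: individual case
probability `exp(κ)(1 + αD + βD²)` with κ normalising the probabilities to sum
to one, truth α = 0.25/Gy, β = 2/Gy².  A fixed total of N = 250 cases (the
study's value) is allocated by one multinomial draw across the 3471
individuals.  Two readings of the case-sampling law were considered; the
multinomial was retained because it fixes the total at exactly N and because
per-individual Bernoulli sampling measurably over-covers β (the six-person
2 Gy group becomes under-dispersed relative to the Poisson likelihood, 98.7%
versus the expected ≈95% at 300 replications).

Cases are generated from realization 0 of the true-dose ensemble; all
realizations, including 0, form the dosimetry ensemble handed to MCML and the
Bayesian fitter.  Where the study conventions leave the replication structure
open, this package fixes 1000 dose realizations per replication and 500
replications, with one case vector per replication.

## Grouped Poisson linear relative-risk fitting

The grouped likelihood is `c_k ~ Poisson(n_k e^κ (1 + αD_k + βD_k²))`.  The
relative-risk factor must stay positive; violating parameters receive
log-likelihood −∞ (a rejected region, not an exception).  For fixed (α, β) the
baseline maximiser is closed-form, `e^κ = Σc_k / Σ n_k(1+αD_k+βD_k²)`, so
fitting is a 2-D Nelder-Mead search over (α, β) with κ profiled out, restarted
from a fixed set of perturbed starts (default start α = 0.1, β = 1) and
polished once; infeasible points get a large barrier value that grows with the
violation so the simplex can recover.  The fit was validated against dense
grid-search maxima.

Profile-likelihood 95% intervals solve `2(ℓ_max − ℓ_profile(b)) = 3.841` by
bracket doubling (up to 60 doublings, initial step max(0.25·|MLE|, 0.25))
followed by bisection to 1e-4 on the deviance scale; a side that never crosses
the threshold is reported as an infinite sentinel and counts as covering.
Inner profile optimisations are warm-started from the previous solution.
Groups with zero cases need no continuity correction — the Poisson likelihood
handles them naturally.

## MCML

Monte Carlo maximum likelihood averages the grouped likelihood over the
ensemble of per-realization group-mean dose vectors *on the natural scale*
(log-sum-exp stabilised) and then maximises — averaging likelihoods, not
log-likelihoods, is the defining choice.  Under the average κ has no
closed-form profile, so the search is 3-D Nelder-Mead over (κ, α, β);
realizations whose relative-risk factor goes non-positive contribute
likelihood zero.  Profile CIs are computed on the averaged-likelihood surface
with the same bracketing machinery, warm-starting the inner 2-D optimisations.
With zero Berkson error the ensemble degenerates and MCML reproduces the
regression-calibration fit.

## Bayesian 2DMC with BMA

The scenario-mixture posterior is

```
log p(α, β, κ, λ | data) = log Σ_j p_j(λ) L_j(α, β, κ) + log priors
```

with `p_j` the softmax-with-reference-category weights of Eq-style
`p_j = e^{λ_j}/(1+Σ e^{λ_k})`, `L_j` the grouped Poisson likelihood under
scenario `j`'s group-mean doses, and independent N(0, 1000²) priors on α, β, κ
and every λ.  The mixture sits at the whole-dataset level — exactly one
scenario is assumed correct for everyone.  κ is a free parameter here (it is
only normalised away in the frequentist fits).

Sampling follows the published protocol exactly: symmetric normal random-walk
proposals with SD 0.2 (κ), 1 (α, β) and 2 (λ); λ proposed in blocks of 10 with
one joint accept/reject per block (the last block may be short); two chains,
1000 burn-in sweeps discarded and 1000 kept.  Chain 1 starts at
(α, β) = (0.1, 1) with a data-implied κ and λ = 0; chain 2 adds +1 to each main
parameter.  Per-scenario likelihood pieces `A_j = Σ_k c_k log(n_k q_jk)` and
`S_j = Σ_k n_k q_jk` are cached so κ and λ updates cost O(R).  Convergence is
monitored with the classic Brooks-Gelman-Rubin potential-scale-reduction
factor per scalar parameter (no rank normalisation); posterior summaries are
pooled-chain means and equal-tailed 2.5/97.5 percentile intervals, which also
define Bayesian "coverage".

### A documented divergence

With large shared Berkson error this implementation does **not** reproduce the
previously reported pathology of the 2DMC-with-BMA method (linear coefficient
inflated roughly tenfold with near-zero credible-interval coverage).  The
reason appears to be structural rather than a defect of this sampler:

* with five dose groups and three free parameters, every scenario's maximised
  likelihood is a near-tie (spreads under 0.1 log-units among the best
  scenarios), so no goodness-of-fit reweighting of scenarios can be decisive
  on grouped data;
* the exact posterior of the mixture model above is analytically the
  equal-weight scenario average on the (α, β, κ) margin, tilted only by
  per-scenario Occam volumes, which *favour* flat-likelihood (large-β)
  scenarios — the opposite direction;
* this sampler does reproduce the published zero-Berkson Bayesian row, where
  the scenario mixture is degenerate, so the core machinery agrees where the
  model is unambiguous.

What this package reports for the pathological scenarios is therefore what the
stated model and protocol actually produce: wide, roughly nominal-coverage
posteriors whose chains lock onto essentially random scenarios (visible as
elevated BGR values for β and acceptance rates above the published ≈30%).
Alternative likelihood placements (geometric mixtures, per-group dose mixing,
individual-level likelihoods with the generating realization included or
excluded) were implemented experimentally and none yields the reported
behaviour either; the comparison tables for this method should be read with
that caveat.

## Evaluation

Coverage is the percentage of closed intervals containing the truth (infinite
sides count as covering; failed fits are excluded from the denominator and
reported in a separate column, never silently dropped).  Predicted-RR bias is
`100·[(1+ᾱD+β̄D²)/(1+αD+βD²) − 1]` at D = 0.1 and 1 Gy using the mean
coefficients.  Reports are written as three wide tables (coverage,
coefficients, RR bias — one row per scenario, paired α/β columns per method),
a long-format CSV, and a JSON manifest of seeds and settings; everything is
reproducible bit-for-bit from the master seed.  An `erc` plug-in slot exists
for an extended-regression-calibration likelihood adjustment; none ships.

## Problem sizes

Default study conditions are 500 replications × 1000 dose realizations with
250 cases.  The packaged benchmark script uses those defaults for the
frequentist quantities, 100 replications for the MCML coverage check, and
50 replications with 200-realization ensembles for the Bayesian method, whose
sampler dominates the run time (~2.5 s per replication); the `--quick` CLI
profile (50 × 100) is intended for pipeline smoke tests.  At 500 replications
a coverage estimate near 95% carries a binomial standard error of about one
percentage point; coefficient means carry Monte-Carlo standard errors of
0.03-0.05 at the default scale, several-fold larger in shared-error scenarios.

## Known limitations

* The generator emulates grouped cohorts with known, fixed group structure and
  multiplicative lognormal errors; it does not model additive Berkson-classical
  mixtures, individual dosimetry reconstruction, person-time, covariates or
  competing risks, so passing tests say nothing about those settings.
* The mean maximum-likelihood estimate of α is slightly above the true 0.25
  under the exact generative model (≈ +0.07 at zero error, a finite-sample
  effect of the strongly curved α-β likelihood ridge with only ~20 expected
  cases in the α-identifying group); published reference means sit slightly
  below 0.25, a difference that survived extensive cross-checking of the
  fitter against grid-search oracles and several case-sampling laws.
* The 2DMC-with-BMA comparison is subject to the divergence documented above.
* Wald and bootstrap intervals, overdispersion, and the SAMC sampler variant
  are out of scope.
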