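# sharederr

A simulation laboratory for studying how **shared and unshared dose-measurement
error** distorts radiation dose-response estimation in grouped cohort data, and
how well four correction methods repair it.

## The scientific problem

Epidemiological dose-response analyses — for example leukaemia risk as a
function of bone-marrow dose — must contend with dosimetry error.  Two error
structures behave very differently:

* **Berkson error**: the true dose scatters around the assigned (nominal) dose;
* **classical error**: the measured dose scatters around the true dose.

Either component may be **shared** across the whole cohort (a systematic
dosimetry-system bias, one draw per dose realization) or **unshared**
(individual-specific).  Shared errors are endemic in occupational and fallout
dosimetry, and they interact badly with curvature in the dose response.

`sharederr` builds a synthetic 5-group cohort (3471 persons, central doses
0.01-2 Gy), draws true doses `D_true` and surrogate doses `D_surr` from a
multiplicative lognormal composite error model

```
D_true,i,r = D_cent,k(i) · exp(-(σ²_sh,B + σ²_un,B)/2) · exp(σ_sh,B ε_r + σ_un,B δ_ir)
D_surr,i   = D_cent,k(i) · exp(-(σ²_sh,C + σ²_un,C)/2) · exp(σ_sh,C μ + σ_un,C κ_i)
```

(mean-preserving by construction; GSDs of 0.2 or 0.5 ≙ "20%"/"50%"), simulates
N = 250 cancer cases with individual case probabilities proportional to the
linear-quadratic excess relative risk `1 + αD + βD²` (α = 0.25/Gy, β = 2/Gy²),
and fits the grouped Poisson linear relative-risk model

```
c_k ~ Poisson( n_k · e^κ · (1 + α D_k + β D_k²) )
```

by four methods:

| method | dose used |
|---|---|
| unadjusted | group means of one surrogate draw |
| regression calibration | group means of true doses, averaged over the realization ensemble |
| MCML | the full ensemble of per-realization group means; the likelihood is averaged on the natural scale, then maximised |
| 2DMC with BMA | the same ensemble inside a Bayesian scenario mixture `Σ_j p_j L_j` with softmax weights `p_j(λ)`, sampled by blocked Metropolis-Hastings |

Frequentist intervals are 95% profile-likelihood CIs (deviance threshold
χ²₁(0.95) = 3.841); the Bayesian method reports equal-tailed 95% credible
intervals.  Replicated scenarios yield coverage probabilities, mean
coefficients and the percentage bias of the predicted relative risk
`100·[(1+α̂D+β̂D²)/(1+αD+βD²) − 1]` at 0.1 and 1 Gy.

## Worked example

```python
import sharederr as se

spec = se.ScenarioSpec(
    error=se.ErrorModel(sigma_share_berkson=0.2, sigma_unshare_berkson=0.2,
                        sigma_share_class=0.2, sigma_unshare_class=0.2),
    n_replications=50, n_realizations=200,
    methods=("unadjusted", "regcal", "mcml"), master_seed=7,
)
report = se.run_scenario(spec)
print(report.to_frame()[["method", "coverage_alpha", "coverage_beta",
                         "mean_alpha", "mean_beta"]].to_string(index=False))
```

prints (about 1 minute on one core):

```
    method  coverage_alpha  coverage_beta  mean_alpha  mean_beta
unadjusted            94.0           80.0    0.075873   2.677536
    regcal            92.0           86.0    0.093318   2.377572
      mcml            94.0           96.0    0.176953   2.352309
```

Reading: at moderate (20%) Berkson error all methods keep near-nominal coverage
for the linear coefficient α, but the unadjusted and regression-calibration
fits under-cover the quadratic coefficient β (80-86% here), while MCML's
averaged likelihood over-covers it — its profile intervals are conservative.
The coefficient means carry a Monte-Carlo error of roughly ±0.1 (α) and
±0.15 (β) at 50 replications; shared-error scenarios are dominated by the
common scale draw, so α̂ scatters widely between replications.

A command-line interface wraps the same machinery:

```bash
sharederr run --config steering.yaml --out reports/      # full factorial study
sharederr run --quick --methods regcal --seed 1 --out r/ # 50 reps x 100 realizations
sharederr fit grouped.tsv                                # one grouped-data fit
sharederr simulate --berkson-shared 0.5 --out doses.tsv  # export a dose ensemble
```

The steering file format and all defaults are documented in
`src/sharederr/config.py`; written reports comprise three wide tables
(coverage, coefficients, RR bias), a long-format CSV and a JSON run manifest,
all reproducible bit-for-bit from the master seed.

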