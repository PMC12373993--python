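# allogrowth

Allometric energy-allocation growth modelling for individual body-length
trajectories, built around *Daphnia*-style life-table experiments: repeated
length measurements at birth, at every brood, and at death, plus brood
sizes, under different temperature regimes.

The core model splits total mass into somatic and gonadic parts with
allometric acquisition, cost, and reproduction terms, and reduces — via the
mass–length power law `s = h l^k` — to a single equation for body length,

    dl_t = q (1 − r_t) l_t^λ dt ,

with a scenario-specific growth scalar `q`, a shared length-scale exponent
`λ`, and a scenario-specific, time-varying relative fecundity investment
`r_t = dg/dm ∈ [0, 1)` (zero at birth, saturating with age).  The package

* forward-simulates both the mass system and the length reduction (RK4),
* estimates `(q, λ, r_t, σ)` from uneven-time length records alone by
  profile least squares: a parallel-curve level criterion profiles the
  shared `λ`, and loess-based gradient matching with trapezium weights
  yields each scenario's `f_t = q(1 − r_t)` without ever solving the ODE
  during fitting,
* converts the fitted allocation into a lifetime-fecundity curve
  `N̂(τ) ∝ q ∫ r_u l_u^λ du` scaled to observed neonate counts,
* attaches bootstrap percentile confidence intervals, and
* generates synthetic populations with known ground truth that emulate the
  four-scenario experiment (constant 15/20/25 °C and an unpredictable
  15–25 °C program), so the whole pipeline is testable at desk scale.

The estimator is a scikit-learn style class
(`AllometricGrowthEstimator`: `fit`, `predict`, `get_params`); the
module-level functions `profile_fit` and `bootstrap_ci` wrap it.
See `docs/methods.md` for the model, the estimation details and the
generator's calibration.

## Worked example

```python
import numpy as np
from allogrowth import (generate_default_population, profile_fit,
                        cumulative_reproduction, scale_to_counts,
                        mean_lifetime, neonates_at, alpha_from_lambda)

dataset, truths = generate_default_population(seed=1)   # 628 individuals
fit = profile_fit(dataset)

print(f"lambda_hat = {fit.lambda_hat:.3f}"
      f"  (alpha_hat = {alpha_from_lambda(fit.lambda_hat, 3):.3f} at k=3)")
for scen in fit.scenarios:
    tau = mean_lifetime(dataset, scen)
    grid = np.arange(0.0, max(tau, fit.r_hat[scen].times[-1]) + 0.25, 0.25)
    curve = scale_to_counts(cumulative_reproduction(fit, scen, grid),
                            dataset, scen)
    print(f"{scen:18s} q_hat={fit.q_hat[scen]:.3f}"
          f"  tau_hat={tau:5.1f} d  N_tau={neonates_at(curve, tau):5.1f}")
```

Output:

```
lambda_hat = 0.173  (alpha_hat = 0.724 at k=3)
constant_high      q_hat=0.208  tau_hat= 48.4 d  N_tau=181.9
constant_low       q_hat=0.118  tau_hat= 80.7 d  N_tau=239.3
constant_rearing   q_hat=0.170  tau_hat= 71.1 d  N_tau=232.6
unpredictable      q_hat=0.191  tau_hat= 52.2 d  N_tau=193.4
```

Read: growth is fastest under constant high temperature and slowest under
constant low (`q` ordering low < rearing < unpredictable < high), while
lifespan orders the other way; individuals under the unpredictable program
grow almost as fast as under constant heat but produce fewer lifetime
neonates (N̂ at the mean lifespan) than under the cool or rearing regimes —
the "live fast, die young" pattern.  The exponent `λ ≈ 0.17` corresponds to
a mass-acquisition exponent `α ≈ 0.72 ≈ 2/3` under cubic mass–length
scaling.

## Command line

```sh
allogrowth simulate --scenario all --seed 7 --out pop.csv   # + pop.truth.json
allogrowth fit pop.csv --out fit.json                        # + fit.r_hat.csv
allogrowth bootstrap pop.csv -B 200 --seed 11 --out fit.json
allogrowth fecundity pop.csv --fit fit.json                  # summary table
allogrowth report pop.csv --fit fit.json                     # plots
```

Input CSV schema: `individual_id,scenario,time_days,length_mm,neonates`,
one row per observation event; a `--config` TOML file and a column-mapping
hook adapt foreign deposits (including micrometre lengths).

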