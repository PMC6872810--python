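# joinprod

Joinpoint-augmented surplus-production modelling for fisheries-style
population assessment.

## The problem

Surplus-production (biomass-dynamics) models are a workhorse of stock
assessment: biomass `B_t` grows logistically toward a carrying capacity
`K` at intrinsic rate `r` and is depleted by harvest `C_t`,

    B_t = B_{t-1} + r B_{t-1} (1 - B_{t-1}/K) - C_{t-1},
    C_t = q B_t E_t,

with catchability `q` and harvesting effort `E_t`.  Standard assessments
assume `r` and `q` are constant over the whole series.  When anthropogenic
pressure suddenly shifts the population's dynamics — `(r1, q1)` becomes
`(r2, q2)` at an unknown change year — those assessments can be badly
biased.  This package implements and evaluates a remedy: estimate the
change year from the observable catch-per-unit-effort index
`I_t = C_t / E_t` by **two-breakpoint segmented (joinpoint) regression**,
then feed it into a **Bayesian state-space surplus-production model** that
estimates separate parameters on either side of the change.

It is aimed at quantitative ecologists and stock-assessment scientists who
want to (a) reproduce the simulation study behind this design and (b) run
the same joinpoint + state-space pipeline on their own yearly catch/effort
series.

## What is inside

| module | contents |
| --- | --- |
| `joinprod.simulate` | the generative model: stabilization burn-in, 64 analyzed years, regime change after year 32, Poisson(10,000) effort, lognormal catch noise; parameters drawn from finite design sets |
| `joinprod.segmented` | `SegmentedRegression` (sklearn-style estimator): Muggeo iterative linearization with bootstrap restarting; `estimate_joinpoint` averages the five standard initializations into t1*, t2*, t* and the transition period |
| `joinprod.bayes` | `SurplusProductionModel`: lognormal state-space model on the proportion P_t = B_t/K, fitted by a compiled Metropolis-within-Gibbs sampler under scenario 1 (change ignored), 2 (estimated t*) or 3 (true change year) |
| `joinprod.experiment` | `run_study`: the full rejection-sampling simulation study with per-bin relative-bias tables |
| `joinprod.config` / `joinprod.cli` | YAML config and the `joinprod` command line (`simulate`, `joinpoint`, `fit`, `study`) |

## Worked example

```python
import numpy as np
from joinprod import (
    PopulationParameters, simulate_series, estimate_joinpoint,
    SurplusProductionModel,
)

params = PopulationParameters(r1=0.8, r2=0.3, q1=2.5e-5, q2=2.5e-5,
                              catch_noise_var=1e-4)
series = simulate_series(params, np.random.default_rng(7))

jp = estimate_joinpoint(series, rng=np.random.default_rng(1))
print(f"t1*={jp.t1_star:.2f}  t2*={jp.t2_star:.2f}  "
      f"t*={jp.t_star}  transition={jp.transition:.2f}")

model = SurplusProductionModel(scenario=2, change_year=jp.t_star,
                               random_state=1).fit(series)
print(model.summary_.loc[["r1", "r2", "q1", "q2"]][["mean", "q2.5", "q97.5"]])
```

Output:

```
t1*=30.91  t2*=39.12  t*=31  transition=8.22
           mean      q2.5     q97.5
param
r1       0.8911    0.7115    0.9951
r2       0.3222    0.2896    0.3777
q1     2.37e-05 2.193e-05 2.902e-05
q2    2.734e-05  2.44e-05 3.316e-05
```

The joinpoint stage locates the change year (truth: the regime switches
after year 32) and an ~8-year transition during which the population
slides to its new, lower equilibrium; with that estimated change year the
state-space fit brackets all four generating parameters (true values 0.8,
0.3, 2.5e-5, 2.5e-5) with every 95% interval covering the truth.  Fitting
the same series under scenario 1 instead underestimates r1 by tens of
percent — the motivating failure mode.

Command-line equivalent:

```bash
joinprod simulate --seed 7 --out series.csv
joinprod joinpoint --input series.csv
joinprod fit --input series.csv --scenario 2 --change-year 32 --seed 1
joinprod study --n-sims 1000 --seed 1 --scenarios "" --out-dir study_out
```

## Notes

See `docs/methods.md` for the model, the sampler, all prior and tuning
defaults, and the package's documented deviations and limitations.
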