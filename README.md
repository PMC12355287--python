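# wqskit

Weighted quantile sum (WQS) mixture regression and discrete-time survival
modelling for area-level environmental exposures, built around the setting of
kidney-transplant epidemiology: annual zip-code-level panels of PM₂.₅
constituents (elemental and organic carbon, ammonium, nitrate, sulfate, and
ten trace elements) linked to transplant recipients, with binary outcomes
(delayed graft function, first-year acute rejection) and time-to-event
outcomes (death, death-censored graft failure) over five years of follow-up.

## What it computes

**Exposure linkage.** Each recipient's exposure is the calendar-weighted
moving average of each constituent over the 12 months before transplant: for
a transplant in month *m* of year *y*,

    x = (m/12) · level(y) + ((12−m)/12) · level(y−1)

so a July transplant weights the transplant year 7/12 and the prior year 5/12.

**WQS regression.** Constituent concentrations are scored into deciles
d₁…d_J ∈ {0,…,9}. Stage 1 estimates non-negative weights w on the probability
simplex (wᵢ ≥ 0, Σwᵢ = 1) by maximising the GLM likelihood of the outcome on
the index Σᵢ wᵢdᵢ jointly with unconstrained intercept, index and covariate
coefficients — repeated over B bootstrap resamples of a training split and
averaged. Stage 2 freezes the averaged weights, forms wqs = Σᵢ wᵢdᵢ, and fits

    logit P(Y = 1) = β₀ + β₁·wqs + βz′Z

in a held-out validation split; β₁ is the log odds per simultaneous 1-decile
increase in the whole mixture and is reported as (exp(β₁) − 1) × 100 %.

**Discrete-time survival.** Follow-up is expanded to person-months (a
recipient censored at 24 months contributes 24 rows) and the monthly event
indicator is modelled by pooled logistic regression

    logit P(Yₜ = 1 | at risk at t) = β₀ + β₁·wqs + βz′Z + βt′Splines(t)

with a natural cubic spline baseline in months since transplant. With rare
monthly risks exp(β₁) approximates a Cox hazard ratio (aHR).

Effect-measure modification (age ≥ 55, sex, race group, donor type, cold
ischemia time > 12 h) is tested by adding a wqs×modifier term to the stage-2
model; sensitivity analyses restrict follow-up to the first year and accept
extra copollutant covariates. A synthetic-cohort generator (Gaussian-copula
lognormal constituent panels, transplant-like covariates, outcomes drawn from
the models above with known true weights and effects) makes the whole stack
testable end to end.

## Worked example

```python
import numpy as np
import wqskit as wk

cfg = wk.SimulationConfig(n_recipients=16000, n_zips=1200,
                          beta1_binary=np.log(1.2))   # true +20% odds/decile
cohort = wk.simulate_cohort(cfg, seed=0)
exposures = wk.link_cohort(cohort.panel, cohort.recipients)
covs = cohort.recipients[cohort.truth["covariate_names"]]

model = wk.WQSRegression(n_bootstrap=30, random_state=0)
model.fit(exposures, cohort.recipients["dgf"], covariates=covs)

print(model.weights_.sort_values(ascending=False).head(4).round(3).to_dict())
print(round(model.percent_increase_, 1),
      np.round(model.percent_increase_ci, 1))
```

prints

```
{'Br': 0.514, 'Ca': 0.192, 'Cu': 0.157, 'NO3': 0.046}
20.5 [17.8 23.3]
```

The generator put true weights (0.5, 0.3, 0.2) on the first three
constituents and a +20 % odds increase per decile of the index: the top-3
estimated weights identify them in order, and the stage-2 estimate of the
mixture effect (+20.5 %, 95 % CI 17.8–23.3 %) covers the truth. The same
estimator with `family="pooled-logistic"` and `y` as (event, months) pairs
reports an aHR per decile for survival outcomes.

A command line mirrors the library:

```bash
wqskit simulate --seed 3 --out data/
wqskit link --panel data/panel.csv --cohort data/cohort.csv --out expo.csv
wqskit fit-wqs --exposures expo.csv --cohort data/cohort.csv \
       --outcome dgf --seed 1 --out results/
wqskit run --seed 1 --out results/   # full pipeline with manifest
```

## Layout

- `src/wqskit/exposure.py` — constituent panels, moving-average linkage
- `src/wqskit/quantile.py` — decile scoring (`DecileTransformer`)
- `src/wqskit/wqs.py` — constrained stage-1 optimiser, bootstrap weights,
  stage-2 GLM, `WQSRegression`
- `src/wqskit/survival.py` — person-period expansion, natural splines,
  pooled logistic regression, `PooledLogisticHazard`
- `src/wqskit/interaction.py` — subgroup effects and interaction tests
- `src/wqskit/simulate.py` — synthetic cohorts with ground truth
- `src/wqskit/pipeline.py`, `src/wqskit/cli.py` — orchestration, reports,
  manifests, command line

See `docs/methods.md` for the statistical details and design choices.
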