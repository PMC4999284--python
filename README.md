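# popforce

Population dynamics under exogenous socio-environmental forcing: fit
Ricker-family growth models with economic and climatic covariates to
decadal census series, rank the candidate forcing structures by BIC, and
build the tree-ring chronology that supplies the rainfall proxy.

The package grew out of a concrete question — what drove the sustained
depopulation of the Aymara agro-pastoral society in the semiarid Andes of
Tarapacá between 1820 and 1960: the labour pull of the booming lowland
nitrate economy, a multi-decadal rainfall decline, or their interaction?
Everything here is generic, though: any decade-gridded census with an
economic covariate and a moisture proxy fits the machinery.  It is aimed
at quantitative ecologists, demographers and environmental historians who
want the full loop — data model, estimator, model selection, forward
simulation, and a synthetic-data generator that makes every stage
testable without external data.

## The model family

The state is the log population `X_t = ln N_t` and the response is the
realized per-capita growth rate over one census interval of `d = 10`
years,

```
R_t = ln N_t − ln N_{t−d}
```

Candidates combine the generalized Ricker (discrete logistic) form with
exogenous forcing `Z` in one of two geometries:

```
vertical:  R = R_m − exp(a·X + C) + v·Z        (shifts the R-curve up/down)
lateral:   R = R_m − exp(a·X + C + b·Z)        (shifts the equilibrium)
```

`R_m` is the maximum per-capita growth rate per decade, `a` the
density-dependence (interference) exponent, `C = ln c` the log
competition constant.  A lateral perturbation moves the carrying capacity
`X* = (ln R_m − C − b·Z)/a` without changing the slope of R at
equilibrium (`dR/dX|X* = −a·R_m`); a vertical one changes both.  The
catalogue ships six concrete variants — GDP and a rain index entering
vertically, laterally, or as a GDP/rain ratio — with their published
least-squares estimates, plus pure `ricker` and `exponential` members.

Fits are multi-start nonlinear least squares on R; models are ranked by
`BIC = −2 lnL + p ln n` with concentrated Gaussian likelihood and
evidence weights `∝ exp(−ΔBIC/2)`.  The chronology side implements
negexp/linear/mean detrending, Tukey-biweight averaging, rbar and the
Expressed Population Signal `EPS = n·r̄/(n·r̄ + 1 − r̄)` in sliding
windows, variance stabilization, and z-score calibration against an
instrumental series.

## Worked example

Generate a synthetic study (census driven by the ratio-forced model at
its published parameters, growing GDP, declining rainfall), rebuild the
growth records, fit all six candidates, and simulate the winner from the
first census value:

```python
import popforce as pf

report = pf.run_pipeline(pf.RunConfig(seed=1, n_starts=20))
print(report["best_id"], report["prediction_r"])
```

which prints (selection table abridged):

```
model  loglik      bic  p  delta_bic  weight     r2
    6 22.0403 -30.5404  5     0.0000  0.2768 0.9135
    1 21.9693 -30.3983  5     0.1422  0.2578 0.9126
    2 21.8819 -30.2235  5     0.3169  0.2362 0.9115
    4 22.1761 -28.1039  6     2.4365  0.0819 0.9152
    5 22.1587 -28.0692  6     2.4712  0.0805 0.9150
    3 21.9731 -27.6980  6     2.8424  0.0668 0.9127

best_id = "6",  prediction_r = 0.978
```

Reading this: the generating ratio model (id 6) attains minimum BIC and
the largest evidence weight on this replicate, the six fits explain
91–92% of the variance in R, and the winner's deterministic trajectory —
seeded only by the first census value — correlates with the simulated
census at r = 0.98 on the log scale.  Because 14 increments carry limited
information, single-covariate rivals stay within a few ΔBIC units; the
recovery experiment (`popforce recover`) quantifies exactly how often the
truth wins across 200 replicates.

The same stages are available as subcommands of one CLI:

```
popforce synth --seed 1 --trees 51 --out data/
popforce chronology --rwl data/rings.rwl --out chron/
popforce records --population data/population.csv --gdp data/gdp.csv \
    --rain data/rain.csv --out records.csv
popforce fit --records records.csv --models 1,2,3,4,5,6 --out table.csv
popforce recover --reps 200 --seed 1 --out recovery.json
popforce run --config config.yaml --out results/
```

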