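# Methods

## The scientific problem

`popforce` analyses a declining human population on a decadal census grid
under two exogenous pressures: an economic pull (per-capita GDP, a proxy
for labour demand outside the study region) and a climatic push (a
tree-ring-derived rainfall proxy for a semiarid agro-pastoral homeland).
The motivating case is the Aymara depopulation of the Andes of Tarapacá
between 1820 and 1960, but every component is generic: a census series, a
monotonically growing economic covariate, and a declining moisture proxy.

## The R-function model family

The observed state is the log population X_t = ln N_t; the response is the
realized per-capita growth rate over one interval of d = 10 years,

    R_t = ln N_t − ln N_{t−d}.

Candidate models combine three ingredients:

1. **Exponential growth**: R = R_m, a population in an unlimited
   environment; R_m is the maximum per-capita growth rate per decade.
2. **Generalized Ricker (discrete logistic)**:
   R = R_m − exp(a·X + C).  a > 0 measures how fast interference
   intensifies with density (a > 1: super-linear competition); C = ln c
   is the log competition constant.  The equilibrium (carrying capacity)
   is X* = (ln R_m − C)/a.
3. **Exogenous forcing**, entering in one of two geometries (Royama's
   classification):
   - *vertical*: added to R (`R ← R + v·Z`), shifting the whole R-curve
     up or down; the slope of R at equilibrium changes with the forcing;
   - *lateral*: added inside the exponential
     (`R = R_m − exp(a·X + C + b·Z)`), sliding the equilibrium along the
     X axis while the slope at equilibrium stays −a·R_m, independent of
     the forcing.  The sign of dR/dX at X* is the local stability
     criterion, so lateral forcing changes *where* the population settles
     without changing *how* it returns.

The catalogue holds six concrete variants (GDP vertical; GDP lateral;
GDP + rain vertical; rain lateral + GDP vertical; GDP + rain lateral;
GDP/rain ratio lateral) with their published least-squares estimates, plus
the pure `ricker` and `exponential` members.  Coefficients are stored
signed exactly as estimated — the generic form always adds terms, and the
sign lives in the parameter.  The ratio variant couples the two pressures
non-linearly: economic pull per unit of rainfall.

Two notational quirks of the source formulation are resolved as follows:
the additive constant of the log-scale model is taken as R_m itself (not
its exponential), matching the fitted table; and the first catalogue
variant is treated as vertical GDP forcing, which is what its printed
formula says, although the surrounding text calls it "vertical or
lateral".

## Growth records

One regression row per consecutive census pair: (X_t, R_{t+1}, GDP_t,
Rain_t), where R_{t+1} is the rate realized over [t, t+10) and both
covariates are arithmetic means of the annual values over the same
half-open decade.  (The decadal-mean treatment is stated for the rain
proxy in the source; GDP is aggregated the same way for symmetry, with a
`gdp_agg="start_year"` knob.)  Records with covariate gaps are dropped —
with 14 usable increments there is no basis for imputation.  The identity
Σ R = ln(N_last/N_first) holds exactly by construction and is asserted in
the tests.

## Fitting and model selection

Each candidate is fitted by nonlinear least squares on R (scipy
`least_squares`, trust-region reflective, analytic Jacobian).  Because GDP
spans thousands of dollars while the rain index sits near 1, covariates
are z-scored internally; a lateral coefficient back-transforms as
b = b~/σ with the shift absorbed into C, a vertical one as v = v~/σ with
the shift absorbed into R_m.  Multi-start: one deterministic start
(equilibrium placed at the observed maximum X, coefficients 0) plus
starts sampled with R_m ∈ [0.01, 3], a log-uniform in [0.1, 6], the
equilibrium within ±0.5 of max X, standardized coefficients ~ N(0, 0.5).
The same ranges serve as box constraints for density-dependent fits: R_m
is by definition a positive maximum growth rate, and without the box a
few percent of noisy replicates run off along the weak-identification
ridge (R_m → ∞ with compensating a, C).  The density-independent
exponential member keeps a sign-free R_m ∈ [−5, 5].  Exploration runs at
moderate precision from every start; the best basin is then polished to
ftol 10⁻¹⁵.  No global-optimality claim is made; stability across start
seeds (identical rss to ~10⁻¹⁶) is the operational test.

Ranking uses the concentrated Gaussian log-likelihood
lnL = −(n/2)(ln(2π·rss/n) + 1) and BIC = −2 lnL + p ln(n), with p
counting structural parameters plus the residual variance.  Evidence
weights are exp(−ΔBIC/2), normalized.  The BIC sample size defaults to
the census-point count (records + 1) rather than the increment count —
the `bic_n` knob switches to raw record count; the default reproduces the
published table's arithmetic, and the choice only shifts comparisons
between models of unequal p by p·Δln(n) ≈ 0.07.

## Simulation and evaluation

Trajectories are seeded only by the first observed value and iterated
deterministically under the covariate path; agreement with observations
is scored by Pearson correlation on the log scale (knob for natural
scale), since both the dynamics and the fitting live on X.  Iterations
with |X| > 50 abort early with the partial path attached — beyond ~10²¹
persons nothing downstream is meaningful.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:

- **GDP**: geometric growth — log value follows a random walk with drift
  (default 700 $ at 1820, drift 0.014/yr, innovation sd 0.03),
  emulating a Maddison-style national per-capita series.
- **Rainfall proxy**: AR(1) deviations (coefficient 0.3, innovation sd
  0.08) around a linear trend (level 1.2, slope −0.0025/yr), clipped at
  a 0.05 floor so ratio models stay defined; a wet early 19th century
  followed by a persistent decline.
- **Census**: forward iteration of a chosen catalogue model with additive
  Gaussian process noise on R (default sd 0.05/decade).  Noise on R
  rather than on N keeps counts positive and matches the least-squares
  error model; with zero noise the generator and the deterministic
  simulator agree bitwise.  The default scenario (model 6 at its
  published parameters, 15 census points from 1820, initial population
  1500) produces the study's qualitative shape: three decades of growth
  to ~3300 followed by sustained decline to ~650.
- **Tree rings**: per-tree negative-exponential age curves
  (a·e^(−b·age) + k with a ∈ [0.8, 1.6] mm, b ∈ [0.01, 0.05]/yr,
  k ∈ [0.2, 0.6] mm) multiplied by a shared signal and lognormal noise,
  with staggered start years.

One integer seed per scenario is split deterministically into sub-streams
(GDP, rain, trees, census), so a whole bundle reproduces bit-for-bit.

What the generator does *not* emulate: age/sex structure, migration as an
explicit flow, census undercount/definitional breaks, spatial structure,
and ring-width features beyond a negexp age trend (no disturbance pulses,
no heteroscedastic juvenile variance).  Passing recovery tests therefore
show that the estimator machinery is correct and calibrated for the
assumed error structure — not that the historical series satisfies it.

## Chronology construction

Each ring-width series is divided by a fitted age curve with a fallback
cascade: negative exponential (a, b > 0, k ≥ 0) → linear regression →
horizontal mean.  The linear fit is only accepted with a negative slope,
and either fit must stay positive and remove a non-trivial trend
(total decay > 10⁻⁶ of the mean width); otherwise the cascade continues.
The site chronology is the per-year Tukey biweight mean (c = 9, iterated
from the median with the MAD fixed, tolerance 10⁻⁸; zero MAD returns the
median).  rbar is the mean pairwise Pearson correlation over each pair's
common years, excluding pairs with < 20 shared years or zero variance —
the conventional definition EPS assumes.  EPS = n·rbar/(n·rbar + 1 −
rbar) is reported globally and in 30-year windows stepped by 15 (final
partial window kept if ≥ 15 years); the 0.85 adequacy convention is
reported, never enforced.  Variance is stabilized by scaling departures
from the mean with sqrt(N_eff/max N_eff), N_eff = n/(1 + (n−1)·rbar) —
an effective-independent-sample-size approximation to the standard
variance-adjustment method.  Calibration against an instrumental series
z-scores both over the common period and regresses precipitation on the
index, so the slope equals Pearson's r.

## Numerical choices

- Equilibria are closed-form, X* = (ln(R_m + vertical) − C − lateral)/a,
  verified (and if needed refined) by bracketed root-finding to 10⁻¹²;
  analytic and numeric slopes at X* agree to ~10⁻⁹ in the tests.
- Exponent arguments are capped at 700 before `exp`; beyond that R is
  reported as −∞ (divergent) rather than overflowing.
- Ties in minimum BIC break toward smaller p, then lower model id.
- A perfect fit (rss = 0) yields lnL = +∞; selection then assigns all
  weight to the tied perfect fits.

## Problem sizes used by the tests and the acceptance script

The recovery experiment runs 200 replicates of the 15-point study design,
fitting all six candidates per replicate with 6 optimizer starts each
(verified to reach the same optima as 40 starts on this problem);
chronology checks use 30–51 synthetic series over 120–188 years; the
AR(1) and calibration null checks use 2,000–40,000-year series where a
closed-form sampling distribution is the oracle.

## Known limitations

- With 14 increments and process noise 0.05, the four Ricker parameters
  sit on a ridge: individual estimates (especially R_m, a, C) scatter
  with median relative errors near 20% even though fits are globally
  optimal and the mean R̂_m lands within ~2% of truth.  Model
  discrimination by BIC picks the generating ratio model in roughly
  55–60% of replicates, with the remainder mostly absorbed by its
  single-covariate neighbours.  This is intrinsic sampling dispersion of
  the design, documented rather than hidden; see the recovery summary
  the acceptance script writes.
- The chronology pipeline implements standard conservative practice
  (negexp/linear/mean detrending, biweight averaging) but not cross-
  dating QC, signal-free or RCS standardization.
- Whether the depopulation analysis should use the raw or the
  variance-stabilized chronology as its rain covariate is not decidable
  from the source material; the pipeline uses the raw index and exposes
  the stabilized one alongside it.
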