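# Methods

This note records the statistical models, the numerical choices, and the
design decisions behind `itsynth`, in the order the pipeline uses them.

## Rate panels

All analyses operate on a long-format table with one row per
(country, year, age_group) and an outcome rate per 1000 women, either
supplied or derived as `1000·(births + abortions)/population` (birth-rate
mode omits abortions, for settings where abortion counts are not
comparable across countries). Series handed to the engines must be
complete over the analysis window: interior gaps raise an error rather
than being imputed, because both designs assume an uninterrupted annual
series. Rates are stored as floats and rounded only for display.

## Interrupted time series

### Model

With intervention year `T0` and time coded `t = year − T0`, the
single-unit segmented model is

    y_t = β0 + β1 t + β2 1[year ≥ c] + β3 1[year ≥ T0]
        + β4 max(0, year − (T0−1)) + β5 max(0, year − (s−1)) + ε_t

where `c` is an optional pre-intervention corrector (default 1996, the
level bump attributed to the 1995 UK contraceptive-safety scare), and `s`
an optional common-shock year (2008 in sensitivity analyses) shared by
all units. The trend-change regressor `max(0, year − (T0−1))` equals 1 in
the first intervention year, so `β4` is the accumulating per-year change
in slope — "β4 fewer events per 1000 women per year than the pre-trend
predicts".

The controlled model stacks a treated and a control unit in a single
regression with a treated intercept and treated×level-change and
treated×trend-change interactions (plus treated×pre-trend when parallel
pre-trends are not assumed, and optionally a per-unit corrector). The
interaction coefficients are the effect estimates: any level or trend
shock common to both units at `T0` cancels from them exactly (this is a
tested invariant). The "no-policy" counterfactual for the treated unit is
the model prediction with the treated-specific intervention interactions
zeroed — the treated pre-trend carrying only the changes the control
experienced. Fitting the difference inside one regression (rather than
subtracting two separate fits) yields a confidence interval for the
difference directly.

### AR(1) errors: why REML, not Cochrane–Orcutt

Annual health-outcome series are serially correlated, and 25-point series
leave little information to estimate that correlation. The textbook ITS
remedy — iterative Cochrane–Orcutt/Prais–Winsten FGLS with ρ estimated
from the lag-1 regression of OLS residuals — fails quietly here: the
segmented design (intercepts, trends, level dummies, trend changes) spans
most of the low-frequency space, so the residuals are nearly whitened
*mechanically*. On simulated panels with true ρ = 0.3 the residual-based
estimate averages ≈ 0.07 (single-unit designs give ≈ −0.04), the FGLS
standard errors are barely wider than OLS, and the nominal 95% interval
for the controlled trend difference covers the truth only ~85% of the
time.

The default scheme therefore estimates ρ by **REML profile likelihood**
(the restricted likelihood accounts for the fitted regression exactly,
removing the attenuation; mean ρ̂ ≈ 0.29 under true 0.3), fits by
Prais–Winsten GLS at ρ̂ (first observation of each unit block retained,
scaled by √(1−ρ²)), and computes **Satterthwaite degrees of freedom** per
coefficient from the observed REML information for (σ², ρ), so the t
intervals widen for the variance-parameter uncertainty that dominates at
this length (typical df ≈ 8 rather than n−k ≈ 45). Measured null coverage
of the controlled trend-difference CI is ≈ 95% over 1000 simulated
panels. This mirrors small-sample mixed-model practice (REML +
Satterthwaite/Kenward–Roger). The Cochrane–Orcutt iteration
(`ar1_method="co"`, iterate to |Δρ| < 1e-6, max 50) and plain OLS with
Newey–West lag-1 standard errors (`ar1_correction=False, hac=True`) remain
available for comparison.

Diagnostics (Durbin–Watson, ACF and PACF at lag 1) are always computed on
the *untransformed* residuals and reported regardless of the correction
setting, so the user can replicate the practice of correcting only when
all three diagnostics agree; the correction itself is governed by an
explicit flag rather than an automatic rule.

Phase-in years, when excluded, are dropped as rows, not dummied. 95%
intervals use the t distribution (small n). A noiseless series generated
from the design's own column space is recovered exactly (zero residuals,
zero-width intervals).

## Synthetic control

### Weights

Donor weights solve `min_w Σ_k v_k (x1_k − X0_k·w)²` on the probability
simplex. The QP is solved by a primal **active-set method**: start at the
best single-donor vertex, add the most KKT-violating excluded donor,
step with exact line search to the blocking bound, and drop constraints
with negative multipliers. Because the Hessian `2A'A` is only positive
semidefinite whenever there are fewer predictors than donors, direction
solves add a ridge of `1e-10·tr(H)/J` (guaranteeing strict descent and
finite termination) and the final support is re-solved exactly without
it; stationarity is declared when the predicted objective decrease falls
below `1e-13·(1+‖b‖²)`, which guards the near-perfect-fit regime. On
random instances the solution matches an exhaustive support-enumeration
oracle to machine precision. The solver is deterministic; no SLSQP or
random restarts are involved at this level.

### Predictors and the grouping search

Predictors are means of the outcome over contiguous blocks of
pre-intervention years; auxiliary covariates (optional, off by default)
are z-scaled before entering the V-weighted objective so that scales such
as GDP do not dominate. With ≤ 15 pre-years, all `2^(n−1)` contiguous
partitions are enumerated and each is fitted and scored by pre-period
outcome MSPE. "As few groups as possible with minimised MSPE" is made
precise as a tolerance-band lexicographic rule: among partitions within
5% of the global minimum MSPE (plus an absolute epsilon of 1e-12 so that
a degenerate all-partitions-perfect case collapses into one tie band),
the fewest-group partition wins, ties broken by lower MSPE and then by
earliest cut positions. The full enumeration table is returned for audit.
The search scores candidates with equal predictor weights; the final fit
may then optimise V (`v_mode="optimized"`): the selection concerns the
grouping, and scoring 256 partitions under a nested V search would
multiply the cost for no change in ranking in practice.

The importance weights V, when optimised, minimise pre-period outcome
MSPE of the induced w*(V) by Nelder–Mead on a log-simplex
parametrisation, multi-started from equal V plus seeded random draws
(deterministic given the seed). With a single predictor V = (1) is
forced.

### Placebo inference

*In-space*: each donor is treated in turn; its donor pool is the
remaining units **excluding the real treated unit**, so no placebo can
borrow the exposed series. By default the full grouping search is re-run
per placebo (`protocol="full"`, the methodologically symmetric choice); a
`"fixed"` protocol reuses the treated unit's predictor spec and is much
cheaper. Units whose pre-period MSPE exceeds 5× the treated unit's can be
filtered before plotting gap fans (the treated unit is always retained;
the filter is idempotent).

*Ratio test*: each unit's statistic is `mspe_post / mspe_pre`; a zero
pre-period MSPE makes the ratio undefined and is reported as an error
naming the unit. The permutation p-value is `rank/n`, where rank counts
the treated unit itself and every unit with a ratio ≥ the treated one
(ties outrank — the conservative direction). With 16 units, 13 placebo
exceedances give p = 14/16 = 0.875 (displayed 0.88) and rank 11 gives
11/16 = 0.6875 (0.69). Under an exchangeable null the p-value is uniform
on its 16 attainable values {1/16, …, 1}; the calibration check therefore
measures the Kolmogorov distance of the empirical distribution from that
**discrete** null CDF (against the continuous uniform the distance is at
least 1/16 by construction, which would measure discretisation rather
than calibration). Measured distance over 500 exchangeable replicates:
≈ 0.066.

*In-time*: the protocol is re-run with the pre-period ending before each
dummy date; a dummy at the true intervention year takes exactly the main
fit's code path and reproduces it bit for bit (tested).

*Leave-one-out*: repeatedly remove the currently top-weighted donor
(weights within 1e-9 count as tied; alphabetically first tied donor is
dropped) and refit with the predictor spec held fixed, so changes are
attributable to donor removal alone.

## Synthetic-data generator

Each unit's latent mean is a shared piecewise-linear secular trend —
default slope +0.5/yr to 1998, −1.5/yr from 1999, an extra −1.0/yr from
2008 — from a baseline of 45 events per 1000 women at 1990, plus a
unit-level offset (sd 3). "UK-like" units add a +2.0 level bump from 1996.
The treated unit may carry an intervention effect (level Δ plus
accumulating trend Δ/yr from 1999; default (0, 0), the null world). Noise
is AR(1) with ρ = 0.3 and innovation sd 0.8, initialised at stationarity
(variance sd²/(1−ρ²)) so 25-point series have no burn-in artefact. Rates
are truncated at zero with a warning; default parameters make truncation
negligible. Count columns can be emitted by inverting the rate against a
fixed population of 100 000, making rate↔count round-trips exact. The
same seed always reproduces the same panel.

Two structural points matter for what passing tests do and do not show:

* **Mixture mode and identifiability.** For planted-weight recovery the
  treated series is a stated convex combination of the donors' *realised*
  series plus its own noise. Under the default conditions (15 donors, 9
  pre-years, donors differing only by constant offsets) the weights are
  *not identifiable*: 15 weights against 9 equations is underdetermined,
  and offset-only donors leave sum-zero weight directions pinned by
  nothing but noise. The recovery studies therefore use a 4-donor pool
  with per-unit slope heterogeneity (`slope_sd=0.5`/yr; default 0 so the
  base generator still honours the parallel-trends world the ITS design
  assumes) and noise sd 0.05 — conditions under which the sum-zero space
  is exactly pinned by the offset, slope and pill structure. Mean maximal
  weight error over 100 seeds: ≈ 0.03. Recovery failures under weaker
  identification are a property of the estimand, not the solver (the
  solver's objective is verified against an exact oracle separately).
* **What is not emulated:** age-structured fertility, cohort effects,
  policy spillovers between units, measurement revisions, and any
  calibration to real national series. Passing tests demonstrate that the
  engines are correct and calibrated under the stated data-generating
  process, not that any particular real-world policy was or was not
  effective.

## Problem sizes and determinism

The simulation studies use sizes chosen to give stable Monte-Carlo
estimates while staying desk-scale: 1000 replicates for the null-coverage
check of the controlled ITS (binomial se ≈ 0.7% at 95%), 500 for p-value
uniformity (KS noise ≈ 0.03–0.04 against a band of 0.08), 100 for
planted-weight recovery, 256-partition enumeration for the grouping
oracle. The whole acceptance run completes in about a minute on one CPU.
Every stochastic component takes an explicit seed; panels, CLI outputs
and placebo protocols are bit-reproducible given the seed.

## Known limitations

* The ITS engine fits one control unit at a time (pairwise comparisons),
  matching the design it implements; multi-control ITS would need a
  different error structure.
* REML+Satterthwaite is calibrated for the AR(1) world the generator
  produces; heavier serial dependence (AR(2), long memory) would require
  a richer correlation model.
* The grouping search is exhaustive and intentionally refuses pre-periods
  longer than 15 years unless forced.
* The V-optimisation is a heuristic multi-start over a non-convex
  landscape; it is deterministic given the seed but not guaranteed
  globally optimal (its result is accepted only when it beats equal-V on
  the pre-period MSPE, which is tested).
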