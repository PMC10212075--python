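# Methods

`fishlhopt` predicts how marine-fish reproductive schedules — the age at
maturity and the steepness of the fecundity–mass relationship — should vary
across latitudes if life histories are optimised against local mortality,
growth and offspring-size conditions, and projects how those schedules shift
under ocean warming.  This note records the model, the estimation choices,
and the places where a design decision was genuinely open.

## The allocation model

Surplus energy ("production") is acquired at rate `P(w) = k w^b` with
`b = 3/4` by default (any `0 < b < 1` is supported; `b = 2/3` gives the
cubic, von Bertalanffy-like variant).  A fraction `u(t)` of production goes
to growth: `u = 1` before the age at maturity `alpha` and
`u = exp(-h (t - alpha))` after, so the reproductive-output rate is
`f(t) = (1 - u) P(w)`.  Because `dw/dt = u P(w)` is separable, the mass
trajectory has a closed form in which `w^(1-b)` grows linearly in the
"effective growth time" `tau(t)` that saturates at `alpha + 1/h`.  The
closed form is verified against adaptive Runge–Kutta integration of the
allocation ODE to 1e-6 relative error in the test-suite.

Units: grams and years throughout; `k` in g^(1-b) y^-1; `h` and `M` in y^-1.

## Fitness, longevity and the reproductive window

Fitness is lifetime reproductive output

    R0 = (1 - p) exp(-M alpha) \int exp(-M (t - alpha)) f(t) dt,

with survivorship combining an initial mortality burst `p` (0.8 by default;
it scales fitness and sets the longevity bound but barely moves the
optimum) and a constant instantaneous rate `M`.  The longevity bound
`T = -(1/M) ln(0.01 / (1 - p))` is the horizon at which survivorship
reaches 1% (`ln(20)/M` at `p = 0.8`).

**Window anchoring.**  Two conventions are implemented for how `T` closes
the fitness integral.  Under `horizon="birth"` the integral runs over
`[alpha, T]` with `T` an absolute age.  Under `horizon="maturity"` — the
default — `T` is the *duration* of the reproductive window and the integral
runs over `[alpha, alpha + T]`.  The published latitudinal predictions this
package reproduces (maturation near 12 y at 60 deg, at ~1 y in the tropics,
with the optimum computed per latitude from the fitted gradients) are
recovered only under the duration convention; under the birth-anchored
window the 60-deg optimum falls to ~4 y.  Both remain available, and every
numerical claim in the test-suite states which convention it uses.  The
window duration is capped at 60 y for numerical safety when `M` is tiny
(a warning is logged).

The integral is evaluated by adaptive quadrature (relative tolerance 1e-9)
and checked against an instant-switch closed form (`h -> inf`) and a
trapezoid oracle at 1e-4 y resolution.

**Optimiser.**  `alpha` is maximised by a coarse grid (0.05 y step over the
window) followed by bounded scalar refinement to 1e-4 y, with ties broken
toward the smaller `alpha`.  A boundary optimum at `alpha = 0` is a valid
outcome under extreme mortality.  A first-order condition was deliberately
not used: `R0(alpha)` can be nearly flat near the boundary, and the grid
also provides the tie-breaking rule.

## Reproductive scaling

The scaling exponent is the log–log slope of reproductive output against
body mass over the reproductive window, evaluated at the optimal schedule.
Two estimators are provided:

* `method="cumulative"` (default): the regression of
  `ln(cumulative output)` on `ln(mass)` with uniform time weighting over
  the window, computed in the continuum (the limit of an OLS on an
  ever-denser uniform time grid; the discrete slope converges slowly
  because `ln C` has an integrable logarithmic singularity at maturity, so
  the limit itself is the well-defined quantity).  The quadrature uses a
  grid logarithmic near maturity and linear elsewhere; refining it changes
  the slope by <1e-3.
* `method="annual"`: OLS of the instantaneous output *rate* against mass at
  yearly steps `alpha+1, alpha+2, ...` up to the window end, falling back
  to the window midpoint and end when fewer than two yearly steps fit.
  The rate at exactly `alpha` is zero, which is why the steps start one
  year in.

The cumulative estimator is the default because it reproduces both the
published endpoint values (2.8 at 0 deg; 8.7 at 60 deg, to within 8%) and
their threefold ratio, whereas the yearly rate slope spans only ~1.3–3.3
across the same calibration.  Both satisfy the model's qualitative
predictions: scaling exceeds `b`, exceeds 1 (hyperallometry) and increases
with the age at maturity.

## Calibration

**Latitude gradients.**  `ln M`, `ln k` and `ln w0` are regressed on
absolute latitude (OLS; normal-approximation intervals; the sign of
latitude is ignored).  Two published calibrations ship with the package:

* `literature_gradients("coefficients")` — the reported regression
  coefficients, rounded to two decimals, with standard errors recovered
  from the reported 95% intervals (used for bootstrap ribbons).
* `literature_gradients("predictions")` — gradients reconstructed from the
  reported per-latitude predictions (M: 0.85 -> 0.17 /y over 0–60 deg;
  k: 4.36 -> 2.11; w0: 14.4 -> 12.9 g).  The reported k and w0 point values
  at 0, 20, 40 and 60 deg are log-linear in latitude to three decimals, so
  this reconstruction recovers the unrounded fit; the rounded coefficients
  do not reproduce those same point values (e.g. `exp(-0.31) = 0.73`, not
  0.85).  Pipelines that reproduce published outputs use this source.

**Growth and the allocation rate.**  `(k, w0)` are fitted to pre-maturity
mass-at-age data by nonlinear least squares on the closed-form branch,
initialised from the linearisation `w^(1-b) ~ t`.  Where a trajectory
approaches its asymptote, `h` is fitted on both branches (jointly with
`k, w0`, or alone with them fixed).  With no trajectory data, `h` defaults
to its empirical median 0.26 y^-1 (quartiles 0.18–0.39); fitness varies far
more across `alpha` than across this `h` range, which the suite checks.

**Egg-count model.**  After curation (marine species only; elasmobranchs
and tuna excluded; one modal year per species and location, ties to the
earlier year; at least 10 records per species-location), batch fecundity is
modelled as

    ln F = c + d |lat| + (RS_a + RS_b |lat|) ln(mass) + species effects,

a linear mixed model (REML) with per-species random intercepts and mass
slopes.  When the mixed fit is singular, or when a phylogeny is supplied,
a two-stage estimator takes over: per-species OLS of `ln F` on `ln mass`,
then meta-regression of the species intercepts and slopes on latitude —
generalised least squares with a Brownian-motion correlation (from MRCA
root-distances on the tree) for the intercepts.  On balanced noiseless data
the two estimators agree exactly.  Egg counts are treated as Gaussian on
the log scale, matching how the coefficients being reproduced were
estimated.  The published fixed effects (`c = 5.39`, `d = -0.02`,
`RS_a = 1.00`, `RS_b = 0.004`) are available as
`literature_fecundity_coefs()`; they put a 10-kg equatorial female at
~2.19 million eggs per batch.

**A50.**  Age at 50% maturity uses the same log-linear machinery, with
indirect (back-calculated) estimates excluded by default.  The published
intercept is -0.28 on the ln scale; the printed slope (0.03, with an
inconsistent interval) cannot reproduce the published 7.7-fold change over
0–60 deg, so the packaged constant uses the endpoint-derived slope
`ln(5.87/0.76)/60 = 0.034`.

## Seasonal (bang-bang) model

As a robustness alternative, life is discretised into one-year seasons
containing a 200-day productive block; within each block the individual
grows first and then switches abruptly to pure reproduction, with mortality
acting year-round.  Switch times are found by backward induction on the
transformed mass state `v = w^(1-b)` (value function on an 800-point grid,
301 candidate switch times), then polished by L-BFGS-B on the exact fitness
of the full switch vector; on 3-season toy problems the result matches
exhaustive grid search.  The horizon extends until later seasons contribute
<0.1% to fitness.

The age at maturity is reported as the first reproductive season's index
plus the *fraction* of the productive season spent growing — i.e. the
productive days are taken as spread through the year when converting the
switch position to a calendar age.  Under the published settings (`w0 = 1`,
`k = 5`, 200-day season) this gives 2.77 y at `M = 0.6` and maturation in
the first season at `M = 1.0`.  The smooth allocation model fitted to the
resulting end-of-season weights (with `k`, `w0` and the maturation age held
fixed and only `h` free, on the productive-time axis where the two models
share a pre-maturity trajectory) tracks them to 3% relative RMS at
`M = 0.2`, degrading to ~14% at `M = 1.0`, where a staircase schedule is
intrinsically less smooth.  For latitudinal sweeps, season length follows
the logit-linear regression `logit(P) = 2.96 - 0.07 |lat|` and mortality
the log-linear gradient; maturation jumps by whole seasons, so the age
profile is discontinuous by construction.

## Sensitivity extensions

**Size-dependent mortality** replaces `M` by `M (w / w_ref)^(-q)`;
survivorship uses the cumulative hazard along the growth trajectory
(dense trapezoid interpolant inside the fitness integral; the hazard
itself is checked against a 1e-4-resolution oracle), and the 1%-survival
age solves the hazard condition by root bracketing.  `q = 0` reduces
exactly to the baseline.  The reference mass is a required user choice:
normalising at a trajectory-derived mass (maturity or asymptotic mass of
the baseline optimum) makes `w_ref` itself a strong function of latitude
and degrades the optimisation (adult mortality escaping to zero, or
juvenile mortality inflated until all optima collapse).  A fixed
cross-latitude reference near the centre of the observed mass range
(~700 g, the geometric midpoint of 10 g – 50 kg) preserves the qualitative
latitudinal pattern for `q` in {0.25, 0.5}, which is what the suite
checks.

**Overhead costs** multiply the output rate by `(1 - c(w))` with a
logistic `c(w)`; the cost fraction must stay in [0, 1) (validated at
construction and again along the trajectory).  A cost that rises with size
flattens the scaling exponent at every calibrated latitude; `kind="none"`
reproduces the baseline exactly.

## Climate projection

Mean SST is smoothed on absolute latitude with a penalised spline and then
projected onto the monotone-decreasing cone (pool-adjacent-violators on a
fine grid), guaranteeing a unique inverse.  For a warming `delta_T` at
latitude `L`, the matched latitude solves `SST(L') = SST(L) + delta_T` by
root bracketing; when the projected temperature exceeds the warmest
present-day mean (low latitudes), the projection is reported missing
rather than extrapolated.  Future fecundity at `L` is the present-day
prediction of the egg-count model at `L'`; the mass-specific percentage
change equals the percentage change in eggs because mass is held fixed.
Scenario offsets: +0.64 and +0.73 C (low emissions, mid/late century),
+0.95 and +2.58 C (high emissions).  The observed climatology is a user
input; the packaged synthetic profile (warm plateau of 27–28 C below
~20 deg declining smoothly to ~1 C at 75 deg) reproduces the qualitative
published result — large high-latitude females lose the most eggs — but
not the published magnitudes, which depend on the real SST curve.

## Synthetic data

`fishlhopt.synth` generates every input table with recorded ground truth:
log-linear gradients with lognormal scatter (sd 0.5 for mortality, 0.35
and 0.4 for growth and offspring size — magnitudes chosen so the gradient
fits leave most variance unexplained, as in the compiled data), mass-at-age
trajectories with 10% multiplicative noise, egg counts with species
effects of sd 0.3 (intercept) and 0.05 (mass slope) and residual sd 0.5
around the published fixed effects, optionally with a Brownian intercept
component on a simulated birth–death phylogeny, and smooth or linear SST
profiles.  The default truth equals the published calibration, so synthetic
runs double as reproduction rehearsals.  One integer seed drives each
generator; identical seeds give identical tables.

What the generator does *not* emulate: the literature compilation's
sampling structure (reference clustering beyond simple per-reference
replication, geographic clumping, body-size-dependent reporting biases)
and any mismatch between the assumed lognormal noise and real residuals.
Passing recovery tests therefore demonstrates the estimators are correct
under the stated generative model, not that the published coefficients are
unbiased for real oceans.

## Numerical choices and limitations

* Fitness quadrature: `scipy.integrate.quad`, relative tolerance 1e-9;
  optimiser grid 0.05 y + refinement to 1e-4 y; bootstrap replicate sweeps
  use a 0.2 y grid for speed.
* Scaling quadrature: 4,500-point hybrid grid (geometric near maturity,
  linear in the bulk); stable to <1e-3 under refinement.
* The reproductive window is capped at 60 y; the size-dependent longevity
  search is bracketed on (0, 200] y.
* Reproduction of published values is limited by rounding in the printed
  coefficients: maturation ages and scaling exponents are recovered to
  6–10%, not to print precision; the unrounded posterior fits are not
  recoverable from the available information.
* The model optimises `alpha` only, holding `h` fixed; joint optimisation
  of allocation shape, temperature-dependent production exponents, and
  feedbacks from life history to mortality are out of scope.
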