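# fishlhopt

Life-history optimisation of marine-fish reproductive schedules across
latitudes — and what they imply for fecundity under ocean warming.

Within fish species, batch fecundity rises *disproportionately* with body
mass (reproductive hyperallometry), and both the steepness of that
relationship and the age at maturity vary systematically from the tropics
to the poles.  `fishlhopt` implements the optimisation argument that links
the two: given how natural mortality `M`, the growth coefficient `k` and
the offspring-size parameter `w0` change with latitude, the age at maturity
that maximises lifetime reproductive output — and the fecundity–mass
scaling it produces — can be predicted, compared against compiled
maturation and fecundity data, and projected forward under warming
scenarios.  It is written for quantitative ecologists and fisheries
scientists who want the full pipeline (calibration, optimisation,
robustness checks, projection) as tested, scriptable components.

## The model

Production scales allometrically with mass, `P(w) = k w^b` (default
`b = 3/4`), and is split between growth and reproduction by an allocation
fraction

    u(t) = 1                      for t <  alpha
    u(t) = exp(-h (t - alpha))    for t >= alpha,

so that `dw/dt = u(t) P(w)` and the reproductive-output rate is
`f(t) = (1 - u(t)) P(w)`.  The mass trajectory has a closed form: `w^(1-b)`
grows linearly in effective growth time, saturating at `alpha + 1/h`.
Fitness is lifetime reproductive output

    R0 = (1 - p) e^(-M alpha) ∫ e^(-M (t - alpha)) f(t) dt,

integrated over a reproductive window whose duration
`T = -(1/M) ln(0.01 / (1 - p))` is the 1%-survivorship horizon; `p` is an
initial mortality burst (0.8).  The optimal `alpha` trades juvenile
survival against the larger body — and steeper fecundity trajectory — that
later maturation buys.  The reproductive-scaling exponent is the log–log
slope of reproductive output against mass over that window.  Two companion
analyses probe robustness (size-dependent mortality, overhead costs of
reproduction; a seasonal bang-bang allocation model solved by backward
induction), and a temperature-matching step projects fecundity change by
finding, for each warmed latitude, the latitude that currently experiences
its future temperature.

## Worked example

Optimal schedule at 60 degrees absolute latitude, using the published
gradient calibration:

```python
from fishlhopt import (GrowthParams, MortalityModel, LifeHistoryModel,
                       literature_gradients)

g = literature_gradients("predictions")
M, k, w0 = g.predict(60.0)          # 0.17 /y, 2.11 g^(1/4)/y, 12.9 g
res = LifeHistoryModel(GrowthParams(k=k, w0=w0), MortalityModel(M=M),
                       h=0.26).fit()
print(res.summary())
```

```
Life-history optimisation (Day-Taylor allocation model)
========================================================
  production:  k = 2.11 g^(1-b)/y, b = 0.75, w0 = 12.9 g
  mortality:   M = 0.17 /y, burst p = 0.8
  allocation:  h = 0.26 /y (fixed)
--------------------------------------------------------
  optimal age at maturity   alpha* = 11.158 y
  reproductive window ends  T      = 28.780 y
  mass at maturity                 = 3665 g
  lifetime reproductive output R0  = 165.557
  reproductive scaling exponent    = 8.078
```

A low-mortality, slow-growing polar environment favours delaying maturity
to ~11 y at ~3.7 kg, and the resulting fecundity–mass relationship is
steeply hyperallometric (exponent ~8).  The same call at latitude 0 gives
maturation within the first year and an exponent of 2.79 — the
tropical-to-polar contrast the model exists to explain.  On the empirical
side, the fitted egg-count model predicts a 10-kg equatorial female to
produce

```python
from fishlhopt import literature_fecundity_coefs, predict_fecundity
predict_fecundity(literature_fecundity_coefs(), 10_000, 0.0)  # 2.19e+06 eggs
```

## Command line

```sh
fish-lhopt simulate  --seed 1 --out run/    # synthetic inputs, known truth
fish-lhopt calibrate --seed 1 --out run/    # gradient/growth/fecundity fits
fish-lhopt sweep     --out run/             # optimum per latitude
fish-lhopt climate   --scenario RCP8.5-late --out run/
fish-lhopt reproduce --out run/             # computed vs reported table
```

Each command writes CSV outputs plus a JSON manifest (seed, config, input
hashes); a YAML config file can replace the flags.

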