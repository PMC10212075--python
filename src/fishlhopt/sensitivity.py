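"""Sensitivity machinery: size-dependent mortality and reproductive overheads.

Two relaxations of the baseline model:

* **Size-dependent mortality.**  The instantaneous rate becomes
  ``M * (w / w_ref)**(-q)``: larger fish die at a lower rate.  Survivorship
  is then ``(1 - p) * exp(-Lambda(t))`` with the cumulative hazard
  ``Lambda(t) = integral of the rate along the growth trajectory``, and the
  1%-survival longevity solves ``Lambda = ln((1-p)/0.01)`` numerically.
  ``q = 0`` reduces everything exactly to the baseline.

* **Overhead costs of reproduction.**  A fraction ``c(w)`` of reproductive
  allocation is lost before it manifests as output:
  ``f(t) = (1 - u(t)) * P(w) * (1 - c(w))``.  The published explorations use
  logistic costs such as ``0.4 / (1 + exp(-0.002*(w - 2000)))``; costs that
  rise with size flatten the predicted reproductive scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

from .growth import (
    AllocationSchedule,
    GrowthParams,
    MortalityModel,
    fecundity_rate,
    weight_at,
)
from .optimize import WINDOW_CAP, ScalingEstimate, lifetime_R0, reproductive_scaling

__all__ = [
    "mortality_rate_at",
    "cumulative_hazard",
    "sizedep_longevity",
    "lifetime_R0_sizedep",
    "optimal_maturity_sizedep",
    "OverheadCostSpec",
    "scaling_with_overheads",
]


def mortality_rate_at(w, m: MortalityModel):
    """Instantaneous mortality rate (y^-1) at mass ``w`` (g).

    ``M * (w / w_ref)**(-q)``; constant ``M`` when ``q = 0``.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("mass must be positive")
    if m.q == 0:
        out = np.full_like(w, m.M)
    else:
        out = m.M * (w / m.w_ref) ** (-m.q)
    return out if out.ndim else float(out)


def cumulative_hazard(t: float, gp: GrowthParams, s: AllocationSchedule, m: MortalityModel) -> float:
    """Integrated mortality hazard from age 0 to ``t`` along the trajectory."""
    if m.q == 0:
        return float(m.M * t)
    val, _ = quad(
        lambda u: mortality_rate_at(weight_at(u, gp, s), m),
        0.0,
        t,
        limit=200,
        epsrel=1e-9,
        points=[s.alpha] if 0 < s.alpha < t else None,
    )
    return float(val)


def sizedep_longevity(
    gp: GrowthParams, s: AllocationSchedule, m: MortalityModel, cap: float = 200.0
) -> float:
    """Age at 1% survivorship under size-dependent mortality.

    Solves ``Lambda(T) = ln((1 - p)/0.01)`` on the cumulative hazard by root
    bracketing.  Raises if the threshold is not reached below ``cap`` years.
    """
    target = float(np.log((1.0 - m.p) / 0.01))
    g = lambda t: cumulative_hazard(t, gp, s, m) - target  # noqa: E731
    if g(cap) < 0:
        raise RuntimeError(f"1%-survival age not reached below {cap} y; hazard too small")
    return float(brentq(g, 1e-9, cap, xtol=1e-8))


def lifetime_R0_sizedep(
    alpha: float, gp: GrowthParams, h: float, m: MortalityModel, horizon: str = "maturity"
) -> float:
    """Lifetime reproductive output with mass-dependent survivorship.

    Replaces ``exp(-M t)`` by ``exp(-Lambda(t))`` in the fitness integral;
    the longevity bound solves the 1%-survival condition on the cumulative
    hazard.  Exactly reproduces :func:`fishlhopt.optimize.lifetime_R0` at
    ``q = 0``.
    """
    if m.q == 0:
        return lifetime_R0(alpha, gp, h, m, horizon=horizon)
    s = AllocationSchedule(alpha=alpha, h=h)
    T = min(sizedep_longevity(gp, s, m), WINDOW_CAP)
    if horizon == "birth":
        lo, hi = alpha, T
        if lo >= hi:
            return 0.0
    else:
        lo, hi = alpha, alpha + T
    # dense hazard interpolant (cumulative trapezoid) keeps the fitness
    # integral from nesting adaptive quadratures
    tt = np.linspace(0.0, hi, 4001)
    rate = mortality_rate_at(weight_at(tt, gp, s), m)
    lam_grid = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(tt))])
    lam = lambda t: np.interp(t, tt, lam_grid)  # noqa: E731
    lam_alpha = lam(alpha)

    def integrand(t):
        return np.exp(-(lam(t) - lam_alpha)) * fecundity_rate(t, gp, s)

    val, _ = quad(integrand, lo, hi, limit=200, epsrel=1e-8)
    return float((1.0 - m.p) * np.exp(-lam_alpha) * val)


def optimal_maturity_sizedep(
    gp: GrowthParams,
    m: MortalityModel,
    h: float = 0.26,
    horizon: str = "maturity",
    grid_step: float = 0.25,
    xtol: float = 1e-3,
) -> tuple[float, float]:
    """(alpha*, R0*) under size-dependent mortality (coarse grid + refine).

    The reference mass ``w_ref`` should normally be set to the mass at
    maturity of the size-independent optimum so that ``q`` tilts, rather
    than rescales, the mortality schedule.
    """
    obj = lambda a: lifetime_R0_sizedep(a, gp, h, m, horizon=horizon)  # noqa: E731
    # upper bound for the search: longevity of the pure-growth trajectory,
    # which has the lowest hazard (largest masses) of any candidate schedule
    s_grow = AllocationSchedule(alpha=WINDOW_CAP, h=h)
    amax = min(sizedep_longevity(gp, s_grow, m), WINDOW_CAP)
    grid = np.arange(0.0, amax, grid_step)
    vals = np.array([obj(a) for a in grid])
    i = int(np.argmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda a: -obj(a), bounds=(lo, hi), method="bounded",
                              options={"xatol": xtol})
        if -res.fun >= vals[i]:
            return float(res.x), float(-res.fun)
    return float(grid[i]), float(vals[i])


@dataclass(frozen=True)
class OverheadCostSpec:
    """Size-dependent overhead cost of reproduction.

    ``kind="none"`` is the baseline (no losses).  ``kind="logistic"`` gives
    ``c(w) = c_max / (1 + exp(-rate * (w - midpoint))) + offset``; the cost
    fraction must stay inside [0, 1) for all masses.
    """

    kind: str = "none"
    c_max: float = 0.0
    rate: float = 0.0
    midpoint: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "logistic"):
            raise ValueError(f"unknown cost kind {self.kind!r}")
        if self.kind == "logistic":
            lo, hi = self.offset, self.c_max + self.offset
            if not (0.0 <= min(lo, hi) and max(lo, hi) < 1.0):
                raise ValueError(
                    f"cost fraction range [{min(lo, hi):.3g}, {max(lo, hi):.3g}] leaves [0, 1)"
                )

    def cost(self, w):
        w = np.asarray(w, dtype=float)
        if self.kind == "none":
            out = np.zeros_like(w)
        else:
            out = self.c_max / (1.0 + np.exp(-self.rate * (w - self.midpoint))) + self.offset
        return out if out.ndim else float(out)


def scaling_with_overheads(
    gp: GrowthParams,
    s: AllocationSchedule,
    m: MortalityModel,
    cost: OverheadCostSpec,
    method: str = "cumulative",
    horizon: str = "maturity",
) -> ScalingEstimate:
    """Reproductive scaling when a fraction of allocation is lost as overhead.

    The output rate becomes ``(1 - u) P(w) (1 - c(w))``; the scaling is then
    extracted exactly as in :func:`fishlhopt.optimize.reproductive_scaling`.
    ``kind="none"`` reproduces the base scaling identically.
    """
    if cost.kind == "none":
        return reproductive_scaling(gp, s, m, method=method, horizon=horizon)

    wmax = weight_at(s.alpha + WINDOW_CAP, gp, s)
    grid = np.linspace(gp.w0, wmax, 512)
    if np.any(cost.cost(grid) >= 1.0):
        raise ValueError("overhead cost reaches 1 on the trajectory; no output possible")

    def fec(t):
        w = weight_at(t, gp, s)
        return fecundity_rate(t, gp, s) * (1.0 - cost.cost(w))

    return reproductive_scaling(gp, s, m, method=method, horizon=horizon, fecundity=fec)
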