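"""Growth, allocation and fecundity under the Day–Taylor energy-allocation model.

An individual acquires surplus energy ("production") at a rate that scales
allometrically with body mass,

    P(w) = k * w**b,            0 < b < 1,

and routes a fraction ``u(t)`` of it into somatic growth.  Before the age at
maturity ``alpha`` all production goes to growth (``u = 1``); afterwards the
growth share decays exponentially at rate ``h`` (``u = exp(-h*(t - alpha))``)
and the remainder ``(1 - u) * P(w)`` is the instantaneous reproductive output,
a mass-flux proxy for fecundity.  Because ``dw/dt = u(t) * P(w)`` is separable,
the mass trajectory has a closed form for any production exponent ``b``: the
quantity ``w**(1-b)`` grows linearly in "effective growth time"

    tau(t) = t                                     for t <  alpha
    tau(t) = alpha + (1 - exp(-h*(t-alpha))) / h   for t >= alpha,

so ``w(t) = ((1-b)*k*tau(t) + w0**(1-b)) ** (1/(1-b))``.  With the default
``b = 3/4`` this is the familiar quartic trajectory; ``b = 2/3`` gives the
cubic (von Bertalanffy-type) variant.

Units: mass in grams, age in years, ``k`` in g^(1-b) y^-1, ``h`` and the
mortality rate ``M`` in y^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParams",
    "AllocationSchedule",
    "MortalityModel",
    "production",
    "allocation_fraction",
    "weight_at",
    "fecundity_rate",
    "asymptotic_weight",
]


@dataclass(frozen=True)
class GrowthParams:
    """Production parameters of the growth model.

    Parameters
    ----------
    k : float
        Production coefficient (g^(1-b) y^-1), ``k > 0``.
    w0 : float
        Theoretical initial weight (g), ``w0 > 0``.  Plays the role of the
        offspring-size parameter; analogous to ``t0`` in length-based
        von Bertalanffy fits.
    b : float, optional
        Production scaling exponent, ``0 < b < 1``.  Default 3/4.
    """

    k: float
    w0: float
    b: float = 0.75

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"production coefficient k must be positive, got {self.k}")
        if not self.w0 > 0:
            raise ValueError(f"initial weight w0 must be positive, got {self.w0}")
        if not 0 < self.b < 1:
            raise ValueError(f"production exponent b must lie in (0, 1), got {self.b}")


@dataclass(frozen=True)
class AllocationSchedule:
    """Age at maturity and the post-maturity allocation shift rate.

    ``alpha`` is the age (y) at which reproductive allocation begins and ``h``
    (y^-1) the exponential rate at which the growth share of production
    declines thereafter.  ``h = 0`` is rejected: it would mean reproduction
    never actually starts.
    """

    alpha: float
    h: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"age at maturity alpha must be >= 0, got {self.alpha}")
        if not self.h > 0:
            raise ValueError(f"allocation rate h must be positive, got {self.h}")


@dataclass(frozen=True)
class MortalityModel:
    """Instantaneous natural mortality with an initial burst.

    Survivorship to age ``t`` is ``(1 - p) * exp(-M * t)`` in the
    size-independent case (``q = 0``): a fraction ``p`` of offspring dies
    immediately after spawning (larval burst) and survivors die at constant
    rate ``M``.  ``q > 0`` makes the rate decline with mass as
    ``M * (w / w_ref) ** (-q)``, normalised at the reference mass ``w_ref``
    (see :mod:`fishlhopt.sensitivity`).
    """

    M: float
    p: float = 0.8
    q: float = 0.0
    w_ref: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError(f"mortality rate M must be positive, got {self.M}")
        if not 0 <= self.p < 1:
            raise ValueError(f"initial mortality burst p must lie in [0, 1), got {self.p}")
        if self.q < 0:
            raise ValueError(f"size-dependency exponent q must be >= 0, got {self.q}")
        if self.q > 0 and (self.w_ref is None or not self.w_ref > 0):
            raise ValueError("size-dependent mortality (q > 0) requires a positive w_ref")


def production(w, gp: GrowthParams):
    """Surplus energy acquisition rate ``P(w) = k * w**b`` (g y^-1).

    ``w`` may be a scalar or array of non-negative masses (g).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("mass must be non-negative")
    out = gp.k * w**gp.b
    return out if out.ndim else float(out)


def allocation_fraction(t, s: AllocationSchedule):
    """Share of production routed to growth at age ``t``.

    1 before maturity; ``exp(-h*(t - alpha))`` afterwards.  Continuous and
    non-increasing in ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    out = np.where(t < s.alpha, 1.0, np.exp(-s.h * np.maximum(t - s.alpha, 0.0)))
    return out if out.ndim else float(out)


def _effective_time(t, s: AllocationSchedule):
    t = np.asarray(t, dtype=float)
    return np.where(
        t < s.alpha,
        t,
        s.alpha + (1.0 - np.exp(-s.h * np.maximum(t - s.alpha, 0.0))) / s.h,
    )


def weight_at(t, gp: GrowthParams, s: AllocationSchedule):
    """Mass (g) at age ``t`` (y) under the closed-form trajectory.

    Equals the solution of ``dw/dt = u(t) * P(w)`` with ``w(0) = w0``; the two
    branches join with continuous value and derivative at ``t = alpha``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    c = 1.0 - gp.b
    out = (c * gp.k * _effective_time(t, s) + gp.w0**c) ** (1.0 / c)
    return out if out.ndim else float(out)


def fecundity_rate(t, gp: GrowthParams, s: AllocationSchedule):
    """Instantaneous reproductive output ``f(t) = (1 - u(t)) * P(w(t))`` (g y^-1).

    Zero up to and including maturity, then rises toward the asymptote
    ``k * w_inf**b``.
    """
    u = allocation_fraction(t, s)
    w = weight_at(t, gp, s)
    out = (1.0 - np.asarray(u)) * gp.k * np.asarray(w) ** gp.b
    return out if out.ndim else float(out)


def asymptotic_weight(gp: GrowthParams, s: AllocationSchedule) -> float:
    """Upper mass bound ``w_inf`` reached as ``t -> infinity``.

    From the closed form, effective growth time saturates at
    ``alpha + 1/h``, so
    ``w_inf = ((1-b)*k*(alpha + 1/h) + w0**(1-b)) ** (1/(1-b))``.
    Increasing in ``alpha`` (more juvenile growth), decreasing in ``h``
    (faster shutdown of post-maturity growth).
    """
    c = 1.0 - gp.b
    return float((c * gp.k * (s.alpha + 1.0 / s.h) + gp.w0**c) ** (1.0 / c))
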