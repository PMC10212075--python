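"""Warming projections by temperature-matched latitudes.

The projection logic: fit a smooth, monotone-decreasing profile of mean sea
surface temperature (SST) against absolute latitude; under a warming
scenario adding ``delta_T`` degrees at latitude ``L``, find the lower
latitude ``L'`` that *currently* experiences the projected temperature
(``SST(L') = SST(L) + delta_T``).  Assuming the fecundity-latitude
relationship tracks temperature, the future egg count of a fish at ``L`` is
the present-day prediction at ``L'``.  Near the equator the projected
temperature can exceed every present-day mean, in which case no matched
latitude exists and the change is undefined (reported as missing).

Scenario warming levels follow the IPCC mid- and late-century projections
for a low (RCP2.6) and high (RCP8.5) emissions pathway: +0.64, +0.73, +0.95
and +2.58 deg C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.optimize import brentq

from .calibrate import FecundityModelCoefs

__all__ = [
    "ClimateScenario",
    "SCENARIOS",
    "SSTProfileModel",
    "SSTProfile",
    "fit_sst_profile",
    "matched_latitude",
    "fecundity_change_grid",
]


@dataclass(frozen=True)
class ClimateScenario:
    """A labelled SST increase (deg C) relative to the present day."""

    label: str
    delta_T: float

    def __post_init__(self) -> None:
        if self.delta_T < 0:
            raise ValueError("delta_T must be >= 0")


SCENARIOS = {
    "RCP2.6-mid": ClimateScenario("RCP2.6-mid", 0.64),
    "RCP2.6-late": ClimateScenario("RCP2.6-late", 0.73),
    "RCP8.5-mid": ClimateScenario("RCP8.5-mid", 0.95),
    "RCP8.5-late": ClimateScenario("RCP8.5-late", 2.58),
}


class SSTProfile:
    """Fitted, monotone-decreasing SST-vs-latitude curve.

    Callable at any latitude within the fitted range.  ``grid`` and
    ``fitted`` store the monotone curve; ``rms_resid`` summarises the fit to
    the input points.
    """

    def __init__(self, grid: np.ndarray, fitted: np.ndarray, rms_resid: float) -> None:
        self.grid = grid
        self.fitted = fitted
        self.rms_resid = rms_resid
        self.lat_min = float(grid[0])
        self.lat_max = float(grid[-1])

    def __call__(self, lat):
        lat = np.abs(np.asarray(lat, dtype=float))
        if np.any((lat < self.lat_min - 1e-9) | (lat > self.lat_max + 1e-9)):
            raise ValueError(
                f"latitude outside the fitted range [{self.lat_min}, {self.lat_max}]"
            )
        out = np.interp(lat, self.grid, self.fitted)
        return out if out.ndim else float(out)

    @property
    def sst_max(self) -> float:
        return float(self.fitted[0])

    def summary(self) -> str:
        return (
            f"SST profile: {self.lat_min:.1f}-{self.lat_max:.1f} deg, "
            f"{self.fitted[0]:.2f} -> {self.fitted[-1]:.2f} C, "
            f"RMS residual {self.rms_resid:.3f} C"
        )


class SSTProfileModel:
    """Penalised-spline smooth of SST on absolute latitude.

    A smoothing spline is fitted to the points and then projected onto the
    monotone-decreasing cone (pool-adjacent-violators on a fine grid), which
    guarantees a unique inverse for latitude matching.  Requires at least 10
    points spanning at least 40 degrees.
    """

    def __init__(self, lats, ssts) -> None:
        lats = np.abs(np.asarray(lats, dtype=float))
        ssts = np.asarray(ssts, dtype=float)
        order = np.argsort(lats)
        self.lats, self.ssts = lats[order], ssts[order]
        if len(self.lats) < 10:
            raise ValueError("need at least 10 SST points")
        if np.ptp(self.lats) < 40:
            raise ValueError("SST points must span at least 40 degrees of latitude")

    def fit(self, smoothing: float | None = None, n_grid: int = 1501) -> SSTProfile:
        # collapse duplicate latitudes (spline requires strictly increasing x)
        df = pd.DataFrame({"lat": self.lats, "sst": self.ssts}).groupby("lat", as_index=False).mean()
        x, y = df["lat"].to_numpy(), df["sst"].to_numpy()
        if smoothing is None:
            smoothing = len(x) * 0.25  # mild penalty; profiles are very smooth
        k = min(3, len(x) - 1)
        spl = UnivariateSpline(x, y, k=k, s=smoothing)
        grid = np.linspace(x[0], x[-1], n_grid)
        fitted = spl(grid)
        fitted = self._decreasing_projection(fitted)
        lo, hi = self.ssts.min(), self.ssts.max()
        fitted = np.clip(fitted, lo, hi)
        rms = float(np.sqrt(np.mean((np.interp(self.lats, grid, fitted) - self.ssts) ** 2)))
        return SSTProfile(grid, fitted, rms)

    @staticmethod
    def _decreasing_projection(y: np.ndarray) -> np.ndarray:
        """Pool-adjacent-violators projection onto non-increasing sequences."""
        z = -y.copy()
        n = len(z)
        # blocks of (sum, count) merged until isotonic (non-decreasing in z)
        sums, counts = [], []
        for v in z:
            sums.append(v)
            counts.append(1)
            while len(sums) > 1 and sums[-2] / counts[-2] > sums[-1] / counts[-1]:
                s, c = sums.pop(), counts.pop()
                sums[-1] += s
                counts[-1] += c
        out = np.empty(n)
        i = 0
        for s, c in zip(sums, counts):
            out[i : i + c] = s / c
            i += c
        return -out


def fit_sst_profile(table: pd.DataFrame) -> SSTProfile:
    """Fit the monotone SST profile from a (lat, sst) table."""
    cols = {c.lower(): c for c in table.columns}
    lat_col = cols.get("lat") or cols.get("latitude") or cols.get("abs_lat")
    sst_col = cols.get("sst") or cols.get("temperature")
    if lat_col is None or sst_col is None:
        raise ValueError("SST table needs latitude and SST columns")
    return SSTProfileModel(table[lat_col], table[sst_col]).fit()


def matched_latitude(profile: SSTProfile, lat: float, delta_T: float) -> float:
    """Latitude currently experiencing ``SST(lat) + delta_T``.

    Root-bracketed inverse of the monotone fitted curve.  Returns ``nan``
    when the projected temperature exceeds the warmest present-day SST
    (unmatched low-latitude warming).  ``delta_T = 0`` returns ``lat``.
    """
    lat = abs(float(lat))
    if delta_T == 0.0:
        return lat
    target = profile(lat) + delta_T
    if target > profile.sst_max + 1e-12:
        return float("nan")
    g = lambda L: profile(L) - target  # noqa: E731
    if g(profile.lat_min) <= 0.0:
        return profile.lat_min
    return float(brentq(g, profile.lat_min, lat, xtol=1e-10))


def fecundity_change_grid(
    coefs: FecundityModelCoefs,
    profile: SSTProfile,
    scenario: ClimateScenario,
    masses=None,
    lats=None,
) -> pd.DataFrame:
    """Projected fecundity changes over a mass x latitude grid.

    For each (latitude, mass): present-day expected eggs, the matched-
    latitude projection under the scenario, their difference, and the
    percentage change in mass-specific fecundity (which equals the
    percentage change in eggs, as mass is held fixed).  Rows with no matched
    latitude carry missing projections.
    """
    if masses is None:
        masses = np.geomspace(10.0, 50_000.0, 60)
    if lats is None:
        lats = np.arange(
            max(0.0, profile.lat_min), min(75.0, profile.lat_max) + 1e-9, 0.5
        )
    rows = []
    for lat in np.atleast_1d(lats):
        lat = float(lat)
        lat_m = matched_latitude(profile, lat, scenario.delta_T)
        for mass in np.atleast_1d(masses):
            now = coefs.predict(mass, lat)
            if np.isnan(lat_m):
                fut = dif = pct = float("nan")
            else:
                fut = coefs.predict(mass, lat_m)
                dif = fut - now
                pct = 100.0 * (fut - now) / now
            rows.append(
                {
                    "latitude": lat,
                    "matched_latitude": lat_m,
                    "mass_g": float(mass),
                    "eggs_now": now,
                    "eggs_future": fut,
                    "delta_eggs": dif,
                    "delta_pct_mass_specific": pct,
                    "scenario": scenario.label,
                }
            )
    return pd.DataFrame(rows)
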