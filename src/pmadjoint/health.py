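"""GBD-style health impact of annual-mean PM2.5 exposure.

Attributable premature deaths per cell and cause follow the population
attributable fraction (PAF) form

    deaths[i, d] = P[i] * y0[country(i), d] / 1e5 * (RR_d(C[i]) - 1) / RR_d(C[i]),

with cause-specific relative-risk curves RR_d tabulated at exposure knots and
interpolated piecewise-linearly; below the theoretical minimum-risk exposure
level (TMREL) RR = 1, above the last knot RR is held flat.  The cost function
J of the adjoint is the sum of these deaths over the receptor region and the
six causes (COPD, IHD, LRI, LC, T2D, stroke).

A linearised response (``response="linear"``) replaces the PAF by a secant
slope through the origin, making J an exactly linear functional of exposure;
this is the response used in the pipeline's linear mode, where first-order
attribution is exact.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .grids import CountryMask, Field, GridError

CAUSES = ("COPD", "IHD", "LRI", "LC", "T2D", "stroke")
BOUNDS = ("low", "mid", "high")

DEFAULT_TMREL = 2.4  # µg/m^3


class HealthError(ValueError):
    pass


@dataclasses.dataclass
class RRCurveSet:
    """Tabulated relative-risk curves with low/mid/high bounds per cause.

    ``knots[cause]`` is an ascending exposure grid starting at the TMREL and
    ``rr[cause][bound]`` the RR values at those knots (RR at the TMREL is 1).
    """

    knots: dict[str, np.ndarray]
    rr: dict[str, dict[str, np.ndarray]]
    tmrel: float = DEFAULT_TMREL

    def __post_init__(self) -> None:
        for cause, k in self.knots.items():
            k = np.asarray(k, dtype=float)
            self.knots[cause] = k
            if k[0] != self.tmrel or np.any(np.diff(k) <= 0):
                raise HealthError(f"knots for {cause} must ascend from the TMREL")
            curves = self.rr[cause]
            for b in BOUNDS:
                r = np.asarray(curves[b], dtype=float)
                curves[b] = r
                if abs(r[0] - 1.0) > 1e-12:
                    raise HealthError(f"RR at the TMREL must be 1 ({cause}/{b})")
                if np.any(np.diff(r) < -1e-12):
                    raise HealthError(f"RR must be nondecreasing ({cause}/{b})")
            if (np.any(curves["low"] > curves["mid"] + 1e-12)
                    or np.any(curves["mid"] > curves["high"] + 1e-12)):
                raise HealthError(f"need low <= mid <= high pointwise ({cause})")

    def causes(self) -> tuple[str, ...]:
        return tuple(self.knots)


def relative_risk(curves: RRCurveSet, cause: str, conc: np.ndarray | float,
                  bound: str = "mid") -> np.ndarray:
    """Piecewise-linear RR at exposure ``conc`` (flat above the last knot,
    1 at or below the TMREL)."""
    if cause not in curves.knots:
        raise HealthError(f"unknown cause {cause!r}")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise HealthError("exposure must be >= 0")
    k = curves.knots[cause]
    r = curves.rr[cause][bound]
    return np.interp(c, k, r, left=1.0, right=float(r[-1]))


def rr_derivative(curves: RRCurveSet, cause: str, conc: np.ndarray,
                  bound: str = "mid") -> np.ndarray:
    """dRR/dC of the interpolated curve (0 below the TMREL / above the last knot)."""
    k = curves.knots[cause]
    r = curves.rr[cause][bound]
    slopes = np.diff(r) / np.diff(k)
    c = np.asarray(conc, dtype=float)
    seg = np.clip(np.searchsorted(k, c, side="right") - 1, 0, len(slopes) - 1)
    d = slopes[seg]
    d = np.where((c < k[0]) | (c >= k[-1]), 0.0, d)
    return d


@dataclasses.dataclass
class MortalityTable:
    """Baseline mortality rate y0 (deaths per 100,000/yr) per (country, cause)."""

    table: pd.DataFrame  # columns: country_id, cause, low, mid, high

    def __post_init__(self) -> None:
        t = self.table
        need = {"country_id", "cause", "low", "mid", "high"}
        if not need <= set(t.columns):
            raise HealthError(f"mortality table needs columns {sorted(need)}")
        bad = (t["low"] < 0) | (t["low"] > t["mid"]) | (t["mid"] > t["high"])
        if bad.any():
            raise HealthError("mortality bounds must satisfy 0 <= low <= mid <= high")
        self._lut = {b: {} for b in BOUNDS}
        for _, row in t.iterrows():
            for b in BOUNDS:
                self._lut[b][(int(row["country_id"]), row["cause"])] = float(row[b])

    def rate(self, country_id: int, cause: str, bound: str = "mid") -> float:
        try:
            return self._lut[bound][(country_id, cause)]
        except KeyError:
            raise HealthError(f"no mortality rate for country {country_id}, cause {cause}")

    def rate_field(self, mask: CountryMask, cause: str, bound: str = "mid",
                   unassigned_rate: float = 0.0) -> np.ndarray:
        """Per-cell y0 for a cause, using the country of each cell."""
        out = np.full(mask.grid.shape, unassigned_rate, dtype=float)
        for cid in mask.country_ids:
            out[mask.ids == cid] = self.rate(int(cid), cause, bound)
        return out


@dataclasses.dataclass
class HealthInputs:
    """Everything the cost function needs: P, y0, RR curves, countries."""

    population: Field                       # persons per fine cell (mid estimate)
    mortality: MortalityTable
    curves: RRCurveSet
    mask: CountryMask
    population_bound_factors: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"low": 1.0, "mid": 1.0, "high": 1.0})
    unassigned_mortality: float = 0.0       # y0 used for id-0 cells (0 = no deaths)

    def __post_init__(self) -> None:
        if np.any(self.population.values < 0):
            raise HealthError("population must be >= 0")
        if not self.population.grid.equals(self.mask.grid):
            raise GridError("population and mask must share a grid")

    def population_at(self, bound: str) -> np.ndarray:
        return self.population.values * self.population_bound_factors[bound]


@dataclasses.dataclass
class CostFunctionResult:
    """Total deaths J over the receptor region plus per-cell/per-cause detail."""

    J: float
    per_cell: np.ndarray                # (nlat, nlon) deaths, receptor cells only
    per_cause: dict[str, float]
    bound: str = "mid"

    def cause_shares(self) -> dict[str, float]:
        tot = sum(self.per_cause.values())
        if tot == 0:
            return {c: 0.0 for c in self.per_cause}
        return {c: v / tot for c, v in self.per_cause.items()}


def paf_slopes(curves: RRCurveSet, reference_exposure: float = 25.0,
               bound: str = "mid") -> dict[str, float]:
    """Secant PAF slope per cause: PAF(C_ref)/C_ref, units 1/(µg m^-3).

    Used by the linear response mode, where deaths = P * y0/1e5 * slope * C.
    """
    out = {}
    for cause in curves.causes():
        rr = float(relative_risk(curves, cause, reference_exposure, bound))
        out[cause] = (1.0 - 1.0 / rr) / reference_exposure
    return out


def attributable_deaths(exposure_annual: np.ndarray, health: HealthInputs,
                        bound: str = "mid", response: str = "paf",
                        slopes: Mapping[str, float] | None = None) -> dict[str, np.ndarray]:
    """Per-cell attributable deaths per cause over the whole grid."""
    pop = health.population_at(bound)
    conc = np.asarray(exposure_annual, dtype=float)
    if conc.shape != pop.shape:
        raise GridError("exposure and population shapes differ")
    out: dict[str, np.ndarray] = {}
    for cause in health.curves.causes():
        y0 = health.mortality.rate_field(health.mask, cause, bound,
                                         health.unassigned_mortality)
        base = pop * y0 / 1e5
        if response == "paf":
            rr = relative_risk(health.curves, cause, conc, bound)
            out[cause] = base * (rr - 1.0) / rr
        elif response == "linear":
            s = (slopes or paf_slopes(health.curves, bound=bound))[cause]
            out[cause] = base * s * conc
        else:
            raise HealthError(f"unknown response {response!r}")
    return out


def cost_function(exposure_annual: np.ndarray, health: HealthInputs,
                  bound: str = "mid", response: str = "paf",
                  slopes: Mapping[str, float] | None = None) -> CostFunctionResult:
    """J = attributable deaths summed over receptor-flagged cells and causes."""
    receptor = health.mask.receptor_mask()
    if not receptor.any():
        raise HealthError("empty receptor region")
    fields = attributable_deaths(exposure_annual, health, bound, response, slopes)
    per_cell = np.zeros(health.mask.grid.shape)
    per_cause: dict[str, float] = {}
    for cause, f in fields.items():
        masked = np.where(receptor, f, 0.0)
        per_cell += masked
        per_cause[cause] = float(masked.sum())
    return CostFunctionResult(J=float(per_cell.sum()), per_cell=per_cell,
                              per_cause=per_cause, bound=bound)


def cost_gradient(exposure_annual: np.ndarray, health: HealthInputs,
                  bound: str = "mid", response: str = "paf",
                  slopes: Mapping[str, float] | None = None) -> np.ndarray:
    """dJ/dC per fine cell (deaths per µg m^-3), zero outside the receptor."""
    receptor = health.mask.receptor_mask()
    pop = health.population_at(bound)
    conc = np.asarray(exposure_annual, dtype=float)
    g = np.zeros(health.mask.grid.shape)
    for cause in health.curves.causes():
        y0 = health.mortality.rate_field(health.mask, cause, bound,
                                         health.unassigned_mortality)
        base = pop * y0 / 1e5
        if response == "paf":
            rr = relative_risk(health.curves, cause, conc, bound)
            drr = rr_derivative(health.curves, cause, conc, bound)
            g += base * drr / rr**2
        elif response == "linear":
            s = (slopes or paf_slopes(health.curves, bound=bound))[cause]
            g += base * s
        else:
            raise HealthError(f"unknown response {response!r}")
    return np.where(receptor, g, 0.0)


def uncertainty_bounds(exposure_annual: np.ndarray, health: HealthInputs,
                       response: str = "paf",
                       slopes: Mapping[str, float] | None = None) -> dict[str, float]:
    """J with population, mortality and RR all at their low / mid / high values.

    Returns the three totals plus the low/mid and high/mid ratios (fractions).
    """
    out: dict[str, float] = {}
    for b in BOUNDS:
        out[f"J_{b}"] = cost_function(exposure_annual, health, b, response, slopes).J
    out["low_over_mid"] = out["J_low"] / out["J_mid"] if out["J_mid"] else np.nan
    out["high_over_mid"] = out["J_high"] / out["J_mid"] if out["J_mid"] else np.nan
    return out
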