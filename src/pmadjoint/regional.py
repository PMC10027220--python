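"""Extra-regional contributions, the natural/residual split, and
contribution-ratio redistribution maps.

The extra-regional contribution is estimated by a boundary-inflow perturbation
experiment: all edge inflow concentrations are reduced by 20% (BC-20) with
the satellite correction frozen at its BASE values, and the per-cell death
difference is multiplied by five — a first-order extrapolation that is exact
when the death response is linear in the boundary inflow.  The contribution
ratio (CR) of a cell or country divides the deaths its emissions cause
anywhere by the deaths occurring in it; CR > 1 marks net exporters of health
damage, small within-region CR marks over-burdened receptor regions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grids import CountryMask, GridError
from .health import CostFunctionResult

BC_PERTURBATION_SCALE = 5.0          # inverse of the 20% boundary reduction
CR_OVER_CONTRIBUTING = 1.0
CR_STRONG_EXPORTER = 3.0
CR_OVER_BURDENED = 0.42


class RegionalError(ValueError):
    pass


@dataclasses.dataclass
class RegionalSplit:
    """Decomposition of total deaths into extra-regional, domestic
    anthropogenic, and the natural/inherited residual."""

    J_total: float
    J_extra: float
    J_anthro: float

    def __post_init__(self) -> None:
        if self.J_extra + self.J_anthro > self.J_total * (1.0 + 1e-6):
            raise RegionalError(
                "extra-regional + anthropogenic contributions exceed the total")

    @property
    def J_residual(self) -> float:
        return self.J_total - self.J_extra - self.J_anthro

    @property
    def within_domain(self) -> float:
        return self.J_total - self.J_extra

    def shares_of_total(self) -> dict[str, float]:
        t = self.J_total
        return {"extra_regional": self.J_extra / t,
                "anthropogenic": self.J_anthro / t,
                "residual": self.J_residual / t}

    def shares_of_within_domain(self) -> dict[str, float]:
        w = self.within_domain
        return {"anthropogenic": self.J_anthro / w, "residual": self.J_residual / w}


def extra_regional_contribution(J_base: CostFunctionResult,
                                J_bc20: CostFunctionResult,
                                linear_mode: bool = False) -> tuple[float, np.ndarray]:
    """J_extra = 5 x (J_base - J_bc20), per cell and in total.

    Both runs must share the frozen BASE satellite correction.  In linear mode
    a BC-20 total above the base total signals a broken run and is rejected.
    """
    diff_total = J_base.J - J_bc20.J
    if linear_mode and diff_total < -1e-9 * max(abs(J_base.J), 1.0):
        raise RegionalError("BC-20 deaths exceed the base run in linear mode")
    per_cell = BC_PERTURBATION_SCALE * (J_base.per_cell - J_bc20.per_cell)
    return BC_PERTURBATION_SCALE * diff_total, per_cell


def residual_split(J_total: float, J_extra: float, J_anthro: float) -> RegionalSplit:
    """Residual = total - extra-regional - domestic anthropogenic (must be
    nonnegative within 1e-6 relative)."""
    return RegionalSplit(J_total=float(J_total), J_extra=float(J_extra),
                         J_anthro=float(J_anthro))


@dataclasses.dataclass
class ContributionRatioMap:
    """Per-cell CR = deaths caused anywhere / deaths incurred locally."""

    cr: np.ndarray                       # +inf where incurred = 0 with caused > 0
    defined: np.ndarray                  # False where incurred = 0
    variant: str
    country_table: pd.DataFrame


def contribution_ratio(caused: np.ndarray, incurred: np.ndarray,
                       mask: CountryMask, variant: str = "vs_total") -> ContributionRatioMap:
    """CR map plus country-level CRs and threshold classifications.

    ``caused`` is the ledger's per-source-cell marginal (deaths the cell's
    emissions cause anywhere); ``incurred`` the per-cell attributable deaths
    (for the ``within_region`` variant, with the extra-regional per-cell
    deaths already subtracted).  Cells with zero incurred deaths are masked
    (+inf sentinel where caused > 0).
    """
    if variant not in ("vs_total", "within_region"):
        raise RegionalError(f"unknown CR variant {variant!r}")
    caused = np.asarray(caused, dtype=float)
    incurred = np.asarray(incurred, dtype=float)
    if caused.shape != incurred.shape or caused.shape != mask.grid.shape:
        raise GridError("caused/incurred shapes must match the mask grid")
    if np.any(caused < 0) or np.any(incurred < -1e-9):
        raise RegionalError("caused/incurred deaths must be nonnegative")
    defined = incurred > 0
    cr = np.full(caused.shape, np.nan)
    np.divide(caused, incurred, out=cr, where=defined)
    cr[~defined & (caused > 0)] = np.inf
    rows = []
    ids = mask.ids
    for cid in mask.country_ids:
        sel = ids == cid
        c_sum = float(caused[sel].sum())
        i_sum = float(incurred[sel].sum())
        country_cr = c_sum / i_sum if i_sum > 0 else np.inf
        rows.append({
            "country_id": int(cid), "country": mask.name_of(int(cid)),
            "caused": c_sum, "incurred": i_sum, "cr": country_cr,
            "over_contributing": country_cr > CR_OVER_CONTRIBUTING,
            "strong_exporter": country_cr > CR_STRONG_EXPORTER,
            "over_burdened": (variant == "within_region"
                              and country_cr < CR_OVER_BURDENED),
        })
    table = pd.DataFrame(rows).sort_values("cr", ascending=False).reset_index(drop=True)
    return ContributionRatioMap(cr=cr, defined=defined, variant=variant,
                                country_table=table)
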