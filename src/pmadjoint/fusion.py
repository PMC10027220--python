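"""Satellite fusion: bias-rescaling of modelled PM2.5 and fine-grid downscaling.

The coarse model field is corrected per cell by the ratio of the (coarse-
aggregated) satellite annual mean to the model annual mean, with the ratio
clamped to [0.25, 4] to keep the correction bounded; the corrected field is
then distributed onto the fine grid using the satellite annual field as the
spatial pattern, conserving the per-parent area-weighted mean.  When the
pipeline evaluates perturbed runs (gradient checks, boundary perturbations,
counterfactuals) the BASE-run ratios are reused unchanged (``frozen``
rescaling), because re-deriving them would cancel the very signal the
perturbation is meant to produce.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .grids import (Field, GridError, GridSpec, aggregate_fine_to_coarse,
                    disaggregate_coarse_to_fine, downscale_weights)

RATIO_CLAMP = (0.25, 4.0)


@dataclasses.dataclass
class ExposureField:
    """Fine-grid PM2.5 exposure: monthly (12, nlat, nlon) and annual mean."""

    grid: GridSpec
    monthly: np.ndarray
    annual: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if np.any(self.monthly < -1e-12) or np.any(self.annual < -1e-12):
            raise GridError("exposure must be nonnegative")
        if not np.allclose(self.annual, self.monthly.mean(axis=0), rtol=1e-9, atol=1e-12):
            raise GridError("annual exposure must equal the mean of the months")


def rescale_ratios(model_monthly: Field, satellite_fine: Field) -> np.ndarray:
    """Per-coarse-cell correction ratio (satellite annual / model annual),
    clamped to [0.25, 4]; NaN marks cells with zero model annual mean."""
    if np.any(satellite_fine.values < 0):
        raise GridError("satellite field must be >= 0")
    sat_coarse = aggregate_fine_to_coarse(satellite_fine, model_monthly.grid).values
    model_annual = model_monthly.values.mean(axis=0)
    ratio = np.full(model_annual.shape, np.nan)
    ok = model_annual > 0
    np.divide(sat_coarse, model_annual, out=ratio, where=ok)
    ratio[ok] = np.clip(ratio[ok], *RATIO_CLAMP)
    return ratio


def rescale_to_satellite(model_monthly: Field, satellite_fine: Field,
                         ratios: np.ndarray | None = None) -> tuple[Field, np.ndarray]:
    """Correct the coarse monthly model field with the satellite annual field.

    Every month of a coarse cell is multiplied by its clamped annual ratio;
    cells where the model annual mean is zero get the satellite annual value
    spread uniformly across months.  Pass precomputed ``ratios`` to apply a
    frozen BASE correction.  Returns ``(corrected, ratios)``.
    """
    if not satellite_fine.values.any():
        warnings.warn("satellite field is all zero; rescaling is the identity")
        return model_monthly.copy(), np.ones(model_monthly.grid.shape)
    if ratios is None:
        ratios = rescale_ratios(model_monthly, satellite_fine)
    sat_coarse = aggregate_fine_to_coarse(satellite_fine, model_monthly.grid).values
    out = model_monthly.values.copy()
    ok = np.isfinite(ratios)
    out[:, ok] *= ratios[ok]
    out[:, ~ok] = sat_coarse[~ok]        # annual mean then equals the satellite
    return Field(model_monthly.grid, out, model_monthly.units, "pm25_rescaled"), ratios


def downscale_exposure(corrected_coarse: Field, satellite_fine: Field) -> ExposureField:
    """Distribute the corrected coarse monthly field onto the fine grid using
    the satellite annual field as the within-parent pattern."""
    fine = satellite_fine.grid
    pattern = Field(fine, satellite_fine.values, satellite_fine.units, "pattern")
    monthly = disaggregate_coarse_to_fine(corrected_coarse, fine, pattern).values
    return ExposureField(fine, monthly, monthly.mean(axis=0), provenance="downscaled")


def fuse_exposure(model_monthly: Field, satellite_fine: Field,
                  ratios: np.ndarray | None = None) -> tuple[ExposureField, np.ndarray, np.ndarray]:
    """Rescale + downscale in one step.

    Returns ``(exposure, ratios, weights)`` where ``weights`` are the fine
    multiplicative downscaling weights (area-weighted mean 1 per parent), as
    needed by the adjoint chain.
    """
    corrected, ratios = rescale_to_satellite(model_monthly, satellite_fine, ratios)
    exposure = downscale_exposure(corrected, satellite_fine)
    weights = downscale_weights(satellite_fine, model_monthly.grid)
    return exposure, ratios, weights


def population_weighted_mean(conc: np.ndarray, pop: np.ndarray,
                             cells: np.ndarray | None = None) -> float:
    """Sum(C * P) / Sum(P) over the (optionally masked) cells."""
    conc = np.asarray(conc, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if conc.shape != pop.shape:
        raise GridError("concentration and population shapes differ")
    if cells is not None:
        conc, pop = conc[cells], pop[cells]
    total = pop.sum()
    if total <= 0:
        raise GridError("population-weighted mean needs positive total population")
    return float((conc * pop).sum() / total)
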