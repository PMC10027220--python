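"""Adjoint sensitivities of the mortality cost function to emissions.

The forward chain is

    E (kg, fine) --sum--> E (coarse) --CTM steady states--> tracers (12 months)
      --chemistry--> PM2.5 components --sum--> PM2.5 --annual mean-->
      --frozen satellite rescale--> --satellite downscale (fine)-->
      --health response--> J (premature deaths over the receptor region).

Every step except the pointwise chemistry coupling and the health response is
a linear operator assembled as an explicit matrix or a known weighting, so the
adjoint is the exact transpose of the discretisation: one reverse sweep per
month (months are independent steady states) yields dJ/dE for every (species,
month, cell) at once, in deaths per kg emitted.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .grids import GridSpec


@dataclasses.dataclass
class SensitivityField:
    """lambda_E = dJ/dE per (species, month, cell), deaths per kg emitted."""

    grid: GridSpec
    values: dict[str, np.ndarray]          # species -> (12, nlat, nlon)
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, arr in self.values.items():
            if arr.shape != (12,) + self.grid.shape:
                raise ValueError(f"sensitivity for {sp!r} has shape {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite sensitivities for {sp!r}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.values)

    def to_fine(self, fine: GridSpec) -> "SensitivityField":
        """Replicate to a nested fine grid.

        Sensitivity is intensive in the emitted mass (deaths per kg anywhere in
        the coarse cell), so children copy their parent exactly.
        """
        rlat, rlon = self.grid.refinement_from(fine)
        vals = {
            sp: np.repeat(np.repeat(arr, rlat, axis=1), rlon, axis=2)
            for sp, arr in self.values.items()
        }
        return SensitivityField(fine, vals, dict(self.meta))


def monthly_exposure_chain(dj_dc_annual: np.ndarray) -> np.ndarray:
    """Chain rule through the annual mean: dJ/dC_month = dJ/dC_annual / 12 for
    every month.  Returns an array with a leading month axis of length 12."""
    g = np.asarray(dj_dc_annual, dtype=float)
    return np.broadcast_to(g / 12.0, (12,) + g.shape).copy()


def run_adjoint(world, params=None, health=None, **pipeline_kwargs) -> SensitivityField:
    """One-call adjoint sweep for a synthetic world (see Pipeline.adjoint)."""
    from .pipeline import Pipeline
    pipe = Pipeline(world, params=params, health=health, **pipeline_kwargs)
    return pipe.adjoint()


def gradient_check(world, params=None, health=None, n_samples: int = 30,
                   rel_step: float = 0.005, seed: int = 0, **pipeline_kwargs) -> dict:
    """Compare adjoint sensitivities with central finite differences of J
    (see Pipeline.gradient_check)."""
    from .pipeline import Pipeline
    pipe = Pipeline(world, params=params, health=health, **pipeline_kwargs)
    return pipe.gradient_check(n_samples=n_samples, rel_step=rel_step, seed=seed)
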