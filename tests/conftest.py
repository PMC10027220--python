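import numpy as np
import pytest

from pmadjoint import Pipeline, WorldConfig, generate_world
from pmadjoint.attribution import compute_contributions


def tiny_config(seed: int = 11, **overrides) -> WorldConfig:
    """A small, fast world: 10x12 coarse cells, 2x refinement, 4 countries."""
    kw = dict(seed=seed, coarse_nlat=10, coarse_nlon=12, refinement=2,
              n_countries=4, n_cities=8, ocean_lon_max=-12.0)
    kw.update(overrides)
    return WorldConfig(**kw)


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(tiny_config())


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_world):
    """Nonlinear chemistry + PAF response on the tiny world."""
    pipe = Pipeline(tiny_world)
    pipe.base()
    return pipe


@pytest.fixture(scope="session")
def tiny_linear_pipeline(tiny_world):
    """Linear chemistry + linear response, zero boundary inflow: the
    configuration in which first-order attribution is exact."""
    pipe = Pipeline.linear(tiny_world, boundary_scale=0.0)
    pipe.base()
    return pipe


@pytest.fixture(scope="session")
def tiny_ledger(tiny_world, tiny_linear_pipeline):
    lam_fine = tiny_linear_pipeline.adjoint_fine()
    return compute_contributions(lam_fine, tiny_world.emissions["2015"])


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
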