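import numpy as np
import pandas as pd
import pytest

from magrheo import heterogeneity as het
from magrheo import synthetic
from magrheo.types import DriveConfig, FluidProperties, MCMCConfig

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def drive() -> DriveConfig:
    return DriveConfig()


@pytest.fixture
def silicone_oil() -> FluidProperties:
    return FluidProperties(dynamic_viscosity_pa_s=30.0)


@pytest.fixture
def short_mcmc() -> MCMCConfig:
    """Chain lengths for small unit-test posteriors."""
    return MCMCConfig(warmup=1500, draws=1500, thin=3, seed=42)


@pytest.fixture
def small_hier_data() -> het.NormalizedData:
    """One-matrix dataset at a reduced design: 2 samples x 2 holders x 4 spheres."""
    truth = synthetic.default_truth(matrices=("a",), seed=0)
    design = synthetic.Design(n_samples=2, n_holders=2, n_locations=2,
                              n_spheres_per_location=2, n_repeats=2)
    obs = synthetic.gen_hierarchical_observations(design, truth, seed=123)
    return het.normalize(obs, "abs_shear_modulus")


@pytest.fixture
def two_matrix_obs() -> pd.DataFrame:
    truth = synthetic.default_truth(matrices=("a", "b"), seed=0)
    design = synthetic.Design(n_samples=2, n_holders=2, n_locations=2,
                              n_spheres_per_location=1, n_repeats=2)
    return synthetic.gen_hierarchical_observations(design, truth, seed=7)
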