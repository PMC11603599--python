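import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from osmocal.potentials import PairPotentialModel
from osmocal.synthetic import SyntheticRdfSpec, gen_analytic_rdf
from osmocal.units import DEFAULT_BETA


@pytest.fixture(scope="session")
def hard_sphere_2nm() -> PairPotentialModel:
    return PairPotentialModel("hard_sphere", sigma=2.0)


@pytest.fixture(scope="session")
def square_well_unit() -> PairPotentialModel:
    """Square well with beta*epsilon = 1, sigma = 1 nm, range 1.5 sigma."""
    return PairPotentialModel(
        "square_well", sigma=1.0, epsilon=1.0 / DEFAULT_BETA, well_range=1.5
    )


@pytest.fixture(scope="session")
def fine_hs_rdf(hard_sphere_2nm):
    """Noiseless hard-sphere RDF on a 0.01 nm grid out to 10 nm."""
    return gen_analytic_rdf(
        SyntheticRdfSpec(
            potential=hard_sphere_2nm, baseline=1.0, bin_width=0.01, r_max=10.0
        )
    )


@pytest.fixture(scope="session")
def fine_hs_rdf_offset(hard_sphere_2nm):
    """Same hard-sphere RDF with the plateau shifted to 1.02."""
    return gen_analytic_rdf(
        SyntheticRdfSpec(
            potential=hard_sphere_2nm, baseline=1.02, bin_width=0.01, r_max=10.0
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
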