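import numpy as np
import pytest

import lpfsbench as lb


@pytest.fixture(scope="session")
def ref_items():
    return lb.reference_items()


@pytest.fixture(scope="session")
def cohort_1000():
    """Seeded cohort at the generator's default calibration, n = 1000."""
    spec = lb.SimulationSpec(n=1000, seed=3)
    responses, theta = lb.simulate_responses(spec)
    return responses, theta


@pytest.fixture(scope="session")
def poly_1000(cohort_1000):
    responses, _ = cohort_1000
    return lb.polychoric_matrix(responses)


@pytest.fixture(scope="session")
def resp_2000():
    spec = lb.SimulationSpec(n=2000, seed=7)
    responses, theta = lb.simulate_responses(spec)
    return responses, theta


@pytest.fixture(scope="session")
def grm_fit_2000(resp_2000):
    responses, _ = resp_2000
    return lb.fit_grm(responses)


@pytest.fixture(scope="session")
def gpcm_fit_2000(resp_2000):
    responses, _ = resp_2000
    return lb.fit_gpcm(responses)


@pytest.fixture(scope="session")
def ref_benchmarks(ref_items):
    return lb.derive_benchmarks(ref_items)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
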