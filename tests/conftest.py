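import numpy as np
import pytest

import chemosched as cs

#: Short-horizon optimization scenario: the optimal-dosing figures correspond
#: to the high-chemosensitivity setting (cells 0.6, vasculature 0.2); under
#: the lower nominal sensitivities the 14-day optimum degenerates to full dose.
HIGH_SENS = dict(beta1=0.6, beta=0.2)


@pytest.fixture(scope="session")
def params():
    return cs.NOMINAL_PARAMS


@pytest.fixture(scope="session")
def highsens_params():
    return cs.NOMINAL_PARAMS.replace(**HIGH_SENS)


@pytest.fixture(scope="session")
def initial():
    return cs.NOMINAL_INITIAL


@pytest.fixture(scope="session")
def weights():
    return cs.ObjectiveWeights()


@pytest.fixture(scope="session")
def ocp_solution_v05(highsens_params, initial, weights):
    """Solved 14-day schedule at half anti-angiogenic dose (shared, expensive)."""
    problem = cs.transcribe(highsens_params, initial, weights, 0.5)
    return cs.solve_ocp(problem)


@pytest.fixture(scope="session")
def ocp_solution_v1(highsens_params, initial, weights):
    problem = cs.transcribe(highsens_params, initial, weights, 1.0)
    return cs.solve_ocp(problem)


@pytest.fixture()
def rng():
    return np.random.default_rng(20211207)
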