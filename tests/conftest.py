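import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from optoferm import (
    Condition,
    KineticParams,
    StateVector,
    make_truth_surface,
)


@pytest.fixture(scope="session")
def params():
    """A plausible baseline parameter set for unit checks."""
    return KineticParams(mu_max=0.3, k_g=0.5, alpha=2e4, beta=0.05, d_p=0.02, y_gb=0.55)


@pytest.fixture(scope="session")
def batch_start():
    """Characterization batch initial state: OD 0.1, no protein, 1% glucose."""
    return StateVector(c_b=0.1, c_p=0.0, c_g=10.0, n=1)


@pytest.fixture(scope="session")
def truth_surface():
    return make_truth_surface()


@pytest.fixture(scope="session")
def design_grid():
    return {"intensities": (0.0, 5.0, 10.0, 30.0, 50.0, 70.0), "copies": (1, 3, 8)}


@pytest.fixture(scope="session")
def truth_surrogate(truth_surface, design_grid):
    """Six GPs trained directly on the truth-surface parameter values over
    the characterization design — an idealized (calibration-error-free)
    surrogate used to test the GP/prediction stages in isolation."""
    from optoferm.calibration import GPTrainingSet
    from optoferm.gp import ParameterSurrogate
    from optoferm.model import PARAM_NAMES

    conds = [
        Condition(I, n)
        for n in design_grid["copies"]
        for I in design_grid["intensities"]
    ]
    V = np.array([[c.light_intensity for c in conds],
                  [c.copy_number for c in conds]], dtype=float)
    sets = {}
    for name in PARAM_NAMES:
        L = np.array([getattr(truth_surface.params_at(c), name) for c in conds])
        sets[name] = GPTrainingSet(V=V, L=L, parameter=name)
    return ParameterSurrogate.train(sets, restarts=4, seed=0)
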