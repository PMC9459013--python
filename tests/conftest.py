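import numpy as np
import pytest

from stenoflow.geometry import StenosisShape, solve_stenosis_polynomial
from stenoflow.lbm import build_lattice


@pytest.fixture(scope="session")
def lattice2d():
    return build_lattice(2)


@pytest.fixture(scope="session")
def lattice3d():
    return build_lattice(3)


@pytest.fixture(scope="session")
def flat_shape():
    return StenosisShape(D=1.0, coefficients=np.array([0, 0, 0, 0, 0, 1.0]))


@pytest.fixture(scope="session")
def half_depth_shape():
    return solve_stenosis_polynomial(1.0, 0.5, 0.5)


@pytest.fixture(scope="session")
def study2d():
    """Shared reduced 2D chain: 12 simulated stenoses + trained encoder."""
    from stenoflow.study import prepare_2d_study

    return prepare_2d_study(seed=1, n_shapes=12, n_validation=2)


@pytest.fixture(scope="session")
def surrogate_cnn(study2d):
    from stenoflow.study import evaluate_surrogate

    return evaluate_surrogate(study2d, "cnn")


@pytest.fixture(scope="session")
def surrogate_poly(study2d):
    from stenoflow.study import evaluate_surrogate

    return evaluate_surrogate(study2d, "poly")
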