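import numpy as np
import pytest

from vawmi import CovariateSpec, Covariate, MimicParameters, generate_survey
from vawmi.presets import measurement_preset, study_preset


@pytest.fixture(scope="session")
def study_params():
    return study_preset()


@pytest.fixture(scope="session")
def measurement_params():
    return measurement_preset()


@pytest.fixture(scope="session")
def small_survey(study_params):
    """A modest study-shaped survey shared across read-only tests."""
    return generate_survey(study_params, 800, seed=1234)


@pytest.fixture
def tiny_spec():
    """A two-covariate spec for fast targeted tests."""
    return CovariateSpec(
        [
            Covariate("site", ("a", "b"), (0.6, 0.4), "a"),
            Covariate("group", ("x", "y", "z"), (0.5, 0.3, 0.2), "x"),
        ]
    )


def make_params(spec, *, Lambda=None, B=None, A=None, nu=None, Psi=None):
    """Convenience constructor with zero defaults."""
    p = spec.n_dummies
    return MimicParameters(
        nu=np.zeros(15) if nu is None else nu,
        Lambda=np.zeros((15, 3)) if Lambda is None else Lambda,
        A=np.zeros((15, p)) if A is None else A,
        B=np.zeros((3, p)) if B is None else B,
        Psi=np.eye(3) if Psi is None else Psi,
        covariate_spec=spec,
    )
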