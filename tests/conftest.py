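import numpy as np
import pytest

import trunkreach as tr


@pytest.fixture(scope="session")
def body() -> tr.BodyModel:
    """The default 1.78 m / 80 kg body model."""
    return tr.build_body_model(1.78, 80.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def result_g1() -> tr.ExperimentResult:
    """Reference execution (veridical perception) for the default CCW condition."""
    return tr.run_condition(tr.Condition(direction=tr.CCW, G=1.0))


@pytest.fixture(scope="session")
def result_ccw15(result_g1) -> tr.ExperimentResult:
    """Default CCW condition at the largest underestimation (G=1.5, 33%)."""
    return tr.run_condition(
        tr.Condition(direction=tr.CCW, G=1.5), reference=result_g1
    )


@pytest.fixture(scope="session")
def result_cw15() -> tr.ExperimentResult:
    """Default CW condition at G=1.5."""
    return tr.run_condition(tr.Condition(direction=tr.CW, G=1.5))
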