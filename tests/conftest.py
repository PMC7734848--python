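import numpy as np
import pytest

from ms_essn import rrms
from ms_essn.essn import ESSNModel, Marking, Place, Transition, compile_net


@pytest.fixture(scope="session")
def death_model():
    """Pure linear death: X -> (nothing) at rate 1 per token."""
    return ESSNModel(
        "death",
        places=[Place("X")],
        transitions=[Transition("die", "mass_action", [("X", 1)], [], 1.0)],
    )


@pytest.fixture(scope="session")
def imdeath_model():
    """Immigration-death: constant influx 10/day, per-capita death 1/day."""
    return ESSNModel(
        "imdeath",
        places=[Place("X")],
        transitions=[
            Transition("arrive", "mass_action", [], [("X", 1)], 10.0),
            Transition("leave", "mass_action", [("X", 1)], [], 1.0),
        ],
    )


@pytest.fixture(scope="session")
def toggle_model():
    """Two-state toggle A <-> B with unit rates."""
    return ESSNModel(
        "toggle",
        places=[Place("A"), Place("B")],
        transitions=[
            Transition("ab", "mass_action", [("A", 1)], [("B", 1)], 1.0),
            Transition("ba", "mass_action", [("B", 1)], [("A", 1)], 1.0),
        ],
    )


@pytest.fixture(scope="session")
def rrms_model():
    return rrms.build_rrms()


@pytest.fixture(scope="session")
def rrms_net(rrms_model):
    return compile_net(rrms_model)


@pytest.fixture(scope="session")
def marking0():
    return rrms.default_initial_marking()


@pytest.fixture(scope="session")
def reference_fit():
    """Packaged calibrated parameter sets (HD and MS configurations)."""
    import json
    from importlib import resources

    from ms_essn.calibration import FitResult

    path = resources.files("ms_essn.data").joinpath("reference_fit.json")
    return FitResult.from_dict(json.loads(path.read_text()))


def pytest_configure(config):
    np.seterr(all="ignore")
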