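import numpy as np
import pytest

from fmisopk import (
    InputFunctionSpec,
    default_schedule,
    make_input_function,
    preset_params,
)


@pytest.fixture(scope="session")
def schedule():
    """Conventional 2 h, 52-frame acquisition timeline."""
    return default_schedule()


@pytest.fixture(scope="session")
def cp():
    """Default synthetic bolus input function (1 s sampling, 2 h)."""
    return make_input_function(InputFunctionSpec())


@pytest.fixture(scope="session")
def mda_params():
    """Intrinsically hypoxic xenograft preset, 1 h post therapy."""
    return preset_params("MDA-1h")


@pytest.fixture(scope="session")
def u87_params():
    """High-vascularity xenograft preset, 1 h post therapy."""
    return preset_params("U87MG-1h")
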