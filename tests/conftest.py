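import numpy as np
import pytest

import pushpull as pp


@pytest.fixture(scope="session")
def example1():
    """Bromide tracer + reacting ethanol (kr=-0.2/h), equal ratios (100/100)."""
    return pp.generate_example(1)


@pytest.fixture(scope="session")
def example2():
    """As example 1 but ethanol does not react."""
    return pp.generate_example(2)


@pytest.fixture(scope="session")
def example3():
    """No reaction but unequal ratios (100 vs 10): the conventional method's
    documented failure mode."""
    return pp.generate_example(3)


@pytest.fixture(scope="session")
def field_design():
    return pp.generate_field_design()


@pytest.fixture
def flat_adjusted():
    """A constant adjusted curve at the injected concentration."""
    t = np.linspace(0.0, 10.0, 11)
    return pp.AdjustedSeries(
        solute="tracer",
        method="conventional",
        time=t,
        adjusted=np.full(t.size, 50.0),
        c_injection=50.0,
        c_aquifer=0.5,
    )
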