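import numpy as np
import pytest

from ricephys import FvCBParams, KineticConstants, LightResponseParams, RichardsParams


@pytest.fixture
def milk_stage_light_params():
    """Early-milk-stage flag-leaf light-response parameters (test cultivar)."""
    return LightResponseParams(pn_max=46.03, aqy=0.09, theta=0.8, rd=2.0)


@pytest.fixture
def milk_stage_fvcb_params():
    """Milk-stage flag-leaf FvCB capacities (test cultivar)."""
    return FvCBParams(vcmax=105.91, jmax=191.66, rd=1.5)


@pytest.fixture
def kinetics():
    return KineticConstants()


@pytest.fixture
def grain_params():
    """A realistic middle-grain filling trajectory (final weight near the
    27 mg single-grain scale of a 27 g thousand-grain weight)."""
    return RichardsParams(a=27.0, b=25.0, k=0.25, n=1.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
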