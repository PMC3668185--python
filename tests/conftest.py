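import numpy as np
import pytest

from dcesim import AIFModelSpec, KineticParams, generate_aif


@pytest.fixture(scope="session")
def default_aif():
    """Model AIF on the native grid: 0.1 s over 300 s."""
    return generate_aif(AIFModelSpec(), t0=0.0, dt=0.1, duration=300.0)


@pytest.fixture(scope="session")
def grid_params():
    """The full 150-set kinetic parameter grid."""
    return [KineticParams(vp=vp, ktrans=kt, ve=ve)
            for vp in (0.001, 0.005, 0.02, 0.05, 0.1)
            for kt in (0.02, 0.06, 0.1, 0.15, 0.2)
            for ve in (0.1, 0.2, 0.3, 0.4, 0.6, 0.8)]
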