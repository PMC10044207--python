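import numpy as np
import pytest

from ptasim import IndividualParameters, Regimen


@pytest.fixture
def worked_params() -> IndividualParameters:
    """CL 10 L/h, V 20 L (ke 0.5/h), fu 0.8 — the hand-checked example patient."""
    return IndividualParameters(CL_i=10.0, V_i=20.0, fu=0.8)


@pytest.fixture
def q8h_regimen() -> Regimen:
    """2000 mg every 8 h infused over 30 min."""
    return Regimen(mode="intermittent", dose=2000.0, interval=8.0, infusion_duration=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
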