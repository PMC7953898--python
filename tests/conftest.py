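import numpy as np
import pytest
from hypothesis import settings

from toxindex import table1_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Worked-example rate vectors used across the suite
LAM = (0.0, 5.0, 1.0, 5.0, 0.0)
GAM = (0.0, 1.0, 1.0, 1.5, 0.0)
LAM_HAT = (0.0, 3.3, 1.1, 2.9, 0.0)
# ROC / power-curve simulation setting
LAM_SIM = (0.5, 0.75, 1.0, 0.75, 0.5)
GAM_SIM = (0.60, 1.05, 1.50, 1.05, 0.60)


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
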