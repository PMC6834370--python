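import numpy as np
import pytest

from icfra import build_default_protocol
from icfra.groundtruth import KernelParams

DT = 0.1144  # default imaging frame interval (s)


@pytest.fixture(scope="session")
def protocol6():
    """19 x 6 grid, 6 repetitions (the lower end of the study's 6-10)."""
    return build_default_protocol(n_reps=6, order_seed=0)


@pytest.fixture(scope="session")
def protocol8():
    return build_default_protocol(n_reps=8, order_seed=1)


@pytest.fixture(scope="session")
def example_kernel():
    """Kernel parameters of the worked juxtacellular example cell."""
    return KernelParams(f0=28.8, f_1ap=10.2, t_rise_ms=532.0, tau_decay_ms=859.0)
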