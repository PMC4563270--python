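import numpy as np
import pytest

import gapwave as gw


@pytest.fixture(scope="session")
def driven_params():
    """Neuron parameters with the 200 pA constant drive of the pair setup."""
    return gw.DEFAULT_PARAMETERS.with_(I_const=200.0)


@pytest.fixture(scope="session")
def upstroke_state(driven_params):
    """A state on the action-potential upstroke (tight-tolerance warm-up)."""
    s = gw.NeuronState.resting(driven_params)
    for _ in range(170):  # 8.5 ms; the first spike peaks just after
        s, _ = gw.propagate_step(s, 0.05, None, driven_params, abs_tol=1e-12)
    assert s.V > -40.0
    return s


@pytest.fixture(scope="session")
def pair_run_h005():
    """Coupled symmetric pair, 200 ms at h = 0.05 ms, min-delay exchange."""
    net = gw.build_testcase_1a()
    return gw.Simulator(net, gw.SimulationConfig(h=0.05, strategy="dmin")).run(200.0)
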