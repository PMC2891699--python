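import numpy as np
import pytest

import sleepswitch as ss


@pytest.fixture(scope="session")
def human_params():
    return ss.get_preset("human_nominal")


@pytest.fixture(scope="session")
def attractor_config():
    """10 scored days after a 5-day transient (the steady-state protocol)."""
    return ss.SimConfig(duration=360.0, transient_discard=120.0)


@pytest.fixture(scope="session")
def human_sim(human_params, attractor_config):
    """Entrained deterministic human-nominal trajectory, shared across tests."""
    return ss.simulate(human_params, attractor_config)


def make_sim_result(times_h, q_m, params=None):
    """Assemble a SimResult around a prescribed MA firing-rate series, for
    tests of scoring code that do not need the integrator."""
    params = params or ss.get_preset("human_nominal")
    times_h = np.asarray(times_h, dtype=float)
    q_m = np.asarray(q_m, dtype=float)
    frac = np.clip(q_m / params.Q_max, 1e-12, 1 - 1e-12)
    v_m = params.theta + params.sigma_prime * np.log(frac / (1 - frac))
    zeros = np.zeros_like(times_h)
    cfg = ss.SimConfig(duration=max(float(times_h[-1]), 1.0) + 1.0,
                       transient_discard=0.0)
    return ss.SimResult(times=times_h, V_m=v_m, V_v=zeros - 10.0,
                        Q_m=q_m, Q_v=zeros, H=zeros + 1.0,
                        params=params, config=cfg)
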