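import numpy as np
import pytest

import trustdyn as td


@pytest.fixture(scope="session")
def default_session_result():
    """One full default transport session (100 trials, fixed seed).

    Shared across tests that examine macro-scale learning curves; running it
    once keeps the suite fast.
    """
    return td.run_session(td.ScenarioConfig(seed=0, n_trials=100))


@pytest.fixture(scope="session")
def default_geometry():
    return td.build_geometry()


def make_trace(g, dt=1.0, transient=0.0, u=None):
    """Build a TrialTrace directly from an activation array (steps, N)."""
    g = np.asarray(g, dtype=float)
    steps = g.shape[0]
    config = td.IntegrationConfig(dt=dt, duration=steps * dt, transient=transient)
    return td.TrialTrace(
        time_ms=(np.arange(steps) + 1) * dt,
        u=np.zeros_like(g) if u is None else np.asarray(u, dtype=float),
        g=g,
        external=np.zeros_like(g),
        config=config,
    )
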