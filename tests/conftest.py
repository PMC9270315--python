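"""Shared fixtures: reference steady states and the long limit-cycle runs.

The limit-cycle runs are expensive (minutes) and are shared between the
amplitude-comparison and conservation tests via a session-scoped fixture.
"""

import numpy as np
import pytest

from capnet.network import three_node_network
from capnet.sim import Perturbation, per_cycle_amplitudes, simulate
from capnet.steady import find_starting_state

D = 20.0


def run_limit_cycle(alpha: float, H0: float, T: float, dt: float):
    """Simulate off the Case-I state and measure converged cycle amplitudes.

    Amplitude = median half-range of the last three full cycles, segmented by
    the deep troughs of the redundant-vessel flux.
    """
    spec = three_node_network(alpha, H0, D)
    base = find_starting_state(alpha, "I", D, H0)
    res = simulate(spec, T, dt=dt, init=base,
                   perturbation=Perturbation(-1e-6), save_stride=10)
    pc = per_cycle_amplitudes(res.times, res.series("Q", 3),
                              {"H4": res.series("Hbar", 4)})
    qs = pc["amplitudes"]["seg"]
    hs = pc["amplitudes"]["H4"]
    assert len(qs) >= 3, "fewer than three full limit cycles in the run"
    return {
        "result": res,
        "Q3_amp": float(np.median(qs[-3:])),
        "H4_amp": float(np.median(hs[-3:])),
        "n_cycles": len(qs),
        "per_cycle_Q3": qs,
    }


@pytest.fixture(scope="session")
def cycle_runs():
    """Converged limit cycles at (0.5, 0.5) and (0.9, 0.5), two time steps."""
    out = {}
    for alpha, T in ((0.5, 3000.0), (0.9, 6000.0)):
        for dt in (0.01, 0.005):
            out[(alpha, dt)] = run_limit_cycle(alpha, 0.5, T, dt)
    return out


@pytest.fixture(scope="session")
def case1_states():
    """Reference Case-I nontrivial states used across stability tests."""
    return {
        (a, h): find_starting_state(a, "I", D, h)
        for a, h in ((0.5, 0.5), (0.9, 0.5), (0.6, 0.44))
    }
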