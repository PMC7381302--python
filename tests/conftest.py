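"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from evnest import ParameterVector, Reaction, ReactionNetwork, Species


def rk4_integrate(rhs, y0, t_end, dt=1e-3):
    """Brute-force fixed-step RK4 integrator (independent solver oracle)."""
    y = np.asarray(y0, dtype=float).copy()
    n_steps = int(round(t_end / dt))
    t = 0.0
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


@pytest.fixture
def decay_network():
    """A -> B, first order."""
    return ReactionNetwork(
        species=(Species("A", initial_copies=100.0), Species("B")),
        reactions=(Reaction("r1", ("A",), ("B",), "first_order_forward", "k"),),
    )


@pytest.fixture
def reversible_network():
    """A <-> B."""
    return ReactionNetwork(
        species=(Species("A", initial_copies=60.0), Species("B", initial_copies=40.0)),
        reactions=(
            Reaction("fwd", ("A",), ("B",), "first_order_forward", "kf"),
            Reaction("rev", ("B",), ("A",), "first_order_reverse", "kr"),
        ),
    )


@pytest.fixture
def enzyme_network():
    """Catalytic motif E + S <-> E:S -> E + P with an accumulator on conversion."""
    return ReactionNetwork(
        species=(
            Species("E", initial_copies=10.0),
            Species("S", initial_copies=100.0),
            Species("ES"),
            Species("P"),
        ),
        reactions=(
            Reaction("bind", ("E", "S"), ("ES",), "second_order_forward", "kf"),
            Reaction("unbind", ("ES",), ("E", "S"), "first_order_reverse", "kr"),
            Reaction("cat", ("ES",), ("E", "P"), "catalysis", "kc"),
        ),
        accumulators=(("P_produced", ("cat",)),),
    )


@pytest.fixture
def enzyme_params():
    return ParameterVector({"kf": 0.01, "kr": 0.1, "kc": 0.05})
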