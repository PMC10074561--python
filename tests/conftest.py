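import numpy as np
import pytest

from equilibra.model import build_model
from equilibra.reactions import parse_reactions
from equilibra.solve import compile_model


PPI_TEXT = "R + P = RP; Kd1"

TERNARY_TEXT = """
R + P = RP; Kd1
R + S = RS; Kd2
RS + P = RPS; Kd1/alpha
RP + S = RPS; Kd2/alpha
"""


@pytest.fixture(scope="session")
def ppi_system():
    return parse_reactions(PPI_TEXT)


@pytest.fixture(scope="session")
def ternary_system():
    return parse_reactions(TERNARY_TEXT)


@pytest.fixture(scope="session")
def ppi_compiled(ppi_system):
    return compile_model(build_model(ppi_system))


@pytest.fixture(scope="session")
def ternary_compiled(ternary_system):
    return compile_model(build_model(ternary_system))


def assert_state_invariants(cm, state, parameter_values, rtol=1e-8):
    """Conservation + mass-action consistency of a solved state.

    Called on every state the suite produces: concentrations are
    nonnegative, free <= total, each balance closes to ``rtol`` relative
    (1e-20 M absolute when the total is zero), and each reaction's
    mass-action ratio reproduces its constant to 1e-6 relative whenever
    the complex is above 1e-30 M.
    """
    species = state.species
    for name, v in species.items():
        assert v >= 0, f"{name} negative: {v}"
    for comp in cm.components:
        tot = state.totals[comp]
        assert state.free[comp] <= tot * (1 + 1e-9) + 1e-30
        bound = sum(
            cm.N[j, i] * state.complexes[cx]
            for j, cx in enumerate(cm.complexes)
            for i, c2 in enumerate(cm.components)
            if c2 == comp
        )
        gap = abs(tot - state.free[comp] - bound)
        if tot > 0:
            assert gap <= rtol * tot, f"balance {comp}: {gap} vs {tot}"
        else:
            assert gap <= 1e-20
    K = cm.constants(parameter_values)
    for k, rxn in enumerate(cm.model.system.reactions):
        cplx = species[rxn.product]
        if cplx <= 1e-30:
            continue
        num = 1.0
        for r in rxn.reactants:
            num *= species[r]
        assert abs(num / cplx - K[k]) / K[k] <= 1e-6, (
            f"mass action violated for {rxn.product}"
        )
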