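import numpy as np
import pytest

from equilibra.model import build_model
from equilibra.reactions import parse_reactions
from equilibra.solve import (
    Condition,
    SolverFailure,
    compile_model,
    kinetic_oracle,
    solve_equilibrium,
    solve_titration,
)
from equilibra.synthetic import stress_system

from .conftest import assert_state_invariants


def quadratic_complex(Rtot, Ptot, Kd):
    """Closed-form 1:1 bound concentration (numerically stable root)."""
    b = Kd + Rtot + Ptot
    return 2.0 * Rtot * Ptot / (b + np.sqrt(b * b - 4.0 * Rtot * Ptot))


class TestBinaryBinding:
    def test_symmetric_case(self, ppi_compiled):
        st = ppi_compiled.solve(
            Condition(totals={"R": 2e-6, "P": 2e-6}, parameter_values={"Kd1": 1e-6})
        )
        assert st.free["R"] == pytest.approx(1e-6, rel=1e-9)
        assert st.free["P"] == pytest.approx(1e-6, rel=1e-9)
        assert st.complexes["RP"] == pytest.approx(1e-6, rel=1e-9)
        assert_state_invariants(ppi_compiled, st, {"Kd1": 1e-6})

    def test_matches_quadratic_over_wide_range(self, ppi_compiled):
        """Agreement with the closed-form solution to 1e-10 relative over
        a million-fold range of Rtot/Kd."""
        Kd, Ptot = 1e-6, 1e-8
        for Rtot in np.geomspace(1e-9, 1e-3, 49):  # Rtot/Kd spans 1e-3 .. 1e3
            st = ppi_compiled.solve(
                Condition(totals={"R": Rtot, "P": Ptot}, parameter_values={"Kd1": Kd})
            )
            expected = quadratic_complex(Rtot, Ptot, Kd)
            assert st.complexes["RP"] == pytest.approx(expected, rel=1e-10)

    def test_zero_totals_give_zero_state(self, ppi_compiled):
        st = ppi_compiled.solve(
            Condition(totals={"R": 0.0, "P": 0.0}, parameter_values={"Kd1": 1e-6})
        )
        assert all(v == 0 for v in st.species.values())

    def test_one_component_absent(self, ppi_compiled):
        st = ppi_compiled.solve(
            Condition(totals={"R": 1e-6, "P": 0.0}, parameter_values={"Kd1": 1e-6})
        )
        assert st.free["R"] == pytest.approx(1e-6, rel=1e-12)
        assert st.complexes["RP"] == 0.0

    def test_component_in_no_reaction_stays_free(self):
        sys_ = parse_reactions("A + B = AB; K")
        # C enters through a second, disjoint system
        sys2 = parse_reactions("A + B = AB; K\nC + D = CD; K2")
        cm = compile_model(build_model(sys2))
        st = cm.solve(Condition(
            totals={"A": 1e-6, "B": 1e-6, "C": 5e-7, "D": 0.0},
            parameter_values={"K": 1e-6, "K2": 1e-6},
        ))
        assert st.free["C"] == pytest.approx(5e-7, rel=1e-12)


class TestTernaryGlue:
    PARAMS = {"Kd1": 4.05e-6, "Kd2": 3.89e-4, "alpha": 1.34e3}
    TOTALS = {"R": 10e-6, "P": 10e-9, "S": 100e-6}

    def test_matches_kinetic_oracle(self, ternary_compiled):
        st = ternary_compiled.solve(
            Condition(totals=self.TOTALS, parameter_values=self.PARAMS)
        )
        oracle = kinetic_oracle(
            ternary_compiled,
            Condition(totals=self.TOTALS, parameter_values=self.PARAMS),
        )
        for name in st.species:
            assert st.species[name] == pytest.approx(
                oracle.species[name], rel=1e-6
            ), name
        assert_state_invariants(ternary_compiled, st, self.PARAMS)

    def test_glue_increases_ternary_occupancy(self, ternary_compiled):
        """More stabilizer pulls more of the scarce partner into RPS."""
        lo = ternary_compiled.solve(Condition(
            totals={**self.TOTALS, "S": 1e-6}, parameter_values=self.PARAMS))
        hi = ternary_compiled.solve(Condition(
            totals={**self.TOTALS, "S": 1e-4}, parameter_values=self.PARAMS))
        assert hi.complexes["RPS"] > lo.complexes["RPS"]


class TestTitration:
    def test_monotone_binding_isotherm(self, ppi_compiled):
        concs = np.geomspace(1e-8, 1e-3, 12)
        conditions = [
            Condition(totals={"R": float(c), "P": 1e-8},
                      parameter_values={"Kd1": 1e-6})
            for c in concs
        ]
        states = solve_titration(ppi_compiled, conditions)
        rp = [s.complexes["RP"] for s in states]
        assert len(states) == 12
        assert all(b >= a * (1 - 1e-12) for a, b in zip(rp, rp[1:]))

    def test_reversed_order_identical_states(self, ppi_compiled):
        concs = np.geomspace(1e-8, 1e-3, 8)
        mk = lambda c: Condition(totals={"R": float(c), "P": 1e-8},
                                 parameter_values={"Kd1": 1e-6})
        fwd = solve_titration(ppi_compiled, [mk(c) for c in concs])
        rev = solve_titration(ppi_compiled, [mk(c) for c in concs[::-1]])
        for a, b in zip(fwd, rev[::-1]):
            for name in a.species:
                assert a.species[name] == pytest.approx(b.species[name], rel=1e-8)

    def test_empty_condition_list_rejected(self, ppi_compiled):
        with pytest.raises(ValueError, match="empty"):
            solve_titration(ppi_compiled, [])

    def test_nonstrict_mode_reports_failures_per_point(self, ppi_compiled):
        conds = [
            Condition(totals={"R": 1e-6, "P": 1e-8}, parameter_values={"Kd1": 1e-6}),
            Condition(totals={"R": 1e-6, "P": 1e-8}, parameter_values={"Kd1": -1.0}),
        ]
        states = solve_titration(ppi_compiled, conds, strict=False)
        assert states[0] is not None and states[1] is None


class TestOracleEquivalence:
    def test_zero_totals(self, ppi_compiled):
        st = kinetic_oracle(ppi_compiled, Condition(
            totals={"R": 0.0, "P": 0.0}, parameter_values={"Kd1": 1e-6}))
        assert all(v == 0 for v in st.species.values())

    @pytest.mark.parametrize("seed", range(12))
    def test_random_systems_match_oracle(self, seed):
        """Random small networks: algebraic solve vs ODE relaxation."""
        rng = np.random.default_rng(seed)
        sys_ = stress_system(int(rng.integers(4, 9)), seed=seed)
        cm = compile_model(build_model(sys_))
        params = {}  # constants are numeric literals already
        totals = {
            c: float(10.0 ** rng.uniform(-8, -5)) for c in cm.components
        }
        cond = Condition(totals=totals, parameter_values=params)
        st = cm.solve(cond)
        oracle = kinetic_oracle(cm, cond)
        scale = max(totals.values())
        for name in st.species:
            a, b = st.species[name], oracle.species[name]
            assert abs(a - b) <= 1e-6 * max(b, 1e-12 * scale), name
        assert_state_invariants(cm, st, params)


class TestStressSystems:
    def test_twenty_species_ladder_solves(self):
        sys_ = stress_system(20, seed=42)
        cm = compile_model(build_model(sys_))
        totals = {c: 1e-6 for c in cm.components}
        st = cm.solve(Condition(totals=totals, parameter_values={}))
        assert_state_invariants(cm, st, {})

    def test_minimal_ladder(self):
        sys_ = stress_system(3, seed=1)
        assert len(sys_.species) == 3

    def test_nonfinite_parameters_rejected(self, ppi_compiled):
        with pytest.raises(ValueError):
            ppi_compiled.solve(Condition(
                totals={"R": 1e-6, "P": 1e-6},
                parameter_values={"Kd1": float("nan")},
            ))
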