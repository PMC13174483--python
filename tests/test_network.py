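"""Mass-action engine: derivative assembly, stiff integration, conservation."""

import numpy as np
import pytest

from thrombogen.fixtures import toy_network
from thrombogen.network import (
    ConfigurationError,
    ConservationGroup,
    NetworkModel,
    Reaction,
    SolverOptions,
    Species,
    build_rhs,
    check_conservation,
    reaction_rates,
    simulate,
    stoichiometry_matrix,
)

from conftest import rk4_integrate


class TestBuildRhs:
    def test_single_unimolecular_term(self):
        model = toy_network("decay", k=0.1)
        dydt = build_rhs(model)(0.0, np.array([1.0, 0.0]))
        assert dydt == pytest.approx([-0.1, 0.1])

    def test_empty_network_has_zero_derivative(self):
        model = NetworkModel([Species("A", 1.0)], [])
        assert build_rhs(model)(5.0, np.array([3.0])) == pytest.approx([0.0])

    def test_bimolecular_product_rule(self):
        model = toy_network("bimolecular", k=1e6, a0=1e-6)
        dydt = build_rhs(model)(0.0, np.array([1e-6, 1e-6, 0.0]))
        assert dydt[2] == pytest.approx(1e-6)

    def test_unknown_species_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown species"):
            NetworkModel([Species("A", 1.0)],
                         [Reaction(("A",), ("Ghost",), 1.0)])

    def test_molecularity_capped_at_two(self):
        with pytest.raises(ConfigurationError, match="molecularity"):
            Reaction(("A", "B", "C"), ("D",), 1.0)

    def test_matches_stoichiometry_times_rates_on_random_states(self, coag_model):
        """Oracle equivalence: N @ v(y) == rhs(y) on >= 100 random states."""
        rhs = build_rhs(coag_model)
        N = stoichiometry_matrix(coag_model)
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.uniform(0, 1e-6, size=len(coag_model.species))
            expected = N @ reaction_rates(coag_model, y)
            np.testing.assert_allclose(rhs(0.0, y), expected, rtol=1e-12)


class TestSimulate:
    def test_exponential_decay_closed_form(self):
        k, a0 = 0.37, 2.0
        traj = simulate(toy_network("decay", k=k, a0=a0), 20.0,
                        SolverOptions(report_step=0.5))
        np.testing.assert_allclose(traj.series("A"), a0 * np.exp(-k * traj.times),
                                   rtol=1e-6, atol=1e-12)

    def test_toy_bimolecular_matches_fine_step_rk4(self):
        """Independent fixed-step RK4 oracle at dt=1e-3 s agrees to < 1e-4."""
        model = toy_network("bimolecular", k=2.0, a0=0.8)
        traj = simulate(model, 5.0, SolverOptions(report_step=5.0))
        oracle = rk4_integrate(build_rhs(model), model.initial_state(), 5.0, 1e-3)
        np.testing.assert_allclose(traj.concentrations[-1], oracle,
                                   rtol=1e-4, atol=1e-12)

    def test_reversible_network_matches_rk4(self):
        model = toy_network("reversible", k=0.7, k2=0.3, a0=1.0)
        traj = simulate(model, 10.0, SolverOptions(report_step=10.0))
        oracle = rk4_integrate(build_rhs(model), model.initial_state(), 10.0, 1e-3)
        np.testing.assert_allclose(traj.concentrations[-1], oracle, rtol=1e-4)

    def test_zero_horizon_returns_initial_state(self, coag_model):
        traj = simulate(coag_model, 0.0)
        assert traj.times.tolist() == [0.0]
        np.testing.assert_array_equal(traj.concentrations[0],
                                      coag_model.initial_state())

    def test_first_row_equals_initial_state(self):
        model = toy_network("decay", k=0.2, a0=3.0)
        traj = simulate(model, 4.0)
        np.testing.assert_array_equal(traj.concentrations[0], [3.0, 0.0])

    def test_tolerance_refinement_converges(self, coag_model):
        """Refining rtol/atol by 10x changes reported series by < 0.1%."""
        coarse = simulate(coag_model, 300.0, SolverOptions(),
                          initial_state=_with_tf(coag_model, 25e-12))
        fine = simulate(coag_model, 300.0,
                        SolverOptions(rtol=1e-9, atol=1e-17),
                        initial_state=_with_tf(coag_model, 25e-12))
        for sp in ("IIa", "mIIa", "Xa"):
            a, b = coarse.series(sp), fine.series(sp)
            scale = np.max(np.abs(b))
            assert np.max(np.abs(a - b)) / scale < 1e-3

    def test_nonnegativity_within_solver_tolerance(self, coag_model):
        from thrombogen.coagulation import SCENARIO_PRESETS, run_scenario
        atol = SolverOptions().atol
        for name in SCENARIO_PRESETS:
            traj = run_scenario(name, 600.0)
            assert traj.concentrations.min() >= -10 * atol, name


def _with_tf(model, tf):
    y0 = model.initial_state()
    y0[model.index("TF")] = tf
    return y0


class TestConservation:
    def test_closed_two_state_system_is_conserved(self):
        model = toy_network("reversible", k=0.4, k2=0.1, a0=1.0)
        model.conservation_groups.append(
            ConservationGroup("total", (("A", 1.0), ("B", 1.0))))
        traj = simulate(model, 50.0)
        assert check_conservation(traj, model)["total"] < 1e-8

    def test_net_production_group_is_flagged_not_an_error(self):
        model = toy_network("bimolecular", k=1.0, a0=1.0)
        model.conservation_groups.append(
            ConservationGroup("just_C", (("C", 1.0),)))
        # C starts at 0 so the drift is reported on an absolute scale
        traj = simulate(model, 2.0)
        assert check_conservation(traj, model)["just_C"] > 0.1

    def test_group_with_unknown_species_rejected(self):
        with pytest.raises(ConfigurationError, match="conservation group"):
            NetworkModel([Species("A", 1.0)], [],
                         [ConservationGroup("g", (("missing", 1.0),))])


class TestSerialization:
    def test_json_round_trip(self, tmp_path, coag_model):
        path = tmp_path / "model.json"
        coag_model.to_json(path)
        loaded = NetworkModel.from_json(path)
        assert loaded.to_dict() == coag_model.to_dict()

    def test_trajectory_csv_round_trip(self, tmp_path):
        traj = simulate(toy_network("decay", k=0.3), 5.0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        assert path.read_text().startswith("time_s,A,B")
        from thrombogen.network import Trajectory
        back = Trajectory.from_csv(path)
        np.testing.assert_array_equal(back.times, traj.times)
        np.testing.assert_array_equal(back.concentrations, traj.concentrations)

    def test_duplicate_species_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            NetworkModel([Species("A", 1.0), Species("A", 2.0)], [])
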