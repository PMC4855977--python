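import numpy as np
import pytest

import phaflux as pf
from phaflux.fba import FbaError, FbaScenario


def _steady_state_residual(network, dist):
    S, rows, cols = network.stoichiometric_matrix()
    v = np.array([dist.flux[r.id] for r in network.reactions])
    return np.abs(S @ v).max()


class TestSolveFba:
    def test_linear_chain_all_unit_flux(self, chain_network):
        sc = FbaScenario(constraints={"up": 1.0}, objective="out",
                         maintenance_reaction="up")
        sol = pf.solve_fba(chain_network, sc)
        assert sol.is_optimal
        assert sol.objective_value == pytest.approx(1.0)
        assert all(sol.flux[r] == pytest.approx(1.0) for r in ("up", "mid", "out"))

    def test_closed_exchanges_zero_optimum(self, ref_network):
        sc = FbaScenario(
            constraints={r.id: 0.0 for r in ref_network.exchange_reactions},
        )
        sol = pf.solve_fba(ref_network, sc)
        assert sol.is_optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert max(abs(v) for v in sol.flux.values()) < 1e-8

    def test_two_route_picks_higher_yield_vertex(self, two_route_network):
        # hand enumeration: uptake 1 can go via r_low (1 B) or r_high (2 B);
        # the optimal vertex is all flux through r_high
        sc = FbaScenario(constraints={"up": 1.0}, objective="out",
                         maintenance_reaction="up")
        sol = pf.solve_fba(two_route_network, sc)
        assert sol.objective_value == pytest.approx(2.0)
        assert sol.flux["r_high"] == pytest.approx(1.0)
        assert sol.flux["r_low"] == pytest.approx(0.0, abs=1e-9)
        assert sol.flux["waste"] == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_sign_invariants(self, ref_network, condition_observations):
        for cond, obs in condition_observations.items():
            sc = pf.scenario_from_observation(obs, name=cond)
            sol = pf.solve_fba(ref_network, sc)
            assert sol.is_optimal, cond
            assert _steady_state_residual(ref_network, sol) <= 1e-8
            for r in ref_network.reactions:
                if not r.reversible:
                    assert sol.flux[r.id] >= -1e-9, (cond, r.id)

    def test_parsimonious_step_preserves_optimum(self, ref_network, condition_observations):
        sc = pf.scenario_from_observation(condition_observations["N-lim-low"])
        plain = pf.solve_fba(ref_network, sc, parsimonious=False)
        pars = pf.solve_fba(ref_network, sc, parsimonious=True)
        assert pars.objective_value == pytest.approx(
            plain.objective_value, rel=1e-9
        )

    def test_infeasible_constraint_flips_status(self, chain_network):
        sc = FbaScenario(constraints={"up": 1.0, "out": 2.0}, objective="out",
                         maintenance_reaction="up")
        sol = pf.solve_fba(chain_network, sc)
        assert sol.status == "infeasible"
        assert set(sol.infeasibility_hint) == {"up", "out"}

    def test_unknown_reaction_rejected(self, chain_network):
        sc = FbaScenario(constraints={"nope": 1.0}, objective="out",
                         maintenance_reaction="up")
        with pytest.raises(FbaError, match="unknown reaction"):
            pf.solve_fba(chain_network, sc)


class TestScenarioFromObservation:
    def test_nlim_low_pha_sink(self, condition_observations):
        sc = pf.scenario_from_observation(condition_observations["N-lim-low"])
        # D*f/(1-f)*1000/M_lump = 0.044*0.297/0.703*1000/167.73
        assert sc.constraints["EX_pha"] == pytest.approx(0.1108, abs=2e-4)
        assert sc.constraints["EX_glycerol"] == pytest.approx(2.47)
        assert sc.constraints["EX_succinate"] == pytest.approx(0.24)
        assert sc.constraints["EX_malate"] == pytest.approx(0.04)

    def test_clim_high_bounds(self, condition_observations):
        sc = pf.scenario_from_observation(condition_observations["C-lim-high"])
        assert sc.constraints["EX_glycerol"] == pytest.approx(2.60)
        lo, hi = sc.constraints["EX_co2"]
        assert (lo, hi) == (pytest.approx(3.1), pytest.approx(3.3))

    def test_zero_pha_fraction_zero_sink(self):
        obs = pf.ChemostatObservation(
            dilution_rate=0.1, q_glycerol_molar=2.0, q_co2=3.0, pha_fraction=0.0
        )
        sc = pf.scenario_from_observation(obs)
        assert sc.constraints["EX_pha"] == 0.0

    def test_default_maintenance_from_pirt(self, condition_observations):
        sc = pf.scenario_from_observation(condition_observations["N-lim-low"])
        assert sc.maintenance_atp == pytest.approx(0.039 * (0.3939 + 2.33 * 1.75))


class TestFluxVariability:
    def test_chain_has_no_freedom(self, chain_network):
        sc = FbaScenario(constraints={"up": 1.0}, objective="out",
                         maintenance_reaction="up")
        fva = pf.flux_variability(chain_network, sc)
        for rid, (lo, hi) in fva.items():
            assert hi - lo == pytest.approx(0.0, abs=1e-9), rid

    def test_parallel_paths_fully_degenerate(self, diamond_network):
        # hand enumeration of the optimal face: r2 + r3 = 1, each in [0, 1]
        sc = FbaScenario(constraints={"up": 1.0}, objective="out",
                         maintenance_reaction="up")
        fva = pf.flux_variability(diamond_network, sc)
        assert fva["r2"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(1.0))
        assert fva["r3"] == (pytest.approx(0.0, abs=1e-9), pytest.approx(1.0))
        assert fva["out"][1] - fva["out"][0] == pytest.approx(0.0, abs=1e-9)

    def test_isocitrate_node_reported_degenerate(self, ref_network, condition_observations):
        # the reference N-limited low-D scenario leaves the split free
        sc = pf.scenario_from_observation(condition_observations["N-lim-low"])
        fva = pf.flux_variability(ref_network, sc)
        lo, hi = fva["aceA"]
        assert hi - lo > 0.5  # strongly degenerate at the optimum

    def test_infeasibility_propagates(self, chain_network):
        sc = FbaScenario(constraints={"up": 1.0, "out": 2.0}, objective="out",
                         maintenance_reaction="up")
        with pytest.raises(FbaError):
            pf.flux_variability(chain_network, sc)


class TestNodeSplit:
    def test_single_consumer_is_unity(self, chain_network):
        sc = FbaScenario(constraints={"up": 1.0}, objective="out",
                         maintenance_reaction="up")
        sol = pf.solve_fba(chain_network, sc)
        split = pf.node_split(sol, chain_network, "A[c]", ["mid"])
        assert split["mid"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_over_all_branches(self, diamond_network):
        sc = FbaScenario(constraints={"up": 1.0, "r2": 0.3}, objective="out",
                         maintenance_reaction="up")
        sol = pf.solve_fba(diamond_network, sc)
        split = pf.node_split(sol, diamond_network, "A[c]", ["r2", "r3"])
        assert split["r2"] == pytest.approx(0.3)
        assert split["r3"] == pytest.approx(0.7)
        assert sum(split.values()) == pytest.approx(1.0)

    def test_zero_consumption_rejected(self, chain_network):
        sc = FbaScenario(constraints={"up": 0.0}, objective="out",
                         maintenance_reaction="up")
        sol = pf.solve_fba(chain_network, sc)
        with pytest.raises(FbaError, match="no consumption"):
            pf.node_split(sol, chain_network, "A[c]", ["mid"])


class TestModeHull:
    def test_normalized_fba_solution_in_mode_hull(
        self, ref_network, ref_modes_normalized, condition_observations
    ):
        # every steady-state flux with unit glycerol uptake must be a convex
        # combination of the glycerol-normalized elementary modes
        from scipy.optimize import linprog

        M = ref_modes_normalized.values  # modes x reactions
        for cond, obs in condition_observations.items():
            sc = pf.scenario_from_observation(obs, name=cond)
            sol = pf.solve_fba(ref_network, sc)
            v = np.array([sol.flux[r] for r in ref_modes_normalized.reaction_ids])
            v = v / sol.flux["EX_glycerol"]
            k = M.shape[0]
            A_eq = np.vstack([M.T, np.ones(k)])
            b_eq = np.concatenate([v, [1.0]])
            res = linprog(np.zeros(k), A_eq=A_eq, b_eq=b_eq,
                          bounds=[(0, None)] * k, method="highs")
            assert res.status == 0, cond
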