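"""The instantaneous growth-per-flux optimisation.

The solver is checked against a brute-force grid search on a toy network
with two degrees of freedom, against direct SLSQP maximisation of the ratio
objective on the full reduced network, and against the structural
invariants every returned flux state must satisfy.
"""

import numpy as np
import pytest
from scipy import optimize as sopt

from dfba_pdo import (ObjectiveSpec, build_reduced_network, solve_flux_state)
from dfba_pdo.kinetics import (KineticParams, acetate_secretion_bound,
                               glycerol_uptake_bound)
from dfba_pdo.network import build_flux_problem
from dfba_pdo.optimize import (FluxProblem, InfeasibleProblemError,
                               solve_fractional)
from dfba_pdo.units import g_per_l_to_mm


def _toy_problem(w: float) -> FluxProblem:
    """Linear chain with a branch: uptake -> {biomass | c -> {P | Q}}.

    Balanced metabolites a and c leave two degrees of freedom
    (v_bio, v_p1); uptake is pinned at 10.
    """
    #            up  bio  branch  p1   p2
    S = np.array([
        [1.0, -1.0, -1.0, 0.0, 0.0],    # a
        [0.0, 0.0, 1.0, -1.0, -1.0],    # c
    ])
    lb = np.array([10.0, 0.0, 0.0, 0.0, 0.0])
    ub = np.array([10.0, 1000.0, 1000.0, 1000.0, 1000.0])
    c_mu = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    atp = np.array([0.0, 0.0, 0.0, 1.0, 0.0])
    return FluxProblem(S=S, lb=lb, ub=ub, c_mu=c_mu, atp_weights=atp, w=w)


def _toy_grid_optimum(prob: FluxProblem, n: int = 801) -> float:
    """Oracle: exhaustive search over the 2-D feasible flux space."""
    best = 0.0
    for v_bio in np.linspace(0.0, 10.0, n):
        branch = 10.0 - v_bio
        for v_p1 in np.linspace(0.0, branch, n // 4 + 2):
            v = np.array([10.0, v_bio, branch, v_p1, branch - v_p1])
            d = prob.denominator(v)
            if d > 0:
                best = max(best, prob.mu(v) / d)
    return best


class TestToyNetworkOracle:
    @pytest.mark.parametrize("w", [1.0, 0.5, 0.04])
    def test_matches_brute_force_grid(self, w):
        prob = _toy_problem(w)
        v, z, _ = solve_fractional(prob)
        z_grid = _toy_grid_optimum(prob)
        assert z >= z_grid - 1e-9          # grid cannot beat the optimiser
        assert z == pytest.approx(z_grid, rel=1e-4)
        assert prob.S @ v == pytest.approx(np.zeros(2), abs=1e-8)

    def test_infeasible_bounds_raise(self):
        prob = _toy_problem(1.0)
        prob.lb = prob.lb.copy()
        prob.ub = prob.ub.copy()
        prob.lb[1] = prob.ub[1] = 20.0     # biomass forced above uptake
        with pytest.raises(InfeasibleProblemError):
            solve_fractional(prob)


def _dynamic_bounds(gl_g_per_l: float, kin: KineticParams):
    g_mm = g_per_l_to_mm(gl_g_per_l, "glycerol")
    v_gly = glycerol_uptake_bound(g_mm, kin)
    return {"glycerol_uptake": (v_gly, v_gly),
            "acetate_kinase": (0.0, acetate_secretion_bound(v_gly, kin))}


class TestReducedNetworkFluxState:
    def test_starvation_gives_zero_everything(self, network, excess_objective):
        fs = solve_flux_state(network, excess_objective,
                              {"glycerol_uptake": (0.0, 0.0)})
        assert fs.mu == 0.0
        assert fs.objective_value == 0.0
        assert all(abs(v) < 1e-9 for v in fs.fluxes.values())

    def test_growth_feasible_on_glycerol_alone(self, network, kinetics):
        # oracle: plain linear programming certifies nonzero growth
        prob = build_flux_problem(
            network, ObjectiveSpec(1.0, network.atp_production_flux_ids),
            _dynamic_bounds(10.0, kinetics))
        res = sopt.linprog(-prob.c_mu, A_eq=prob.S, b_eq=np.zeros(prob.S.shape[0]),
                           bounds=list(zip(prob.lb, prob.ub)), method="highs")
        assert res.success and -res.fun > 0.01

    @pytest.mark.parametrize("gl, w", [(5.0, 1.0), (10.0, 1.0), (30.0, 0.04),
                                       (46.0, 0.04)])
    def test_steady_state_and_bounds_invariants(self, network, kinetics, gl, w):
        obj = ObjectiveSpec(w, network.atp_production_flux_ids)
        db = _dynamic_bounds(gl, kinetics)
        fs = solve_flux_state(network, obj, db)
        prob = build_flux_problem(network, obj, db)
        v = np.array([fs.fluxes[r] for r in network.reaction_ids])
        assert np.max(np.abs(prob.S @ v)) < 1e-6
        assert np.all(v >= prob.lb - 1e-6) and np.all(v <= prob.ub + 1e-6)
        assert fs.mu > 0

    def test_matches_direct_slsqp_on_reduced_network(self, network, kinetics,
                                                     excess_objective):
        # oracle: maximise mu/D directly with SLSQP from multiple starts
        db = _dynamic_bounds(30.0, kinetics)
        prob = build_flux_problem(network, excess_objective, db)
        v_star, z_star, _ = solve_fractional(prob)

        def neg_ratio(x):
            d = prob.denominator(x)
            return -prob.mu(x) / d if d > 1e-14 else 0.0

        best = 0.0
        rng = np.random.default_rng(7)
        for trial in range(4):
            x0 = v_star * rng.uniform(0.5, 1.5, len(v_star)) if trial else v_star
            res = sopt.minimize(
                neg_ratio, np.clip(x0, prob.lb, prob.ub), method="SLSQP",
                bounds=list(zip(prob.lb, prob.ub)),
                constraints=[{"type": "eq", "fun": lambda x: prob.S @ x}],
                options={"maxiter": 500, "ftol": 1e-14})
            if np.max(np.abs(prob.S @ res.x)) < 1e-6:
                best = max(best, -res.fun)
        assert z_star == pytest.approx(best, rel=1e-5)

    def test_acetate_flux_exceeds_butyrate_at_excess(self, network, kinetics,
                                                     excess_objective):
        # the secreted-acid hierarchy of the excess regime around 30 g/L
        fs = solve_flux_state(network, excess_objective,
                              _dynamic_bounds(30.0, kinetics))
        assert fs.fluxes["acetate_kinase"] > fs.fluxes["butyrate_kinase"]

    def test_relaxing_acetate_bound_never_decreases_objective(self, network,
                                                              kinetics,
                                                              excess_objective):
        db = _dynamic_bounds(30.0, kinetics)
        fs_tight = solve_flux_state(network, excess_objective, db)
        db_relaxed = dict(db)
        db_relaxed["acetate_kinase"] = (0.0, db["acetate_kinase"][1] * 2.0)
        fs_loose = solve_flux_state(network, excess_objective, db_relaxed)
        assert fs_loose.objective_value >= fs_tight.objective_value - 1e-12

    def test_product_form_is_available(self, network, kinetics):
        obj = ObjectiveSpec(0.04, network.atp_production_flux_ids, form="product")
        fs = solve_flux_state(network, obj, _dynamic_bounds(30.0, kinetics))
        assert fs.mu > 0
        assert fs.objective_value > 0
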