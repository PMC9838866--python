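"""Steady-state adjoint method: linear solves replace backward integration."""

import numpy as np
import pytest

import steadygrad as sg
from steadygrad.conservation import SingularJacobian
from tests.conftest import relative_difference


def prod_deg_model():
    return sg.compile_model(
        sg.parse_model(
            {
                "species": ["X"],
                "parameters": ["k_in", "k_out"],
                "inputs": ["s"],
                "reactions": [
                    {"products": {"X": 1}, "rate": "s*k_in"},
                    {"reactants": {"X": 1}, "rate": "k_out*X"},
                ],
                "observables": {"obs_X": "X"},
            }
        )
    )


class TestPosteqContribution:
    def test_hand_solved_production_degradation(self):
        """p(t'') = 1, 1x1 solve gives p_int = 1, contribution (-1, +2)."""
        m = prod_deg_model()
        th, u = np.array([2.0, 1.0]), np.array([1.0])
        contrib, p_carry, solve = sg.posteq_adjoint_contribution(
            m, np.array([2.0]), th, u, [(0, 3.0, 1.0)]
        )
        assert solve.p_boundary == pytest.approx([1.0])
        assert solve.p_integral == pytest.approx([1.0])
        assert contrib == pytest.approx([-1.0, 2.0])
        assert np.all(p_carry == 0.0)

    def test_zero_residual_zero_contribution(self):
        m = prod_deg_model()
        th, u = np.array([2.0, 1.0]), np.array([1.0])
        contrib, _, solve = sg.posteq_adjoint_contribution(
            m, np.array([2.0]), th, u, [(0, 2.0, 1.0)]
        )
        assert contrib == pytest.approx([0.0, 0.0])
        assert solve.residual == 0.0

    def test_identity_jacobian_case(self):
        """jac = -I: p_integral equals the boundary value."""
        net = sg.parse_model(
            {
                "species": ["x1", "x2"],
                "parameters": ["b1", "b2"],
                "odes": {"x1": "b1 - x1", "x2": "b2 - x2"},
            }
        )
        m = sg.compile_model(net)
        th, u = np.array([1.0, 2.0]), np.array([])
        x_star = th.copy()
        contrib, _, solve = sg.posteq_adjoint_contribution(
            m, x_star, th, u, [(0, th[0] + 0.5, 1.0), (1, th[1] - 1.5, 1.0)]
        )
        assert solve.p_boundary == pytest.approx([0.5, -1.5])
        assert solve.p_integral == pytest.approx([0.5, -1.5])

    def test_singular_jacobian_raises_with_hint(self):
        net = sg.parse_model(
            {
                "species": ["A", "B"],
                "parameters": ["k1", "k2"],
                "reactions": [
                    {"reactants": {"A": 1}, "products": {"B": 1}, "rate": "k1*A"},
                    {"reactants": {"B": 1}, "products": {"A": 1}, "rate": "k2*B"},
                ],
                "initials": {"A": 1},
            }
        )
        m = sg.compile_model(net)
        th, u = np.array([2.0, 1.0]), np.array([])
        with pytest.raises(SingularJacobian, match="conserved"):
            sg.posteq_adjoint_contribution(
                m, np.array([1 / 3, 2 / 3]), th, u, [(0, 1.0, 1.0)]
            )


class TestPreeqContribution:
    def test_zero_adjoint_gives_zero(self):
        m = prod_deg_model()
        contrib, _ = sg.preeq_adjoint_contribution(
            m, np.array([1.0]), np.array([2.0, 1.0]), np.array([0.5]), np.zeros(1)
        )
        assert contrib == pytest.approx([0.0, 0.0])

    def test_scalar_solve(self):
        """jac = -k_out: p_int = p(t0)/k_out; contribution -p_int df/dtheta."""
        m = prod_deg_model()
        th = np.array([2.0, 4.0])
        u_pre = np.array([0.5])
        x_star = np.array([0.5 * 2.0 / 4.0])
        p_t0 = np.array([3.0])
        contrib, solve = sg.preeq_adjoint_contribution(m, x_star, th, u_pre, p_t0)
        p_int = 3.0 / 4.0
        dfdth = np.array([0.5, -x_star[0]])
        assert solve.p_integral == pytest.approx([p_int])
        assert contrib == pytest.approx(-p_int * dfdth)


class TestSsasaGradient:
    def test_steady_state_data_only_closed_form(self, prod_deg_ss_problem):
        res = sg.ssasa_gradient(prod_deg_ss_problem, [2.0, 1.0])
        assert res.gradient_linear == pytest.approx([-1.0, 2.0], rel=1e-8)
        assert res.counters["backward_rhs_equilibration"] == 0
        assert res.condition_methods["c0"]["posteq"] == "ssasa-linear-solve"

    def test_equals_asa_without_equilibration(self):
        prob, th = sg.make_problem(sg.FixtureSpec("production_degradation", sigma=0.1))
        gs = sg.gradient(prob, th, method="ssasa")
        ga = sg.gradient(prob, th, method="asa")
        assert gs.gradient == pytest.approx(ga.gradient, rel=1e-9, abs=1e-12)

    def test_mm_chain_both_equilibrations_vs_oracles(self):
        spec = sg.FixtureSpec("mm_chain", seed=0, sigma=0.1, equilibration="both")
        prob, th = sg.make_problem(spec)
        th_eval = th + 0.1
        gs = sg.gradient(prob, th_eval, method="ssasa")
        gf = sg.gradient(prob, th_eval, method="forward")
        gd = sg.gradient(prob, th_eval, method="fd")
        assert relative_difference(gs.gradient, gf.gradient) < 1e-6
        assert relative_difference(gs.gradient, gd.gradient) < 1e-4

    def test_preeq_linear_network_matches_long_simulation(self):
        spec = sg.FixtureSpec("linear_network", seed=3, sigma=0.1, equilibration="pre")
        prob, th = sg.make_problem(spec)
        gs = sg.gradient(prob, th, method="ssasa")
        ga = sg.gradient(prob, th, method="asa", tail_scale=2.0)
        assert relative_difference(gs.gradient, ga.gradient) < 1e-6

    def test_zero_data_zero_gradient(self):
        prob, th_true = sg.make_problem(
            sg.FixtureSpec("mm_chain", sigma=0.0, equilibration="both")
        )
        res = sg.ssasa_gradient(prob, th_true)
        assert np.max(np.abs(res.gradient)) < 1e-12

    def test_backward_counters_beat_reference(self):
        spec = sg.FixtureSpec("linear_network", seed=2, sigma=0.1, equilibration="post")
        prob, th = sg.make_problem(spec)
        gs = sg.gradient(prob, th, method="ssasa")
        ga = sg.gradient(prob, th, method="asa")
        assert gs.counters["backward_rhs_equilibration"] == 0
        assert ga.counters["backward_rhs_equilibration"] > 0
        total_s = gs.counters["backward_rhs_timecourse"] + gs.counters["backward_rhs_equilibration"]
        total_a = ga.counters["backward_rhs_timecourse"] + ga.counters["backward_rhs_equilibration"]
        assert total_s < total_a

    def test_fallback_uses_backward_integration_when_allowed(self):
        spec = sg.FixtureSpec("conversion", sigma=0.1, n_timepoints=0, equilibration="post")
        prob_full, th = sg.make_problem(spec, reduce=False)
        with pytest.raises(SingularJacobian):
            sg.gradient(prob_full, th, method="ssasa")
        settings = sg.SolverSettings(allow_asa_fallback=True)
        res = sg.gradient(prob_full, th, method="ssasa", settings=settings)
        assert res.condition_methods["c0"]["posteq"] == "asa-backward-fallback"
        assert res.counters["backward_rhs_equilibration"] > 0
        # the fallback gradient agrees with the reduced-model linear-solve path
        prob_red, _ = sg.make_problem(spec)
        red = sg.gradient(prob_red, th, method="ssasa")
        assert relative_difference(res.gradient, red.gradient) < 1e-4
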