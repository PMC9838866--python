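"""Weighted-residual convergence test and steady-state computation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import steadygrad as sg
from steadygrad.equilibration import DegenerateWeightError, EquilibrationFailure


def compile_prod_deg():
    net = sg.parse_model(
        {
            "species": ["X"],
            "parameters": ["k_in", "k_out"],
            "inputs": ["s"],
            "reactions": [
                {"products": {"X": 1}, "rate": "s*k_in"},
                {"reactants": {"X": 1}, "rate": "k_out*X"},
            ],
        }
    )
    return sg.compile_model(net)


class TestWrms:
    def test_zero_derivative_converged(self):
        assert sg.wrms_residual([0.0, 0.0], [1.0, 2.0], 1e-8, 1e-16) == 0.0

    def test_scalar_value(self):
        assert sg.wrms_residual([0.5], [1.0], 1.0, 0.0) == pytest.approx(0.25)

    def test_two_state_not_converged(self):
        assert sg.wrms_residual([2.0, 0.0], [1.0, 1.0], 1.0, 0.0) == pytest.approx(2.0)

    def test_degenerate_weight(self):
        with pytest.raises(DegenerateWeightError):
            sg.wrms_residual([1.0], [0.0], 1e-8, 0.0)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_quadratic_scaling_in_xdot(self, c):
        x = np.array([1.0, 2.0])
        xd = np.array([0.3, -0.4])
        base = sg.wrms_residual(xd, x, 1e-2, 1e-8)
        assert sg.wrms_residual(c * xd, x, 1e-2, 1e-8) == pytest.approx(c * c * base, rel=1e-9)


class TestEquilibrate:
    def test_production_degradation_closed_form(self):
        m = compile_prod_deg()
        res = sg.equilibrate(m, [2.0, 1.0], [1.0], [0.0])
        assert res.wrms < 1.0
        assert res.x_star[0] == pytest.approx(2.0, rel=1e-6)
        assert res.n_rhs_evals > 0

    def test_conversion_reduced_closed_form(self):
        net = sg.parse_model(
            {
                "species": ["A", "B"],
                "parameters": ["k1", "k2", "a0"],
                "reactions": [
                    {"reactants": {"A": 1}, "products": {"B": 1}, "rate": "k1*A"},
                    {"reactants": {"B": 1}, "products": {"A": 1}, "rate": "k2*B"},
                ],
                "initials": {"A": "a0"},
            }
        )
        m, _ = sg.reduce_model(net)
        th = [2.0, 1.0, 1.0]
        res = sg.equilibrate(m, th, [], m.x0(np.array(th), np.array([])))
        # A* = k2 T / (k1 + k2) = 1/3 (so B* = 2/3)
        assert res.x_star[0] == pytest.approx(1.0 / 3.0, rel=1e-6)

    def test_start_at_steady_state_returns_immediately(self):
        m = compile_prod_deg()
        res = sg.equilibrate(m, [2.0, 1.0], [1.0], [2.0])
        assert res.t_equil == 0.0
        assert res.wrms < 1.0

    def test_stable_linear_systems_match_direct_solve(self):
        """x* agrees with -A^-1 b on seeded Hurwitz systems."""
        for seed in range(5):
            net, params = sg.make_model(sg.FixtureSpec("linear_network", seed=seed, n_x=4))
            m = sg.compile_model(net)
            th = params.nominal
            u = np.array([1.0])
            res = sg.equilibrate(m, th, u, np.zeros(4))
            A = m.jac(np.zeros(4), th, u)  # linear system: jac is A everywhere
            b = m.f(np.zeros(4), th, u)
            x_direct = np.linalg.solve(A, -b)
            assert np.max(np.abs(res.x_star - x_direct) / np.abs(x_direct)) < 1e-6

    def test_newton_polish_never_increases_wrms(self):
        m = compile_prod_deg()
        th, u = [2.0, 1.0], [1.0]
        plain = sg.equilibrate(
            m, th, u, [0.0], sg.EquilibrationSettings(newton_polish=False)
        )
        polished = sg.equilibrate(
            m, th, u, [0.0], sg.EquilibrationSettings(newton_polish=True)
        )
        assert polished.wrms <= plain.wrms
        assert polished.method in ("simulation", "simulation+newton")

    def test_failure_carries_last_wrms(self):
        net = sg.parse_model(
            {"species": ["x"], "parameters": ["k"], "odes": {"x": "k"}}
        )
        m = sg.compile_model(net)
        with pytest.raises(EquilibrationFailure) as exc:
            sg.equilibrate(
                m, [1.0], [], [0.0], sg.EquilibrationSettings(max_doublings=3)
            )
        assert exc.value.wrms >= 1.0


class TestSteadyStateForCondition:
    def test_preequilibration_scales_inflow(self):
        """u_pre halves k_in: x(t0) = 1 for k_in = 2, k_out = 1."""
        m = compile_prod_deg()
        cond = sg.ExperimentCondition(id="c", u=[1.0], u_pre=[0.5])
        res = sg.steady_state_for_condition(m, [2.0, 1.0], cond, phase="pre")
        assert res.x_star[0] == pytest.approx(1.0, rel=1e-6)

    def test_postequilibration_from_timecourse_end(self):
        m = compile_prod_deg()
        cond = sg.ExperimentCondition(id="c", u=[1.0])
        cond.requires_postequilibration = True
        res = sg.steady_state_for_condition(
            m, [2.0, 1.0], cond, phase="post", x_timecourse_end=[0.5]
        )
        direct = sg.equilibrate(m, [2.0, 1.0], [1.0], [0.5])
        assert res.x_star[0] == pytest.approx(direct.x_star[0], rel=1e-10)

    def test_condition_without_flags_is_an_error(self):
        m = compile_prod_deg()
        cond = sg.ExperimentCondition(id="c", u=[1.0])
        with pytest.raises(ValueError, match="no pre-equilibration"):
            sg.steady_state_for_condition(m, [2.0, 1.0], cond, phase="pre")
        with pytest.raises(ValueError, match="no post-equilibration"):
            sg.steady_state_for_condition(m, [2.0, 1.0], cond, phase="post")

    def test_failure_is_tagged_with_phase(self):
        net = sg.parse_model(
            {"species": ["x"], "parameters": ["k"], "inputs": ["s"], "odes": {"x": "k*s"}}
        )
        m = sg.compile_model(net)
        cond = sg.ExperimentCondition(id="c", u=[1.0], u_pre=[1.0])
        with pytest.raises(EquilibrationFailure) as exc:
            sg.steady_state_for_condition(
                m, [1.0], cond, sg.EquilibrationSettings(max_doublings=2), phase="pre"
            )
        assert exc.value.phase == "pre"
        assert "'c'" in str(exc.value)
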