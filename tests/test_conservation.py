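"""Conserved-quantity detection, model reduction and singularity checks."""

import numpy as np
import pytest
import sympy as sp

import steadygrad as sg
from steadygrad.conservation import SingularJacobian


def conversion_network(with_a0=True):
    return sg.parse_model(
        {
            "species": ["A", "B"],
            "parameters": ["k1", "k2", "a0"] if with_a0 else ["k1", "k2"],
            "reactions": [
                {"reactants": {"A": 1}, "products": {"B": 1}, "rate": "k1*A"},
                {"reactants": {"B": 1}, "products": {"A": 1}, "rate": "k2*B"},
            ],
            "initials": {"A": "a0" if with_a0 else 1},
        }
    )


class TestFindConservedQuantities:
    def test_conversion_total(self):
        an = sg.find_conserved_quantities(np.array([[-1, 1], [1, -1]]))
        assert an.n_c == 1
        assert an.L.tolist() == [[1, 1]]
        assert (an.L @ np.array([[-1, 1], [1, -1]]) == 0).all()

    def test_untouched_species(self):
        an = sg.find_conserved_quantities(np.array([[1], [0]]))
        assert an.n_c == 1
        assert an.L.tolist() == [[0, 1]]

    def test_full_row_rank_matrix_has_no_laws(self):
        # independent rank oracle: numpy SVD on a seeded random integer matrix
        rng = np.random.default_rng(5)
        while True:
            S = rng.integers(-3, 4, size=(5, 8))
            if np.linalg.matrix_rank(S.astype(float)) == 5:
                break
        an = sg.find_conserved_quantities(S)
        assert an.n_c == 0

    def test_L_annihilates_S_exactly(self):
        rng = np.random.default_rng(3)
        v = rng.integers(-2, 3, size=(6, 3))
        S = np.hstack([v, v[:, :1] - v[:, 1:2]])  # engineered rank deficiency in columns
        an = sg.find_conserved_quantities(S)
        assert (an.L @ S == 0).all()
        assert an.n_c == 6 - np.linalg.matrix_rank(S.astype(float))

    def test_elimination_prefers_largest_coefficient(self):
        an = sg.find_conserved_quantities(np.array([[-2], [1]]))  # L = [1, 2]
        assert an.L.tolist() == [[1, 2]]
        assert an.eliminated_indices == (1,)


class TestReduceModel:
    def test_conversion_reduced_rhs_and_jacobian(self):
        model, an = sg.reduce_model(conversion_network())
        assert an.n_c == 1
        assert model.species_ids == ("A",)
        x = np.array([0.25])
        th = np.array([2.0, 1.0, 1.0])  # k1, k2, a0 -> T = a0 = 1
        u = np.array([])
        # f_A = -k1 A + k2 (T - A);  jac = -(k1 + k2)
        assert model.f(x, th, u) == pytest.approx([-2.0 * 0.25 + 1.0 * 0.75])
        assert model.jac(x, th, u) == pytest.approx(np.array([[-3.0]]))

    def test_no_laws_is_identity(self):
        net, _ = sg.make_model(sg.FixtureSpec("mm_chain"))
        reduced, an = sg.reduce_network(net)
        assert an.n_c == 0
        assert reduced is net

    def test_total_theta_dependence_propagates(self):
        """dT/da0 enters the reduced df/dtheta; checked by finite differences."""
        model, _ = sg.reduce_model(conversion_network())
        x = np.array([0.4])
        th = np.array([2.0, 1.0, 1.5])
        u = np.array([])
        dfdth = model.dfdtheta(x, th, u)
        fd = np.empty(3)
        for k in range(3):
            h = 1e-7
            tp, tm = th.copy(), th.copy()
            tp[k] += h
            tm[k] -= h
            fd[k] = (model.f(x, tp, u)[0] - model.f(x, tm, u)[0]) / (2 * h)
        assert dfdth[0] == pytest.approx(fd, rel=1e-6, abs=1e-8)
        assert dfdth[0, 2] == pytest.approx(1.0)  # k2 * dT/da0 = k2 = 1

    def test_full_and_reduced_simulations_agree(self):
        """Kept-state trajectories match between full and reduced models."""
        net = conversion_network()
        full = sg.compile_model(net)
        red, an = sg.reduce_model(net)
        th = np.array([2.0, 1.0, 1.0])
        u = np.array([])
        from scipy.integrate import solve_ivp

        ts = np.linspace(0, 5, 20)
        x0_full = full.x0(th, u)
        sol_full = solve_ivp(
            lambda t, x: full.f(x, th, u), (0, 5), x0_full, t_eval=ts,
            method="BDF", rtol=1e-10, atol=1e-12,
        )
        sol_red = solve_ivp(
            lambda t, x: red.f(x, th, u), (0, 5), red.x0(th, u), t_eval=ts,
            method="BDF", rtol=1e-10, atol=1e-12,
        )
        k = an.kept_indices[0]
        assert np.max(np.abs(sol_full.y[k] - sol_red.y[0])) < 1e-8
        # L x(t) stays at the total along the full trajectory
        totals = an.L @ sol_full.y
        assert np.max(np.abs(totals - (an.L @ x0_full)[:, None])) < 1e-8

    def test_L_annihilates_f_symbolically(self):
        net = conversion_network()
        an = sg.find_conserved_quantities(net.stoichiometry)
        f = sp.Matrix(net.f_exprs)
        assert sp.simplify((sp.Matrix(an.L.tolist()) * f)[0]) == 0


class TestAssertNonsingular:
    def test_singular_matrix_raises(self):
        with pytest.raises(SingularJacobian, match="conserved quantities"):
            sg.assert_nonsingular(np.array([[-1.0, 1.0], [1.0, -1.0]]) * 3.0)

    def test_negative_identity_passes(self):
        assert sg.assert_nonsingular(-np.eye(3)) == pytest.approx(1.0)

    def test_conversion_full_vs_reduced_jacobian(self):
        net = conversion_network()
        full = sg.compile_model(net)
        red, _ = sg.reduce_model(net)
        th = np.array([2.0, 1.0, 1.0])
        u = np.array([])
        x_ss_full = np.array([1.0 / 3.0, 2.0 / 3.0])
        with pytest.raises(SingularJacobian):
            sg.assert_nonsingular(full.jac(x_ss_full, th, u))
        assert sg.assert_nonsingular(red.jac(np.array([1.0 / 3.0]), th, u)) > 1e-10

    def test_raw_ode_model_skips_moiety_detection(self):
        net = sg.parse_model(
            {"species": ["x"], "parameters": ["k"], "odes": {"x": "-k*x"}}
        )
        with pytest.warns(UserWarning, match="no reaction structure"):
            reduced, an = sg.reduce_network(net)
        assert an.n_c == 0
        assert reduced is net
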