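"""Model parsing, symbolic compilation and parameter scales."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, strategies as st

import steadygrad as sg
from steadygrad.model import ModelDefinitionError, ScaleDomainError


def conversion_network():
    return sg.parse_model(
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


class TestParsing:
    def test_conversion_reaction_stoichiometry(self):
        net = conversion_network()
        assert net.stoichiometry.tolist() == [[-1, 1], [1, -1]]
        A, B, k1, k2 = sp.symbols("A B k1 k2")
        assert net.rates == [k1 * A, k2 * B]
        # f = S v as a symbolic identity
        assert [sp.expand(e) for e in net.f_exprs] == [
            sp.expand(-k1 * A + k2 * B),
            sp.expand(k1 * A - k2 * B),
        ]

    def test_raw_ode_passthrough(self):
        net = sg.parse_model(
            {
                "species": ["x"],
                "parameters": ["k_in", "k_out"],
                "odes": {"x": "k_in - k_out*x"},
            }
        )
        x, k_in, k_out = sp.symbols("x k_in k_out")
        assert sp.expand(net.f_exprs[0]) == sp.expand(k_in - k_out * x)

    def test_undeclared_symbol_is_named(self):
        with pytest.raises(ModelDefinitionError, match="k9"):
            sg.parse_model(
                {"species": ["x"], "parameters": ["k1"], "odes": {"x": "k9*x"}}
            )

    def test_duplicate_species_rejected(self):
        with pytest.raises(ModelDefinitionError, match="duplicate"):
            sg.parse_model({"species": ["A", "A"], "parameters": []})

    def test_wrong_format_header_rejected(self):
        with pytest.raises(ModelDefinitionError, match="format"):
            sg.parse_model({"format": "other-v9", "species": ["A"]})


class TestCompile:
    def test_production_degradation_derivatives(self):
        net = sg.parse_model(
            {"species": ["x"], "parameters": ["k_in", "k_out"], "odes": {"x": "k_in - k_out*x"}}
        )
        m = sg.compile_model(net)
        x = np.array([3.0])
        th = np.array([2.0, 1.0])
        u = np.array([])
        assert m.jac(x, th, u) == pytest.approx(np.array([[-1.0]]))
        assert m.dfdtheta(x, th, u) == pytest.approx(np.array([[1.0, -3.0]]))

    def test_conversion_jacobian(self):
        m = sg.compile_model(conversion_network())
        x = np.array([0.3, 0.7])
        th = np.array([2.0, 1.0])
        u = np.array([])
        assert m.jac(x, th, u) == pytest.approx(np.array([[-2.0, 1.0], [2.0, -1.0]]))

    def test_projection_observable(self):
        net = sg.parse_model(
            {
                "species": ["x1", "x2"],
                "parameters": ["k"],
                "odes": {"x1": "-k*x1", "x2": "k*x1"},
                "observables": {"y": "x2"},
            }
        )
        m = sg.compile_model(net)
        x, th, u = np.array([1.0, 2.0]), np.array([0.5]), np.array([])
        assert m.dhdx(x, th, u) == pytest.approx(np.array([[0.0, 1.0]]))
        assert m.dhdtheta(x, th, u) == pytest.approx(np.array([[0.0]]))

    @pytest.mark.parametrize("kind", ["conversion", "mm_chain", "linear_network"])
    def test_symbolic_derivatives_match_finite_differences(self, kind):
        """jac and dfdtheta agree with central differences at 20 random points."""
        net, params = sg.make_model(sg.FixtureSpec(kind, seed=1))
        m = sg.compile_model(net)
        rng = np.random.default_rng(11)
        u = np.ones(m.n_u)
        for _ in range(20):
            x = rng.uniform(0.2, 2.0, m.n_x)
            th = rng.uniform(0.5, 2.0, m.n_theta)
            jac_fd = np.empty((m.n_x, m.n_x))
            for j in range(m.n_x):
                h = 1e-6 * (1.0 + abs(x[j]))
                xp, xm = x.copy(), x.copy()
                xp[j] += h
                xm[j] -= h
                jac_fd[:, j] = (m.f(xp, th, u) - m.f(xm, th, u)) / (2 * h)
            scale = 1.0 + np.abs(m.jac(x, th, u))
            assert np.max(np.abs(m.jac(x, th, u) - jac_fd) / scale) < 1e-6
            dfdth_fd = np.empty((m.n_x, m.n_theta))
            for k in range(m.n_theta):
                h = 1e-6 * (1.0 + abs(th[k]))
                tp, tm = th.copy(), th.copy()
                tp[k] += h
                tm[k] -= h
                dfdth_fd[:, k] = (m.f(x, tp, u) - m.f(x, tm, u)) / (2 * h)
            scale = 1.0 + np.abs(m.dfdtheta(x, th, u))
            assert np.max(np.abs(m.dfdtheta(x, th, u) - dfdth_fd) / scale) < 1e-6


class TestScales:
    def test_log10_zero_maps_to_one(self):
        assert sg.apply_scale([0.0], ["log10"]) == pytest.approx([1.0])

    def test_chain_rule_log10(self):
        # d(10^s)/ds at theta=2: unit linear gradient becomes 2 ln 10
        g = sg.chain_rule([1.0], [2.0], ["log10"])
        assert g == pytest.approx([2.0 * np.log(10.0)])
        # cross-check by finite differences of s -> J(10^s)
        s0 = np.log10(2.0)
        h = 1e-7
        fd = ((10 ** (s0 + h)) - (10 ** (s0 - h))) / (2 * h)  # J(theta) = theta
        assert g[0] == pytest.approx(fd, rel=1e-6)

    def test_linear_scales_are_identity(self):
        g = np.array([1.5, -2.0])
        assert sg.chain_rule(g, [3.0, 4.0], ["lin", "lin"]) == pytest.approx(g)

    def test_non_positive_log10_value_rejected(self):
        with pytest.raises(ScaleDomainError):
            sg.to_estimation_scale([-1.0], ["log10"])

    @given(st.floats(min_value=-6.0, max_value=6.0), st.sampled_from(["lin", "log10"]))
    def test_scale_round_trip(self, value, scale):
        linear = sg.apply_scale([value], [scale])
        back = sg.to_estimation_scale(linear, [scale])
        assert back[0] == pytest.approx(value, rel=1e-12, abs=1e-12)


class TestParameterSet:
    def test_bounds_validation(self):
        with pytest.raises(ValueError, match="outside bounds"):
            sg.ParameterSet(["k"], [10.0], ["lin"], [0.0], [1.0])
        with pytest.raises(ScaleDomainError):
            sg.ParameterSet(["k"], [1.0], ["log10"], [-1.0], [10.0])

    def test_estimation_bounds(self):
        p = sg.ParameterSet(["k"], [1.0], ["log10"], [1e-3], [1e3])
        lb, ub = p.bounds_estimation()
        assert lb == pytest.approx([-3.0])
        assert ub == pytest.approx([3.0])
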