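import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

import steadygrad as sg

hyp_settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
hyp_settings.load_profile("ci")

warnings.filterwarnings("ignore", message="Newton polish failed")


def relative_difference(g1, g2) -> float:
    """Scale-relative max difference between two gradient vectors."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    norm = max(np.max(np.abs(g1)), np.max(np.abs(g2)), 1e-300)
    return float(np.max(np.abs(g1 - g2)) / norm)


def make_prod_deg_ss_problem():
    """Production-degradation with one steady-state datum ybar*=3, sigma=1.

    The closed-form gradient at (k_in, k_out) = (2, 1) is (-1, +2) on the
    linear scale: dJ/dtheta = -(ybar* - k_in/k_out) d(k_in/k_out)/dtheta.
    """
    network = sg.parse_model(
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
    params = sg.ParameterSet(
        ids=["k_in", "k_out"],
        nominal=[2.0, 1.0],
        scales=["lin", "lin"],
        lower=[1e-3, 1e-3],
        upper=[1e3, 1e3],
    )
    cond = sg.ExperimentCondition(id="c0", u=[1.0])
    table = sg.MeasurementTable.from_records([("c0", "obs_X", np.inf, 3.0, 1.0)])
    return sg.Problem(network, [cond], table, params)


@pytest.fixture(scope="session")
def prod_deg_ss_problem():
    return make_prod_deg_ss_problem()


@pytest.fixture(scope="session")
def suite():
    """The seeded cross-validation suite of 13 fixture problems."""
    return sg.fixture_suite(seed=0)


@pytest.fixture(scope="session")
def suite_gradients(suite):
    """Gradients of every suite problem by every method (computed once)."""
    out = {}
    for spb in suite:
        grads = {
            m: sg.gradient(spb.problem, spb.theta_eval, method=m)
            for m in ("ssasa", "forward", "fd", "asa")
        }
        out[spb.name] = grads
    return out
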