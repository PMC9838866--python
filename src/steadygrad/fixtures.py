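"""Seeded synthetic models and datasets for testing and validation.

Every fixture has, by construction, an exponentially stable steady state
(Hurwitz Jacobian after moiety reduction, verified at generation time) and
Gaussian measurement noise — the statistical structure the steady-state
adjoint method assumes.  Four model kinds are provided:

``production_degradation``
    one state, f = s*k_in - k_out*x; closed-form steady state s*k_in/k_out.
``conversion``
    A <-> B with one conserved total (exercises moiety reduction; the
    unreduced steady-state Jacobian is singular).
``linear_network``
    seeded random stable linear system xdot = r*A x + s*b with A strictly
    diagonally dominant (Gershgorin guarantees a Hurwitz matrix).
``mm_chain``
    three-state Michaelis-Menten chain (nonlinear, full-rank stoichiometry).

Time points are log-spaced over [0.1, 10] model time units, because
equilibrating systems change on logarithmic time scales.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .equilibration import EquilibrationSettings, equilibrate
from .model import ParameterSet, ReactionNetwork, compile_model, parse_model, to_estimation_scale
from .problem import ExperimentCondition, MeasurementTable, Problem

__all__ = ["FixtureSpec", "make_model", "make_data", "make_problem", "fixture_suite", "SuiteProblem"]

KINDS = ("production_degradation", "conversion", "linear_network", "mm_chain")


@dataclasses.dataclass
class FixtureSpec:
    kind: str = "production_degradation"
    n_x: int = 5  # linear_network only
    seed: int = 0
    sigma: float = 0.1
    n_timepoints: int = 8
    equilibration: str = "none"  # none | pre | post | both

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.equilibration not in ("none", "pre", "post", "both"):
            raise ValueError(f"unknown equilibration mode {self.equilibration!r}")


def _bounds(ids) -> dict:
    return dict(lower=np.full(len(ids), 1e-3), upper=np.full(len(ids), 1e3))


def _build(spec: FixtureSpec, rng: np.random.Generator):
    if spec.kind == "production_degradation":
        network = parse_model(
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
        theta_true = np.array([2.0, 1.0])
    elif spec.kind == "conversion":
        network = parse_model(
            {
                "species": ["A", "B"],
                "parameters": ["k1", "k2", "a0"],
                "inputs": ["s"],
                "reactions": [
                    {"reactants": {"A": 1}, "products": {"B": 1}, "rate": "s*k1*A"},
                    {"reactants": {"B": 1}, "products": {"A": 1}, "rate": "k2*B"},
                ],
                "initials": {"A": "a0"},
                "observables": {"obs_A": "A", "obs_B": "B"},
            }
        )
        theta_true = np.array([2.0, 1.0, 1.0])
    elif spec.kind == "linear_network":
        n = spec.n_x
        M = rng.uniform(0.2, 1.0, size=(n, n))
        np.fill_diagonal(M, 0.0)
        A = M - np.diag(M.sum(axis=1) + 0.5)
        b_true = rng.uniform(0.5, 1.5, size=n)
        species = [f"X{i+1}" for i in range(n)]
        params = ["r"] + [f"b{i+1}" for i in range(n)]
        odes = {}
        for i in range(n):
            terms = " + ".join(f"({float(A[i, j])!r})*{species[j]}" for j in range(n))
            odes[species[i]] = f"r*({terms}) + s*b{i+1}"
        network = parse_model(
            {
                "species": species,
                "parameters": params,
                "inputs": ["s"],
                "odes": odes,
                "observables": {f"obs_{sp}": sp for sp in species},
            }
        )
        theta_true = np.concatenate([[1.0], b_true])
    else:  # mm_chain
        network = parse_model(
            {
                "species": ["S1", "S2", "S3"],
                "parameters": ["k0", "V1", "K1", "V2", "K2", "k3"],
                "inputs": ["s"],
                "reactions": [
                    {"products": {"S1": 1}, "rate": "s*k0"},
                    {"reactants": {"S1": 1}, "products": {"S2": 1}, "rate": "V1*S1/(K1 + S1)"},
                    {"reactants": {"S2": 1}, "products": {"S3": 1}, "rate": "V2*S2/(K2 + S2)"},
                    {"reactants": {"S3": 1}, "rate": "k3*S3"},
                ],
                "observables": {"obs_S1": "S1", "obs_S2": "S2", "obs_S3": "S3"},
            }
        )
        theta_true = np.array([1.0, 3.0, 1.0, 4.0, 2.0, 1.0])
    ids = list(network.parameters)
    params = ParameterSet(
        ids=ids,
        nominal=theta_true,
        scales=["log10"] * len(ids),
        **_bounds(ids),
    )
    return network, params


def _verify_stable(network: ReactionNetwork, theta_true: np.ndarray) -> bool:
    """Hurwitz check of the (moiety-reduced) Jacobian at the steady state."""
    from .conservation import reduce_model

    if network.stoichiometry.shape[1] > 0:
        model, _ = reduce_model(network)
    else:
        model = compile_model(network)
    u = model.extend_inputs(np.ones(model.n_u_base), np.ones(model.n_u_base))
    x0 = model.x0(theta_true, u)
    res = equilibrate(model, theta_true, u, x0, EquilibrationSettings())
    eig = np.linalg.eigvals(model.jac(res.x_star, theta_true, u))
    return bool(np.all(eig.real < 0))


def make_model(spec: FixtureSpec):
    """Generate a seeded model with a verified exponentially stable steady state.

    Returns ``(network, parameters)`` with the true parameters as nominal
    values (log10 scale, bounds [1e-3, 1e3]).  If the stability check fails,
    the model is regenerated with the next sub-seed, at most 10 times.
    """
    for attempt in range(10):
        rng = np.random.default_rng((spec.seed + 1000 * attempt) % 2**31)
        network, params = _build(spec, rng)
        if _verify_stable(network, params.nominal):
            return network, params
    raise RuntimeError(f"could not generate a stable '{spec.kind}' fixture (seed {spec.seed})")


def make_condition(spec: FixtureSpec) -> ExperimentCondition:
    u_pre = np.array([0.5]) if spec.equilibration in ("pre", "both") else None
    return ExperimentCondition(id="c0", u=np.array([1.0]), u_pre=u_pre)


def _timepoints(spec: FixtureSpec) -> np.ndarray:
    if spec.n_timepoints <= 0:
        return np.array([])
    return np.logspace(-1.0, 1.0, spec.n_timepoints)


def make_data(network: ReactionNetwork, theta_true, spec: FixtureSpec) -> MeasurementTable:
    """Simulate at the true parameters and add seeded Gaussian noise.

    Emits time-course rows at log-spaced times (unless ``n_timepoints`` is
    zero) and steady-state rows for post-equilibrating modes.  With
    ``sigma = 0`` the recorded values equal the noiseless simulation exactly
    (the recorded noise level then defaults to 1 so likelihoods stay
    defined).
    """
    from .settings import SolverSettings
    from .simulate import simulate_condition

    if network.stoichiometry.shape[1] > 0:
        from .conservation import reduce_model

        model, analysis = reduce_model(network)
        network_sim = model.network if analysis.n_c else network
    else:
        network_sim = network
        model = compile_model(network)

    cond = make_condition(spec)
    times = _timepoints(spec)
    obs_ids = list(model.observable_ids)
    sigma_record = spec.sigma if spec.sigma > 0 else 1.0
    rows = []
    for t in times:
        for o in obs_ids:
            rows.append((cond.id, o, float(t), 0.0, sigma_record))
    if spec.equilibration in ("post", "both"):
        for o in obs_ids:
            rows.append((cond.id, o, np.inf, 0.0, sigma_record))
    if not rows:
        raise ValueError("fixture would have no measurements; check n_timepoints/equilibration")
    table = MeasurementTable.from_records(rows)

    prob = Problem(
        network=network_sim,
        conditions=[cond],
        measurements=table,
        parameters=ParameterSet(
            ids=list(network.parameters),
            nominal=np.asarray(theta_true, dtype=float),
            scales=["log10"] * len(network.parameters),
            **_bounds(network.parameters),
        ),
        model=model,
    )
    sim = simulate_condition(prob, np.asarray(theta_true, dtype=float), cond, SolverSettings())
    d = prob.condition_data(cond.id)

    rng = np.random.default_rng((spec.seed + 7919) % 2**31)
    values = np.empty(len(table))
    df = table.df
    k_tc = 0
    k_ss = 0
    for idx in range(len(df)):
        if np.isfinite(df.loc[idx, "time"]):
            y = sim.y_at_times[d.tc_time_index[k_tc], d.tc_obs_index[k_tc]]
            k_tc += 1
        else:
            y = sim.y_star[d.ss_obs_index[k_ss]]
            k_ss += 1
        values[idx] = y + (rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0)
    df["value"] = values
    return MeasurementTable(df)


def make_problem(spec: FixtureSpec, reduce: bool = True):
    """Assemble a complete seeded problem; returns ``(problem, theta_true_est)``.

    Conserved moieties are removed by default so the steady-state adjoint
    method is applicable; pass ``reduce=False`` to keep the full model (used
    to exercise the singular-Jacobian error path).
    """
    network, params = make_model(spec)
    table = make_data(network, params.nominal, spec)
    problem = Problem(
        network=network,
        conditions=[make_condition(spec)],
        measurements=table,
        parameters=params,
    )
    if reduce:
        problem = problem.reduced()
    return problem, to_estimation_scale(params.nominal, params.scales)


@dataclasses.dataclass
class SuiteProblem:
    name: str
    spec: FixtureSpec
    problem: Problem
    theta_true: np.ndarray  # estimation scale
    theta_eval: np.ndarray  # estimation scale, perturbed off the truth


def fixture_suite(seed: int = 0, sigma: float = 0.1) -> list[SuiteProblem]:
    """Seeded cross-validation suite covering all equilibration modes.

    Thirteen problems: production-degradation, conversion (with a conserved
    moiety, reduced), a 5-state random stable linear network and the
    Michaelis-Menten chain, in pre-, post-, both- and no-equilibration
    variants.  Gradients are compared at a perturbed point ``theta_eval``
    (true parameters plus up to 0.2 log10 units) so residuals are nonzero.
    """
    presets = [
        ("prod_deg/none", FixtureSpec("production_degradation", seed=seed, sigma=sigma)),
        ("prod_deg/post", FixtureSpec("production_degradation", seed=seed, sigma=sigma, equilibration="post")),
        ("prod_deg/ss_only", FixtureSpec("production_degradation", seed=seed, sigma=sigma, n_timepoints=0, equilibration="post")),
        ("prod_deg/pre", FixtureSpec("production_degradation", seed=seed, sigma=sigma, equilibration="pre")),
        ("prod_deg/both", FixtureSpec("production_degradation", seed=seed, sigma=sigma, equilibration="both")),
        ("conversion/none", FixtureSpec("conversion", seed=seed, sigma=sigma)),
        # steady-state-only data: with time-course data to t = 10 the fast
        # conversion kinetics are already equilibrated at the last time point,
        # leaving no post-equilibration span to exercise
        ("conversion/ss_only", FixtureSpec("conversion", seed=seed, sigma=sigma, n_timepoints=0, equilibration="post")),
        ("conversion/both", FixtureSpec("conversion", seed=seed, sigma=sigma, equilibration="both")),
        ("linear/none", FixtureSpec("linear_network", seed=seed + 1, sigma=sigma)),
        ("linear/post", FixtureSpec("linear_network", seed=seed + 2, sigma=sigma, equilibration="post")),
        ("linear/pre", FixtureSpec("linear_network", seed=seed + 3, sigma=sigma, equilibration="pre")),
        ("mm_chain/post", FixtureSpec("mm_chain", seed=seed, sigma=sigma, equilibration="post")),
        ("mm_chain/both", FixtureSpec("mm_chain", seed=seed, sigma=sigma, equilibration="both")),
    ]
    out = []
    for i, (name, spec) in enumerate(presets):
        problem, theta_true = make_problem(spec)
        rng = np.random.default_rng((spec.seed * 131 + 17 * i + 5) % 2**31)
        lb, ub = problem.parameters.bounds_estimation()
        theta_eval = np.clip(theta_true + rng.uniform(-0.2, 0.2, theta_true.size), lb, ub)
        out.append(SuiteProblem(name, spec, problem, theta_true, theta_eval))
    return out
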