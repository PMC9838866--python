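"""Negative log-likelihood, gradient assembly and multi-start estimation.

For independent Gaussian noise the objective is

    J(theta) = 1/2 sum [ log(2 pi sigma^2) + ((ybar - y)/sigma)^2 ]

summed over time-course and steady-state measurement rows alike.  The
constant log terms are kept so that printed objective values are comparable
across runs.  Gradients on the estimation scale are obtained from the
linear-scale gradient by the chain rule (log10 entries multiplied by
theta*ln 10), applied last.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import minimize

from .equilibration import Counters, EquilibrationFailure
from .model import chain_rule
from .problem import MeasurementTable, Problem
from .settings import SolverSettings
from .simulate import simulate_condition

__all__ = [
    "ObjectiveValue",
    "GradientResult",
    "negative_log_likelihood",
    "objective_value",
    "assemble_gradient",
    "estimate",
    "StartResult",
    "EstimationReport",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclasses.dataclass
class ObjectiveValue:
    nll: float
    per_condition: dict[str, float]


@dataclasses.dataclass
class GradientResult:
    """Objective value, gradient, per-segment method tags and work counters."""

    nll: float
    gradient: np.ndarray  # estimation scale
    gradient_linear: np.ndarray
    method: str
    condition_methods: dict[str, dict[str, str]]
    counters: dict[str, int]
    per_condition: dict[str, float]
    linear_solves: list = dataclasses.field(default_factory=list)

    def as_dict(self, parameter_ids) -> dict:
        return {
            "nll": self.nll,
            "method": self.method,
            "gradient": dict(zip(parameter_ids, map(float, self.gradient))),
            "gradient_linear": dict(zip(parameter_ids, map(float, self.gradient_linear))),
            "condition_methods": self.condition_methods,
            "counters": dict(self.counters),
        }


def _nll_terms(values_sim, values_meas, sigmas) -> float:
    values_sim = np.asarray(values_sim, dtype=float)
    r = (np.asarray(values_meas, dtype=float) - values_sim) / np.asarray(sigmas, dtype=float)
    return float(0.5 * np.sum(_LOG2PI + 2.0 * np.log(sigmas) + r**2))


def negative_log_likelihood(simulated, table: MeasurementTable) -> ObjectiveValue:
    """Objective from simulated values aligned with the measurement rows.

    ``simulated`` must have one finite entry per table row (in table row
    order); a missing or non-finite entry raises an error naming the row.
    """
    sim = np.asarray(simulated, dtype=float)
    if sim.shape != (len(table),):
        raise ValueError(
            f"need one simulated value per measurement row ({len(table)}), got shape {sim.shape}"
        )
    bad = np.flatnonzero(~np.isfinite(sim))
    if bad.size:
        row = table.df.iloc[bad[0]]
        raise ValueError(
            f"missing/non-finite simulation for measurement row {bad[0]} "
            f"(condition '{row.condition_id}', observable '{row.observable_id}', t={row.time})"
        )
    per_condition: dict[str, float] = {}
    for cid in table.condition_ids:
        mask = (table.df["condition_id"] == cid).to_numpy()
        per_condition[cid] = _nll_terms(
            sim[mask], table.df["value"].to_numpy()[mask], table.df["sigma"].to_numpy()[mask]
        )
    return ObjectiveValue(nll=float(sum(per_condition.values())), per_condition=per_condition)


def nll_condition(sim) -> float:
    """Objective contribution of one simulated condition."""
    d = sim.data
    total = 0.0
    if d.tc_value.size:
        y = sim.y_at_times[d.tc_time_index, d.tc_obs_index]
        total += _nll_terms(y, d.tc_value, d.tc_sigma)
    if d.ss_value.size:
        total += _nll_terms(sim.y_star[d.ss_obs_index], d.ss_value, d.ss_sigma)
    return total


def objective_value(
    problem: Problem,
    theta_est,
    settings: SolverSettings | None = None,
    counters: Counters | None = None,
) -> ObjectiveValue:
    """Simulate every condition and evaluate the objective."""
    settings = settings or SolverSettings()
    theta_lin = problem.parameters.to_linear(theta_est)
    per = {}
    for cond in problem.conditions:
        sim = simulate_condition(problem, theta_lin, cond, settings, counters)
        per[cond.id] = nll_condition(sim)
    return ObjectiveValue(nll=float(sum(per.values())), per_condition=per)


def assemble_gradient(direct_terms, adjoint_contributions, x0_term, scales, theta_lin) -> np.ndarray:
    """Sum the gradient pieces of one problem and apply the scale chain rule.

    ``direct_terms`` are the data terms through dh/dtheta, the adjoint
    contributions carry the quadrature / linear-solve terms, and ``x0_term``
    is -p(t0)^T dx0/dtheta (zero under pre-equilibration, where it is
    replaced by the pre-equilibration contribution).
    """
    total = np.array(x0_term, dtype=float)
    for name, term in list(direct_terms.items()) + list(adjoint_contributions.items()):
        term = np.asarray(term, dtype=float)
        if np.any(~np.isfinite(term)):
            raise ValueError(f"non-finite gradient contribution in term '{name}'")
        total = total + term
    return chain_rule(total, theta_lin, scales)


# ---------------------------------------------------------------------------
# multi-start estimation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StartResult:
    start_index: int
    theta0: np.ndarray  # estimation scale, full vector
    theta: np.ndarray  # estimation scale, full vector
    nll: float
    grad_norm: float
    n_iterations: int
    converged: bool
    message: str


@dataclasses.dataclass
class EstimationReport:
    starts: list[StartResult]  # sorted by final nll
    seed: int
    gradient_method: str

    @property
    def best(self) -> StartResult:
        return self.starts[0]


def estimate(
    problem: Problem,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 100,
    gradient_method: str = "ssasa",
    settings: SolverSettings | None = None,
    start_points=None,
) -> EstimationReport:
    """Multi-start bounded local optimization of the negative log-likelihood.

    Start points are drawn uniformly within the bounds on the estimation
    scale with a seeded generator (reproducible); each start runs a bounded
    quasi-Newton optimizer (L-BFGS-B) driven by the selected gradient method.
    Fixed parameters (estimate flag off) are held at their nominal values.
    """
    from .api import gradient as gradient_fn  # late import avoids a cycle

    settings = settings or SolverSettings()
    params = problem.parameters
    free = np.flatnonzero(params.estimate)
    if free.size == 0:
        raise ValueError("no free parameters to estimate")
    lb, ub = params.bounds_estimation()
    nominal_est = params.nominal_estimation()
    if start_points is not None:
        starts0 = np.atleast_2d(np.asarray(start_points, dtype=float))[:, free]
        n_starts = starts0.shape[0]
    else:
        rng = np.random.default_rng(seed)
        starts0 = lb[free] + rng.uniform(size=(n_starts, free.size)) * (ub[free] - lb[free])

    def full(theta_free):
        th = nominal_est.copy()
        th[free] = theta_free
        return th

    def fun(theta_free):
        try:
            res = gradient_fn(problem, full(theta_free), method=gradient_method, settings=settings)
        except (EquilibrationFailure, np.linalg.LinAlgError, RuntimeError):
            return 1e10, np.zeros(free.size)
        return res.nll, res.gradient[free]

    results: list[StartResult] = []
    failures: list[str] = []
    for k in range(n_starts):
        opt = minimize(
            fun,
            starts0[k],
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lb[free], ub[free])),
            options={"maxiter": max_iter, "maxfun": 5 * max_iter + 50},
        )
        theta_free = np.clip(opt.x, lb[free], ub[free])
        if not np.isfinite(opt.fun) or opt.fun >= 1e10:
            failures.append(f"start {k}: {opt.message}")
            continue
        results.append(
            StartResult(
                start_index=k,
                theta0=full(starts0[k]),
                theta=full(theta_free),
                nll=float(opt.fun),
                grad_norm=float(np.max(np.abs(np.atleast_1d(opt.jac)))),
                n_iterations=int(opt.nit),
                converged=bool(opt.success),
                message=str(opt.message),
            )
        )
    if not results:
        raise RuntimeError("all optimization starts failed: " + "; ".join(failures))
    results.sort(key=lambda r: r.nll)
    return EstimationReport(starts=results, seed=seed, gradient_method=gradient_method)
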