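"""Steady-state adjoint sensitivity analysis (ssASA).

At an exponentially stable steady state the adjoint ODE has a constant
Jacobian and p relaxes to zero, so the adjoint quadrature over an
equilibration span collapses to a matrix-vector product: the integral
p_integral = int p dt solves the linear system

    J(x*)^T p_integral = -p_boundary,

where p_boundary is p(t'') (the steady-state measurement jump, post-
equilibration) or p(t0) (the adjoint state handed over by the time-course
backward pass, pre-equilibration).  Backward numerical integration over the
equilibration span is thereby avoided entirely; the backward-RHS counters of
:class:`~steadygrad.objective.GradientResult` make that visible.

The linear solve requires a nonsingular steady-state Jacobian; conserved
moieties are the common obstruction and are removed by
:mod:`steadygrad.conservation`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .adjoint import (
    measurement_jump,
    posteq_tail_backward,
    preeq_tail_backward,
    steady_state_direct_and_boundary,
    timecourse_backward,
    timecourse_direct_term,
)
from .conservation import SingularJacobian, assert_nonsingular
from .equilibration import Counters
from .model import chain_rule
from .objective import GradientResult, nll_condition
from .problem import Problem
from .settings import SolverSettings
from .simulate import simulate_condition

__all__ = [
    "SteadyStateAdjointSolve",
    "posteq_adjoint_contribution",
    "preeq_adjoint_contribution",
    "ssasa_gradient",
]


@dataclasses.dataclass
class SteadyStateAdjointSolve:
    """Diagnostics of one adjoint linear solve at a steady state."""

    p_boundary: np.ndarray
    p_integral: np.ndarray
    jac_at_ss: np.ndarray
    reciprocal_condition: float
    residual: float  # ||J^T p_integral + p_boundary||

    @property
    def residual_ratio(self) -> float:
        return self.residual / (1.0 + float(np.linalg.norm(self.p_boundary)))


def _adjoint_solve(model, x_ss, theta, u, p_boundary, tol, counters) -> SteadyStateAdjointSolve:
    J = model.jac(x_ss, theta, u)
    rcond = assert_nonsingular(J, tol)
    lu, piv = scipy.linalg.lu_factor(J.T)
    p_int = scipy.linalg.lu_solve((lu, piv), -p_boundary)
    counters.add("linear_solves")
    residual = float(np.linalg.norm(J.T @ p_int + p_boundary))
    return SteadyStateAdjointSolve(
        p_boundary=np.array(p_boundary, dtype=float),
        p_integral=p_int,
        jac_at_ss=J,
        reciprocal_condition=rcond,
        residual=residual,
    )


def posteq_adjoint_contribution(
    model,
    x_star,
    theta,
    u,
    ss_residual_terms,
    counters: Counters | None = None,
    nonsingular_tol: float = 1e-10,
):
    """Post-equilibration gradient contribution via one linear solve.

    ``ss_residual_terms`` iterates over ``(observable_index, measured, sigma)``
    at the steady state.  Returns ``(gradient_contribution, p_carry, solve)``;
    the contribution includes the direct steady-state data term
    ``-sum r/sigma^2 dh/dtheta`` and the quadrature term
    ``-p_integral^T df/dtheta`` at ``x*``.  ``p_carry`` is exactly zero: the
    adjoint has relaxed to the stable state p = 0 by the end of the time
    course, so nothing is handed back into the time-course backward pass.
    """
    counters = counters if counters is not None else Counters()
    terms = list(ss_residual_terms)
    p_end = measurement_jump(np.zeros(model.n_x), model, x_star, theta, u, terms)
    solve = _adjoint_solve(model, x_star, theta, u, p_end, nonsingular_tol, counters)
    y = model.h(x_star, theta, u)
    dh = model.dhdtheta(x_star, theta, u)
    direct = np.zeros(model.n_theta)
    for i, measured, sigma in terms:
        direct -= (measured - y[i]) / sigma**2 * dh[i]
    contribution = direct - solve.p_integral @ model.dfdtheta(x_star, theta, u)
    return contribution, np.zeros(model.n_x), solve


def preeq_adjoint_contribution(
    model,
    x_star_pre,
    theta,
    u_pre,
    p_at_t0,
    counters: Counters | None = None,
    nonsingular_tol: float = 1e-10,
):
    """Pre-equilibration gradient contribution via one linear solve.

    ``p_at_t0`` is the adjoint state after the time-course backward pass
    (including any jump at t0).  No initial-state sensitivity term is added:
    the adjoint vanishes at the pre-equilibration start, so its scalar
    product with the initial-state sensitivities is zero.
    """
    counters = counters if counters is not None else Counters()
    p_at_t0 = np.asarray(p_at_t0, dtype=float)
    if not np.any(p_at_t0):
        n = model.n_theta
        solve = SteadyStateAdjointSolve(
            p_boundary=np.zeros(model.n_x),
            p_integral=np.zeros(model.n_x),
            jac_at_ss=model.jac(x_star_pre, theta, u_pre),
            reciprocal_condition=float("nan"),
            residual=0.0,
        )
        return np.zeros(n), solve
    solve = _adjoint_solve(model, x_star_pre, theta, u_pre, p_at_t0, nonsingular_tol, counters)
    contribution = -solve.p_integral @ model.dfdtheta(x_star_pre, theta, u_pre)
    return contribution, solve


def ssasa_gradient(
    problem: Problem,
    theta_est,
    settings: SolverSettings | None = None,
    counters: Counters | None = None,
) -> GradientResult:
    """Objective value and gradient with steady-state adjoint linear solves.

    Per condition: forward simulate (pre-equilibration, time course,
    post-equilibration as required), then assemble the gradient from the
    direct data terms, the post-equilibration linear solve, the standard
    backward pass over the finite time course started from p = 0, the
    pre-equilibration linear solve, and — only when the initial state is an
    explicit function of theta, i.e. without pre-equilibration — the
    ``-p(t0)^T dx0/dtheta`` term.  The parameter-scale chain rule is applied
    last.  Backward RHS evaluations over equilibration spans are zero by
    construction unless the singular-Jacobian fallback is enabled and taken.
    """
    settings = settings or SolverSettings()
    counters = counters if counters is not None else Counters()
    for key in ("backward_rhs_timecourse", "backward_rhs_equilibration", "linear_solves"):
        counters.setdefault(key, 0)
    model = problem.model
    theta = problem.parameters.to_linear(np.asarray(theta_est, dtype=float))

    grad_lin = np.zeros(model.n_theta)
    nll = 0.0
    per_condition: dict[str, float] = {}
    tags: dict[str, dict[str, str]] = {}
    solves: list[SteadyStateAdjointSolve] = []

    for cond in problem.conditions:
        sim = simulate_condition(problem, theta, cond, settings, counters)
        per_condition[cond.id] = nll_condition(sim)
        nll += per_condition[cond.id]
        cond_tags: dict[str, str] = {}
        g = timecourse_direct_term(model, sim, theta)
        d = sim.data

        if cond.requires_postequilibration:
            try:
                contrib, p, solve = posteq_adjoint_contribution(
                    model,
                    sim.x_star,
                    theta,
                    sim.u_main,
                    zip(d.ss_obs_index, d.ss_value, d.ss_sigma),
                    counters,
                    settings.nonsingular_tol,
                )
                g += contrib
                solves.append(solve)
                cond_tags["posteq"] = "ssasa-linear-solve"
            except SingularJacobian:
                if not settings.allow_asa_fallback:
                    raise
                direct_ss, p_end = steady_state_direct_and_boundary(model, sim, theta)
                g += direct_ss
                p, q_tail = posteq_tail_backward(
                    model, sim, theta, p_end, counters, settings, sim.posteq.t_equil
                )
                g -= q_tail
                cond_tags["posteq"] = "asa-backward-fallback"
        else:
            p = np.zeros(model.n_x)

        p, q_tc = timecourse_backward(model, sim, theta, p, counters, settings)
        g -= q_tc
        if d.has_timecourse:
            cond_tags["timecourse"] = "asa-backward"

        if cond.requires_preequilibration:
            try:
                contrib, solve = preeq_adjoint_contribution(
                    model, sim.preeq.x_star, theta, sim.u_pre, p, counters,
                    settings.nonsingular_tol,
                )
                g += contrib
                if np.any(p):
                    solves.append(solve)
                cond_tags["preeq"] = "ssasa-linear-solve"
            except SingularJacobian:
                if not settings.allow_asa_fallback:
                    raise
                p_mt, q_pre = preeq_tail_backward(
                    model, sim, theta, p, counters, settings, sim.preeq.t_equil
                )
                g -= q_pre
                g -= p_mt @ model.dx0dtheta(theta, sim.u_pre)
                cond_tags["preeq"] = "asa-backward-fallback"
        else:
            g -= p @ model.dx0dtheta(theta, sim.u_main)
        grad_lin += g
        tags[cond.id] = cond_tags

    return GradientResult(
        nll=nll,
        gradient=chain_rule(grad_lin, theta, problem.parameters.scales),
        gradient_linear=grad_lin,
        method="ssasa",
        condition_methods=tags,
        counters=dict(counters),
        per_condition=per_condition,
        linear_solves=solves,
    )
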