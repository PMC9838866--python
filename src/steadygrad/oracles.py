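"""Independent gradient oracles: forward sensitivities and finite differences.

Forward sensitivity analysis integrates ds/dt = J s + df/dtheta alongside
the states; at a nonsingular steady state the sensitivities are instead
obtained from one linear solve per parameter, J s*_k = -df/dtheta_k, and
pre-equilibration steady-state sensitivities seed the time course.  The
observable sensitivities dy/dtheta = dh/dx s + dh/dtheta assemble the
gradient directly — no adjoint involved, which makes this path a genuinely
independent cross-check of the adjoint engines (and a usable method in its
own right for small models).  The same observable sensitivities yield the
Fisher information matrix used for practical-identifiability assessment.

Central finite differences on the estimation scale serve as the second,
model-free oracle.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp

from .conservation import assert_nonsingular
from .equilibration import Counters, steady_state_for_condition
from .model import chain_rule
from .objective import GradientResult, _nll_terms
from .problem import Problem
from .settings import SolverSettings

__all__ = [
    "FiniteDifferenceError",
    "steady_state_sensitivities",
    "forward_gradient",
    "fd_gradient",
    "fisher_information",
    "identifiable_parameters",
]

_LN10 = np.log(10.0)


class FiniteDifferenceError(RuntimeError):
    pass


def steady_state_sensitivities(model, x_star, theta, u, nonsingular_tol: float = 1e-10):
    """State sensitivities at a steady state by per-parameter linear solves."""
    J = model.jac(x_star, theta, u)
    assert_nonsingular(J, nonsingular_tol)
    B = model.dfdtheta(x_star, theta, u)
    lu, piv = scipy.linalg.lu_factor(J)
    return scipy.linalg.lu_solve((lu, piv), -B)


def _condition_observable_sensitivities(problem, theta, cond, settings, counters):
    """Per-row simulated values and linear-scale sensitivities dy/dtheta.

    Rows are ordered time-course first, then steady-state, matching the
    per-condition measurement layout.  Returns
    ``(y_rows, dy_rows, values, sigmas, tags)``.
    """
    model = problem.model
    n_x, n_th = model.n_x, model.n_theta
    d = problem.condition_data(cond.id)
    u_init = cond.u_pre if cond.requires_preequilibration else cond.u
    u_main = model.extend_inputs(cond.u, u_init)
    tags: dict[str, str] = {}

    if cond.requires_preequilibration:
        pre = steady_state_for_condition(
            model, theta, cond, settings.equilibration, phase="pre",
            rtol=settings.rtol, atol=settings.atol, counters=counters,
        )
        u_pre = model.extend_inputs(cond.u_pre, cond.u_pre)
        x_t0 = pre.x_star
        s0 = steady_state_sensitivities(model, x_t0, theta, u_pre, settings.nonsingular_tol)
        counters.add("linear_solves")
        tags["preeq"] = "forward-linear-solve"
    else:
        x_t0 = model.x0(theta, u_main)
        s0 = model.dx0dtheta(theta, u_main)

    # time course: augmented system z = [x, vec(s)]
    if d.has_timecourse and d.times[-1] > 0.0:
        def rhs(t, z):
            counters.add("forward_rhs")
            x = z[:n_x]
            s = z[n_x:].reshape(n_x, n_th)
            J = model.jac(x, theta, u_main)
            return np.concatenate(
                [model.f(x, theta, u_main), (J @ s + model.dfdtheta(x, theta, u_main)).ravel()]
            )

        sol = solve_ivp(
            rhs,
            (0.0, float(d.times[-1])),
            np.concatenate([x_t0, np.asarray(s0).ravel()]),
            method="BDF",
            t_eval=d.times,
            rtol=settings.rtol,
            atol=settings.atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"forward sensitivity integration failed for condition "
                f"'{cond.id}': {sol.message}"
            )
        x_at = sol.y[:n_x, :].T
        s_at = sol.y[n_x:, :].T.reshape(d.times.size, n_x, n_th)
        tags["timecourse"] = "forward-ode"
    elif d.has_timecourse:
        x_at = np.tile(x_t0, (d.times.size, 1))
        s_at = np.tile(np.asarray(s0), (d.times.size, 1, 1))
    else:
        x_at = np.zeros((0, n_x))
        s_at = np.zeros((0, n_x, n_th))

    n_rows = d.tc_value.size + d.ss_value.size
    y_rows = np.empty(n_rows)
    dy_rows = np.empty((n_rows, n_th))
    for k, (t_idx, i) in enumerate(zip(d.tc_time_index, d.tc_obs_index)):
        x = x_at[t_idx]
        y_rows[k] = model.h(x, theta, u_main)[i]
        dy_rows[k] = (
            model.dhdx(x, theta, u_main)[i] @ s_at[t_idx]
            + model.dhdtheta(x, theta, u_main)[i]
        )

    if cond.requires_postequilibration:
        x_from = x_at[-1] if d.has_timecourse else x_t0
        post = steady_state_for_condition(
            model, theta, cond, settings.equilibration, phase="post",
            x_timecourse_end=x_from, rtol=settings.rtol, atol=settings.atol,
            counters=counters,
        )
        s_star = steady_state_sensitivities(
            model, post.x_star, theta, u_main, settings.nonsingular_tol
        )
        counters.add("linear_solves")
        tags["posteq"] = "forward-linear-solve"
        y_star = model.h(post.x_star, theta, u_main)
        dhdx = model.dhdx(post.x_star, theta, u_main)
        dhdth = model.dhdtheta(post.x_star, theta, u_main)
        for k, i in enumerate(d.ss_obs_index):
            y_rows[d.tc_value.size + k] = y_star[i]
            dy_rows[d.tc_value.size + k] = dhdx[i] @ s_star + dhdth[i]

    values = np.concatenate([d.tc_value, d.ss_value])
    sigmas = np.concatenate([d.tc_sigma, d.ss_sigma])
    return y_rows, dy_rows, values, sigmas, tags


def forward_gradient(
    problem: Problem,
    theta_est,
    settings: SolverSettings | None = None,
    counters: Counters | None = None,
) -> GradientResult:
    """Gradient via forward sensitivity analysis with steady-state solves."""
    settings = settings or SolverSettings()
    counters = counters if counters is not None else Counters()
    theta = problem.parameters.to_linear(np.asarray(theta_est, dtype=float))

    grad_lin = np.zeros(problem.model.n_theta)
    nll = 0.0
    per_condition: dict[str, float] = {}
    tags: dict[str, dict[str, str]] = {}

    for cond in problem.conditions:
        y, dy, values, sigmas, cond_tags = _condition_observable_sensitivities(
            problem, theta, cond, settings, counters
        )
        grad_lin -= ((values - y) / sigmas**2) @ dy
        cond_nll = _nll_terms(y, values, sigmas)
        nll += cond_nll
        per_condition[cond.id] = cond_nll
        tags[cond.id] = cond_tags

    return GradientResult(
        nll=nll,
        gradient=chain_rule(grad_lin, theta, problem.parameters.scales),
        gradient_linear=grad_lin,
        method="forward",
        condition_methods=tags,
        counters=dict(counters),
        per_condition=per_condition,
    )


def fisher_information(
    problem: Problem,
    theta_est=None,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Expected Fisher information on the estimation scale.

    F = sum_rows (1/sigma^2) (dy/ds)(dy/ds)^T with s the estimation-scale
    parameters, assembled from forward observable sensitivities.  Useful for
    practical-identifiability assessment of a design before fitting.
    """
    settings = settings or SolverSettings()
    theta_est = (
        problem.theta_nominal() if theta_est is None else np.asarray(theta_est, dtype=float)
    )
    theta = problem.parameters.to_linear(theta_est)
    scale_vec = chain_rule(np.ones(theta.size), theta, problem.parameters.scales)
    counters = Counters()
    F = np.zeros((theta.size, theta.size))
    for cond in problem.conditions:
        _, dy, _, sigmas, _ = _condition_observable_sensitivities(
            problem, theta, cond, settings, counters
        )
        dy_est = dy * scale_vec[None, :]
        W = dy_est / sigmas[:, None]
        F += W.T @ W
    return F


def identifiable_parameters(
    problem: Problem,
    theta_est=None,
    relative_sd_threshold: float = 0.025,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Indices of practically identifiable parameters at a design point.

    A parameter counts as identifiable when its predicted relative standard
    deviation on the linear scale — ln(10) times the square root of the
    corresponding diagonal of the inverse Fisher information for log10-scaled
    entries — is below ``relative_sd_threshold``.
    """
    F = fisher_information(problem, theta_est, settings)
    cov = np.linalg.inv(F)
    sd_est = np.sqrt(np.diag(cov))
    rel_sd = np.array(
        [
            s * _LN10 if sc == "log10" else s / max(abs(v), 1e-300)
            for s, sc, v in zip(sd_est, problem.parameters.scales, problem.parameters.nominal)
        ]
    )
    return np.flatnonzero(rel_sd < relative_sd_threshold)


def fd_gradient(objective_fn, theta_est, step: float = 1e-5, scheme: str = "central"):
    """Central finite differences on the estimation scale.

    The step is relative to each coordinate: ``h_k = step * max(1, |theta_k|)``.
    """
    if scheme != "central":
        raise ValueError("only the central scheme is implemented")
    theta = np.asarray(theta_est, dtype=float)
    g = np.zeros(theta.size)
    for k in range(theta.size):
        h = step * max(1.0, abs(theta[k]))
        for sign in (+1.0, -1.0):
            th = theta.copy()
            th[k] += sign * h
            try:
                val = float(objective_fn(th))
            except Exception as err:
                raise FiniteDifferenceError(
                    f"objective evaluation failed while perturbing coordinate {k}: {err}"
                ) from err
            g[k] += sign * val / (2.0 * h)
    return g
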