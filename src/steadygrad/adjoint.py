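"""Standard adjoint sensitivity analysis (ASA) with backward integration.

The adjoint state p satisfies dp/dt = -J(x(t))^T p backward in time, with a
jump of (dh_i/dx)^T (ybar_i - y_i)/sigma_i^2 at every measurement time and
p = 0 beyond the last measurement.  The gradient quadratures
q_k = int p^T df/dtheta_k dt are carried as augmented states so the
integrator controls their error, and the gradient is assembled as

    dJ/dtheta = -sum r/sigma^2 dh/dtheta - q - p(t0)^T dx0/dtheta.

Equilibration intervals (pre and post) are handled here by the reference
"long simulation" treatment: the forward trajectory is extended over the
equilibration span and the adjoint is integrated backward over the same
span.  This is the method the steady-state linear-solve formulation
(:mod:`steadygrad.ssasa`) replaces; keeping it provides the comparison
baseline and the fallback for singular Jacobians.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .equilibration import Counters
from .model import chain_rule
from .objective import GradientResult, nll_condition
from .problem import Problem
from .settings import SolverSettings
from .simulate import simulate_condition

__all__ = ["measurement_jump", "backward_pass", "asa_gradient_longsim"]


class AdjointIntegrationFailure(RuntimeError):
    pass


def measurement_jump(p, model, x_at_tj, theta, u, residual_terms) -> np.ndarray:
    """Apply the adjoint jump of the observables measured at one time point.

    ``residual_terms`` is an iterable of ``(observable_index, measured, sigma)``.
    """
    p = np.array(p, dtype=float)
    y = model.h(x_at_tj, theta, u)
    dhdx = model.dhdx(x_at_tj, theta, u)
    for i, measured, sigma in residual_terms:
        if sigma == 0:
            raise ValueError(f"observable index {i}: sigma must be nonzero")
        p += dhdx[i] * (measured - y[i]) / sigma**2
    return p


def _segment(model, x_of_t, theta, u, t_hi, t_lo, p, q, counters, tag, rtol, atol):
    """Integrate the augmented adjoint system backward over one jump-free span."""
    n_x = model.n_x
    if not np.any(p):  # p stays identically zero on a jump-free span
        return p, q
    z0 = np.concatenate([p, q])

    def rhs(t, z):
        counters.add(tag)
        x = x_of_t(t)
        pp = z[:n_x]
        return np.concatenate(
            [-(model.jac(x, theta, u).T @ pp), -(model.dfdtheta(x, theta, u).T @ pp)]
        )

    def jac(t, z):
        x = x_of_t(t)
        n = z.size
        M = np.zeros((n, n))
        M[:n_x, :n_x] = -model.jac(x, theta, u).T
        M[n_x:, :n_x] = -model.dfdtheta(x, theta, u).T
        return M

    sol = solve_ivp(rhs, (t_hi, t_lo), z0, method="BDF", jac=jac, rtol=rtol, atol=atol)
    if not sol.success:
        raise AdjointIntegrationFailure(
            f"backward integration failed on [{t_lo}, {t_hi}]: {sol.message}"
        )
    z = sol.y[:, -1]
    return z[:n_x], z[n_x:]


def backward_pass(
    model,
    x_of_t,
    theta,
    u,
    t_hi: float,
    t_lo: float,
    p_init,
    jumps=(),
    counters: Counters | None = None,
    tag: str = "backward_rhs_timecourse",
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Backward adjoint integration over [t_lo, t_hi] with measurement jumps.

    ``jumps`` maps measurement times to jump vectors (already summed over the
    observables measured there); a jump at ``t_hi`` is applied before
    integration, a jump at ``t_lo`` after reaching it.  Returns
    ``(p(t_lo), q)`` with ``q = int_{t_lo}^{t_hi} p^T df/dtheta dt``.
    """
    counters = counters if counters is not None else Counters()
    p = np.array(p_init, dtype=float)
    q = np.zeros(model.n_theta)
    jump_map: dict[float, np.ndarray] = {}
    for t_j, vec in dict(jumps).items():
        jump_map[float(t_j)] = np.asarray(vec, dtype=float)
    if t_hi in jump_map:
        p = p + jump_map[t_hi]
    cur = t_hi
    for te in sorted((t for t in jump_map if t_lo <= t < t_hi), reverse=True):
        p, q = _segment(model, x_of_t, theta, u, cur, te, p, q, counters, tag, rtol, atol)
        p = p + jump_map[te]
        cur = te
    if cur > t_lo:
        p, q = _segment(model, x_of_t, theta, u, cur, t_lo, p, q, counters, tag, rtol, atol)
    return p, q


# ---------------------------------------------------------------------------
# shared per-condition pieces (used by the steady-state engine as well)
# ---------------------------------------------------------------------------


def timecourse_direct_term(model, sim, theta) -> np.ndarray:
    """Data term -sum r/sigma^2 dh/dtheta over time-course rows."""
    d = sim.data
    g = np.zeros(model.n_theta)
    for t_idx in np.unique(d.tc_time_index):
        x = sim.x_at_times[t_idx]
        dh = model.dhdtheta(x, theta, sim.u_main)
        y = sim.y_at_times[t_idx]
        mask = d.tc_time_index == t_idx
        for i, val, s in zip(d.tc_obs_index[mask], d.tc_value[mask], d.tc_sigma[mask]):
            g -= (val - y[i]) / s**2 * dh[i]
    return g


def build_jumps(model, sim, theta) -> dict[float, np.ndarray]:
    """Jump vector per unique time-course measurement time."""
    d = sim.data
    jumps: dict[float, np.ndarray] = {}
    for t_idx in np.unique(d.tc_time_index):
        t_j = float(d.times[t_idx])
        mask = d.tc_time_index == t_idx
        vec = measurement_jump(
            np.zeros(model.n_x),
            model,
            sim.x_at_times[t_idx],
            theta,
            sim.u_main,
            zip(d.tc_obs_index[mask], d.tc_value[mask], d.tc_sigma[mask]),
        )
        jumps[t_j] = vec
    return jumps


def steady_state_direct_and_boundary(model, sim, theta):
    """Direct dh/dtheta term and the adjoint boundary value p(t'') at x*."""
    d = sim.data
    direct = np.zeros(model.n_theta)
    dh = model.dhdtheta(sim.x_star, theta, sim.u_main)
    p_end = measurement_jump(
        np.zeros(model.n_x),
        model,
        sim.x_star,
        theta,
        sim.u_main,
        zip(d.ss_obs_index, d.ss_value, d.ss_sigma),
    )
    for i, val, s in zip(d.ss_obs_index, d.ss_value, d.ss_sigma):
        direct -= (val - sim.y_star[i]) / s**2 * dh[i]
    return direct, p_end


def timecourse_backward(model, sim, theta, p_start, counters, settings):
    """Standard backward pass over the time course; returns (p(t0), quadrature)."""
    d = sim.data
    if not d.has_timecourse:
        return np.array(p_start, dtype=float), np.zeros(model.n_theta)
    jumps = build_jumps(model, sim, theta)
    if sim.t_nt == 0.0:  # all measurements at t0: jumps only
        p = np.array(p_start, dtype=float)
        for vec in jumps.values():
            p = p + vec
        return p, np.zeros(model.n_theta)
    return backward_pass(
        model,
        sim.x_of_t,
        theta,
        sim.u_main,
        sim.t_nt,
        0.0,
        p_start,
        jumps,
        counters,
        tag="backward_rhs_timecourse",
        rtol=settings.rtol,
        atol=settings.atol,
    )


def _forward_tail(model, theta, u, x_start, t_span, settings, counters):
    def rhs(t, xx):
        counters.add("forward_rhs")
        return model.f(xx, theta, u)

    sol = solve_ivp(
        rhs,
        (0.0, t_span),
        x_start,
        method="BDF",
        jac=lambda t, xx: model.jac(xx, theta, u),
        rtol=settings.rtol,
        atol=settings.atol,
        dense_output=True,
    )
    if not sol.success:
        raise AdjointIntegrationFailure(f"equilibration-tail simulation failed: {sol.message}")
    return sol.sol


def posteq_tail_backward(model, sim, theta, p_end, counters, settings, tail_time):
    """Reference treatment of the post-equilibration span: backward integration."""
    if tail_time <= 0.0:
        return np.array(p_end, dtype=float), np.zeros(model.n_theta)
    x_of_t = _forward_tail(
        model, theta, sim.u_main, sim.x_end, tail_time, settings, counters
    )
    return backward_pass(
        model,
        lambda t: x_of_t(np.clip(t, 0.0, tail_time)),
        theta,
        sim.u_main,
        tail_time,
        0.0,
        p_end,
        counters=counters,
        tag="backward_rhs_equilibration",
        rtol=settings.rtol,
        atol=settings.atol,
    )


def preeq_tail_backward(model, sim, theta, p_t0, counters, settings, tail_time):
    """Reference treatment of the pre-equilibration span.

    Returns ``(p(-t'), quadrature)``; the caller evaluates the scalar product
    of p(-t') with the initial-state sensitivities of the pre-equilibration
    start (it is not assumed zero here).
    """
    if tail_time <= 0.0:
        return np.array(p_t0, dtype=float), np.zeros(model.n_theta)
    x0_pre = model.x0(theta, sim.u_pre)
    x_of_t = _forward_tail(model, theta, sim.u_pre, x0_pre, tail_time, settings, counters)
    return backward_pass(
        model,
        lambda t: x_of_t(np.clip(t, 0.0, tail_time)),
        theta,
        sim.u_pre,
        tail_time,
        0.0,
        p_t0,
        counters=counters,
        tag="backward_rhs_equilibration",
        rtol=settings.rtol,
        atol=settings.atol,
    )


def asa_gradient_longsim(
    problem: Problem,
    theta_est,
    settings: SolverSettings | None = None,
    counters: Counters | None = None,
    tail_scale: float = 1.0,
) -> GradientResult:
    """Reference ASA gradient with equilibration spans integrated backward.

    ``tail_scale`` multiplies the equilibration-span length used for both the
    forward tail and the backward pass (1.0 reproduces the span the
    equilibration itself needed; larger values let the adjoint decay
    further, which is how the linear-solve limit is demonstrated).
    """
    settings = settings or SolverSettings()
    counters = counters if counters is not None else Counters()
    for key in ("backward_rhs_timecourse", "backward_rhs_equilibration"):
        counters.setdefault(key, 0)
    model = problem.model
    theta_est = np.asarray(theta_est, dtype=float)
    theta = problem.parameters.to_linear(theta_est)

    grad_lin = np.zeros(model.n_theta)
    nll = 0.0
    per_condition: dict[str, float] = {}
    tags: dict[str, dict[str, str]] = {}

    for cond in problem.conditions:
        sim = simulate_condition(problem, theta, cond, settings, counters)
        per_condition[cond.id] = nll_condition(sim)
        nll += per_condition[cond.id]
        cond_tags: dict[str, str] = {}
        g = timecourse_direct_term(model, sim, theta)

        if cond.requires_postequilibration:
            direct_ss, p_end = steady_state_direct_and_boundary(model, sim, theta)
            g += direct_ss
            p, q_tail = posteq_tail_backward(
                model, sim, theta, p_end, counters, settings,
                tail_scale * sim.posteq.t_equil,
            )
            g -= q_tail
            cond_tags["posteq"] = "asa-backward"
        else:
            p = np.zeros(model.n_x)

        p, q_tc = timecourse_backward(model, sim, theta, p, counters, settings)
        g -= q_tc
        if sim.data.has_timecourse:
            cond_tags["timecourse"] = "asa-backward"

        if cond.requires_preequilibration:
            p_mt, q_pre = preeq_tail_backward(
                model, sim, theta, p, counters, settings,
                tail_scale * sim.preeq.t_equil,
            )
            g -= q_pre
            g -= p_mt @ model.dx0dtheta(theta, sim.u_pre)
            cond_tags["preeq"] = "asa-backward"
        else:
            g -= p @ model.dx0dtheta(theta, sim.u_main)
        grad_lin += g
        tags[cond.id] = cond_tags

    return GradientResult(
        nll=nll,
        gradient=chain_rule(grad_lin, theta, problem.parameters.scales),
        gradient_linear=grad_lin,
        method="asa",
        condition_methods=tags,
        counters=dict(counters),
        per_condition=per_condition,
    )
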