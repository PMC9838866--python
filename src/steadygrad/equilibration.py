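"""Steady-state computation by stiff integration with a weighted-residual test.

The system is integrated with a BDF method over doubling time windows until
the weighted root-mean-square of the time derivatives,

    wrms = (1/n_x) * sum_i (xdot_i * w_i)**2,   w_i = 1 / (rtol * x_i + atol),

drops below one.  An optional Newton polish then refines the converged state
by solving ``f(x) = 0``; a polish step is only accepted while it decreases
the wrms, and Newton failure falls back to the pure-simulation result.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Counters",
    "DegenerateWeightError",
    "EquilibrationFailure",
    "EquilibrationSettings",
    "EquilibrationResult",
    "PiecewiseTrajectory",
    "wrms_residual",
    "equilibrate",
    "steady_state_for_condition",
]


class Counters(dict):
    """Work counters (RHS evaluations, linear solves) keyed by category."""

    def add(self, key: str, n: int = 1) -> None:
        self[key] = self.get(key, 0) + n


class DegenerateWeightError(ValueError):
    """A wrms weight denominator rtol*x_i + atol is exactly zero."""


class EquilibrationFailure(RuntimeError):
    def __init__(self, message: str, wrms: float, phase: str = ""):
        super().__init__(message)
        self.wrms = wrms
        self.phase = phase


@dataclasses.dataclass
class EquilibrationSettings:
    """Convergence and schedule settings for steady-state computation.

    ``rtol``/``atol`` are the weighted-residual tolerances (the common
    practice is on the order of 1e-8 and 1e-16); the integration windows start
    at ``t_start_window`` time units and double up to ``max_doublings`` times,
    bounding total work at roughly twice the final window.
    """

    rtol: float = 1e-8
    atol: float = 1e-16
    t_start_window: float = 10.0
    max_doublings: int = 30
    newton_polish: bool = True
    newton_max_iter: int = 20
    max_state: float = 1e8  # divergence guard: abort once any |x_i| exceeds this

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol < 0 or self.max_doublings < 1:
            raise ValueError("require rtol > 0, atol >= 0, max_doublings >= 1")


@dataclasses.dataclass
class EquilibrationResult:
    x_star: np.ndarray
    wrms: float
    t_equil: float
    n_rhs_evals: int
    method: str  # "simulation" or "simulation+newton"
    trajectory: "PiecewiseTrajectory | None" = None


class PiecewiseTrajectory:
    """Dense forward solution stitched from per-window integrator output."""

    def __init__(self, segments):
        self.segments = list(segments)
        self.t_end = self.segments[-1].t[-1] if self.segments else 0.0

    def __call__(self, t: float) -> np.ndarray:
        t = min(max(t, 0.0), self.t_end)
        for seg in self.segments:
            if t <= seg.t[-1]:
                return seg.sol(t)
        return self.segments[-1].y[:, -1]


def wrms_residual(xdot, x, rtol: float, atol: float) -> float:
    """Weighted residual of the time derivatives; converged when < 1."""
    x = np.asarray(x, dtype=float)
    xdot = np.asarray(xdot, dtype=float)
    denom = rtol * x + atol
    if np.any(denom == 0.0):
        raise DegenerateWeightError("wrms weight denominator rtol*x + atol is zero")
    return float(np.mean((xdot / denom) ** 2))


def _newton_polish(model, theta, u, x, wr, settings, counters):
    xn, wr_n = x, wr
    improved = False
    for _ in range(settings.newton_max_iter):
        fx = model.f(xn, theta, u)
        counters.add("forward_rhs")
        try:
            delta = np.linalg.solve(model.jac(xn, theta, u), -fx)
        except np.linalg.LinAlgError:
            warnings.warn("Newton polish failed (singular Jacobian); keeping simulation result")
            break
        x_new = xn + delta
        f_new = model.f(x_new, theta, u)
        counters.add("forward_rhs")
        if not np.all(np.isfinite(x_new)):
            warnings.warn("Newton polish diverged; keeping simulation result")
            break
        try:
            wr_new = wrms_residual(f_new, x_new, settings.rtol, settings.atol)
        except DegenerateWeightError:
            break
        if not np.isfinite(wr_new) or wr_new >= wr_n:
            break
        xn, wr_n = x_new, wr_new
        improved = True
    return (xn, wr_n, improved)


def equilibrate(
    model,
    theta,
    u,
    x_init,
    settings: EquilibrationSettings | None = None,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    counters: Counters | None = None,
    store_trajectory: bool = False,
) -> EquilibrationResult:
    """Integrate to steady state, checking the wrms criterion along the way.

    ``rtol``/``atol`` here are the *integrator* tolerances; the convergence
    test uses ``settings.rtol``/``settings.atol``.  The test is applied at the
    initial state and at every natural integrator output point.
    """
    settings = settings or EquilibrationSettings()
    counters = counters if counters is not None else Counters()
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x = np.asarray(x_init, dtype=float)

    def rhs(t, xx):
        counters.add("forward_rhs")
        return model.f(xx, theta, u)

    def jac(t, xx):
        return model.jac(xx, theta, u)

    n0 = counters.get("forward_rhs", 0)
    fx = model.f(x, theta, u)
    counters.add("forward_rhs")
    wr = wrms_residual(fx, x, settings.rtol, settings.atol)
    segments = []
    t = 0.0
    converged = wr < 1.0
    warned_negative = False

    if not converged:
        window = settings.t_start_window
        for _ in range(settings.max_doublings):
            sol = solve_ivp(
                rhs,
                (t, t + window),
                x,
                method="BDF",
                jac=jac,
                rtol=rtol,
                atol=atol,
                dense_output=store_trajectory,
            )
            if not sol.success:
                raise EquilibrationFailure(
                    f"integrator failed during equilibration: {sol.message}", wr
                )
            if store_trajectory:
                segments.append(sol)
            for idx in range(1, sol.t.size):
                xx = sol.y[:, idx]
                fxx = model.f(xx, theta, u)
                counters.add("forward_rhs")
                wr = wrms_residual(fxx, xx, settings.rtol, settings.atol)
                if wr < 1.0:
                    x, t = xx, sol.t[idx]
                    converged = True
                    break
            if converged:
                break
            x, t = sol.y[:, -1], sol.t[-1]
            if np.max(np.abs(x)) > settings.max_state or not np.all(np.isfinite(x)):
                raise EquilibrationFailure(
                    f"state diverged during equilibration (max |x| > {settings.max_state:g} "
                    f"at t = {t:g}); no reachable steady state",
                    wr,
                )
            if not warned_negative and np.any(x < 0):
                warnings.warn(
                    "negative state encountered during equilibration; the model class "
                    "posits nonnegative states but stiff solvers may undershoot"
                )
                warned_negative = True
            window *= 2.0
        else:
            raise EquilibrationFailure(
                f"equilibration did not converge within {settings.max_doublings} "
                f"doubling windows (last wrms {wr:.3g})",
                wr,
            )

    method = "simulation"
    if settings.newton_polish:
        xn, wr_n, improved = _newton_polish(model, theta, u, x, wr, settings, counters)
        if improved:
            x, wr = xn, wr_n
            method = "simulation+newton"

    return EquilibrationResult(
        x_star=np.asarray(x, dtype=float),
        wrms=wr,
        t_equil=t,
        n_rhs_evals=counters.get("forward_rhs", 0) - n0,
        method=method,
        trajectory=PiecewiseTrajectory(segments) if store_trajectory else None,
    )


def steady_state_for_condition(
    model,
    theta,
    condition,
    settings: EquilibrationSettings | None = None,
    *,
    phase: str = "pre",
    x_timecourse_end=None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    counters: Counters | None = None,
    store_trajectory: bool = False,
) -> EquilibrationResult:
    """Equilibrate the phase of an experimental condition.

    ``phase="pre"`` runs under the pre-equilibration inputs starting from
    ``x0(theta, u_pre)``; the resulting steady state is the initial state of
    the time course.  ``phase="post"`` runs under the main inputs starting
    from the final time-course state ``x_timecourse_end``.
    """
    if phase == "pre":
        if not condition.requires_preequilibration:
            raise ValueError(f"condition '{condition.id}' requires no pre-equilibration")
        u_ext = model.extend_inputs(condition.u_pre, condition.u_pre)
        x_start = model.x0(np.asarray(theta, dtype=float), u_ext)
    elif phase == "post":
        if not condition.requires_postequilibration:
            raise ValueError(f"condition '{condition.id}' requires no post-equilibration")
        u_init = condition.u_pre if condition.requires_preequilibration else condition.u
        u_ext = model.extend_inputs(condition.u, u_init)
        if x_timecourse_end is None:
            raise ValueError("post-equilibration needs the final time-course state")
        x_start = np.asarray(x_timecourse_end, dtype=float)
    else:
        raise ValueError("phase must be 'pre' or 'post'")
    try:
        return equilibrate(
            model,
            theta,
            u_ext,
            x_start,
            settings,
            rtol=rtol,
            atol=atol,
            counters=counters,
            store_trajectory=store_trajectory,
        )
    except EquilibrationFailure as err:
        raise EquilibrationFailure(
            f"{phase}-equilibration of condition '{condition.id}' failed: {err}",
            err.wrms,
            phase=phase,
        ) from err
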