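"""Forward simulation of one experimental condition.

Shared by the objective and by every gradient method: optional
pre-equilibration under the pre-equilibration inputs, a dense time-course
solve to the last finite measurement time, and optional post-equilibration
from the final time-course state.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.integrate import solve_ivp

from .equilibration import Counters, EquilibrationResult, steady_state_for_condition
from .problem import ConditionData, ExperimentCondition, Problem
from .settings import SolverSettings

__all__ = ["ConditionSimulation", "simulate_condition"]


class SimulationFailure(RuntimeError):
    pass


@dataclasses.dataclass
class ConditionSimulation:
    condition: ExperimentCondition
    data: ConditionData
    u_main: np.ndarray  # extended inputs of the time-course / post-eq phase
    u_pre: np.ndarray | None  # extended inputs of the pre-equilibration phase
    preeq: EquilibrationResult | None
    x_t0: np.ndarray
    x_at_times: np.ndarray  # (n_times, n_x)
    dense: object | None  # scipy OdeSolution over [0, t_nt], if a time course ran
    posteq: EquilibrationResult | None
    x_star: np.ndarray | None
    y_at_times: np.ndarray  # (n_times, n_y)
    y_star: np.ndarray | None

    @property
    def t_nt(self) -> float:
        return float(self.data.times[-1]) if self.data.has_timecourse else 0.0

    @property
    def x_end(self) -> np.ndarray:
        return self.x_at_times[-1] if self.data.has_timecourse else self.x_t0

    def x_of_t(self, t: float) -> np.ndarray:
        if self.dense is None:
            return self.x_t0
        return self.dense(np.clip(t, 0.0, self.t_nt))


def simulate_condition(
    problem: Problem,
    theta_lin: np.ndarray,
    condition: ExperimentCondition,
    settings: SolverSettings | None = None,
    counters: Counters | None = None,
    *,
    posteq_trajectory: bool = False,
) -> ConditionSimulation:
    """Run all phases of one condition at linear-scale parameters."""
    settings = settings or SolverSettings()
    counters = counters if counters is not None else Counters()
    model = problem.model
    data = problem.condition_data(condition.id)
    theta_lin = np.asarray(theta_lin, dtype=float)

    u_init = condition.u_pre if condition.requires_preequilibration else condition.u
    u_main = model.extend_inputs(condition.u, u_init)
    u_pre = (
        model.extend_inputs(condition.u_pre, condition.u_pre)
        if condition.requires_preequilibration
        else None
    )

    preeq = None
    if condition.requires_preequilibration:
        preeq = steady_state_for_condition(
            model,
            theta_lin,
            condition,
            settings.equilibration,
            phase="pre",
            rtol=settings.rtol,
            atol=settings.atol,
            counters=counters,
        )
        x_t0 = preeq.x_star
    else:
        x_t0 = model.x0(theta_lin, u_main)

    dense = None
    if data.has_timecourse and data.times[-1] > 0.0:
        def rhs(t, xx):
            counters.add("forward_rhs")
            return model.f(xx, theta_lin, u_main)

        sol = solve_ivp(
            rhs,
            (0.0, float(data.times[-1])),
            x_t0,
            method="BDF",
            jac=lambda t, xx: model.jac(xx, theta_lin, u_main),
            rtol=settings.rtol,
            atol=settings.atol,
            dense_output=True,
        )
        if not sol.success:
            raise SimulationFailure(
                f"time-course integration failed for condition '{condition.id}': {sol.message}"
            )
        dense = sol.sol
        x_at_times = np.asarray(sol.sol(data.times)).T
    elif data.has_timecourse:  # all measurements at t0
        x_at_times = np.tile(x_t0, (data.times.size, 1))
    else:
        x_at_times = np.zeros((0, model.n_x))

    posteq = None
    x_star = None
    y_star = None
    if condition.requires_postequilibration:
        x_from = x_at_times[-1] if data.has_timecourse else x_t0
        posteq = steady_state_for_condition(
            model,
            theta_lin,
            condition,
            settings.equilibration,
            phase="post",
            x_timecourse_end=x_from,
            rtol=settings.rtol,
            atol=settings.atol,
            counters=counters,
            store_trajectory=posteq_trajectory,
        )
        x_star = posteq.x_star
        y_star = model.h(x_star, theta_lin, u_main)

    y_at_times = np.array(
        [model.h(x_at_times[i], theta_lin, u_main) for i in range(x_at_times.shape[0])]
    ).reshape(x_at_times.shape[0], model.n_y)

    return ConditionSimulation(
        condition=condition,
        data=data,
        u_main=u_main,
        u_pre=u_pre,
        preeq=preeq,
        x_t0=np.asarray(x_t0, dtype=float),
        x_at_times=x_at_times,
        dense=dense,
        posteq=posteq,
        x_star=x_star,
        y_at_times=y_at_times,
        y_star=y_star,
    )
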