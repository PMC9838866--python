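"""Method dispatch: one entry point for all gradient engines."""

from __future__ import annotations

import dataclasses

import numpy as np

from .adjoint import asa_gradient_longsim
from .equilibration import Counters
from .model import chain_rule
from .objective import GradientResult, objective_value
from .oracles import fd_gradient, forward_gradient
from .problem import Problem
from .settings import SolverSettings
from .ssasa import ssasa_gradient

__all__ = ["gradient", "GRADIENT_METHODS"]

GRADIENT_METHODS = ("ssasa", "asa", "forward", "fd")

_LN10 = np.log(10.0)


def gradient(
    problem: Problem,
    theta_est=None,
    method: str = "ssasa",
    settings: SolverSettings | None = None,
    counters: Counters | None = None,
    **kwargs,
) -> GradientResult:
    """Objective value and gradient by the selected method.

    ``theta_est`` is on the estimation scale and defaults to the nominal
    parameters.  Methods: ``ssasa`` (default; adjoint with steady-state
    linear solves), ``asa`` (reference adjoint with backward integration over
    equilibration spans), ``forward`` (forward sensitivities), ``fd``
    (central finite differences of the objective, at oracle-grade integrator
    tolerances).
    """
    settings = settings or SolverSettings()
    theta_est = (
        problem.theta_nominal() if theta_est is None else np.asarray(theta_est, dtype=float)
    )
    if method == "ssasa":
        return ssasa_gradient(problem, theta_est, settings, counters, **kwargs)
    if method == "asa":
        return asa_gradient_longsim(problem, theta_est, settings, counters, **kwargs)
    if method == "forward":
        return forward_gradient(problem, theta_est, settings, counters, **kwargs)
    if method == "fd":
        fd_settings = dataclasses.replace(settings, rtol=settings.fd_rtol, atol=settings.fd_atol)
        obj = lambda th: objective_value(problem, th, fd_settings).nll
        g_est = fd_gradient(obj, theta_est, step=settings.fd_step, **kwargs)
        nll = objective_value(problem, theta_est, fd_settings)
        theta_lin = problem.parameters.to_linear(theta_est)
        # invert the chain rule to report a linear-scale gradient as well
        denom = chain_rule(np.ones(theta_lin.size), theta_lin, problem.parameters.scales)
        return GradientResult(
            nll=nll.nll,
            gradient=g_est,
            gradient_linear=g_est / denom,
            method="fd",
            condition_methods={c.id: {"all": "finite-differences"} for c in problem.conditions},
            counters=dict(counters or {}),
            per_condition=nll.per_condition,
        )
    raise ValueError(f"unknown gradient method {method!r}; expected one of {GRADIENT_METHODS}")
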