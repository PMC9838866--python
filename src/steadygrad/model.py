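"""Symbolic ODE models of biochemical reaction networks.

A model is a system ``dx/dt = f(x, theta, u)`` with initial condition
``x(t0) = x0(theta, u)`` and an observation map ``y = h(x, theta, u)``.
States ``x`` are species concentrations, ``theta`` are (estimated)
parameters, and ``u`` are constant experimental inputs that enter rate
expressions like parameters but carry no sensitivities.

Models are declared either as a reaction network (stoichiometry ``S`` plus
rate expressions ``v``, so that ``f = S v``) or as raw right-hand sides, in a
small YAML dialect (``format: steadygrad-model-v1``).  All derivatives needed
by the sensitivity machinery (``df/dx``, ``df/dtheta``, ``dx0/dtheta``,
``dh/dx``, ``dh/dtheta``) are generated symbolically with sympy — never by
numerical differentiation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml
from sympy.parsing.sympy_parser import parse_expr

FORMAT_KEY = "steadygrad-model-v1"

__all__ = [
    "FORMAT_KEY",
    "ModelDefinitionError",
    "ScaleDomainError",
    "ReactionNetwork",
    "ModelFunctions",
    "ParameterSet",
    "parse_model",
    "load_model",
    "compile_model",
    "with_observables",
    "apply_scale",
    "to_estimation_scale",
    "chain_rule",
]


class ModelDefinitionError(ValueError):
    """Raised when a model definition is malformed or references unknown symbols."""


class ScaleDomainError(ValueError):
    """Raised when a log10-scaled parameter is not positive on the linear scale."""


# Functions allowed inside rate / initial / observable expressions.  Anything
# else that is not a declared symbol is rejected with an error naming it.
_FUNCTIONS = {
    "exp": sp.exp,
    "log": sp.log,
    "ln": sp.log,
    "sqrt": sp.sqrt,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "tanh": sp.tanh,
    "Abs": sp.Abs,
    "Min": sp.Min,
    "Max": sp.Max,
}
_GLOBALS = {
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
    "Symbol": sp.Symbol,
}


def _sympify(expr, symbols: Mapping[str, sp.Symbol], context: str) -> sp.Expr:
    if isinstance(expr, (int, float)):
        return sp.sympify(expr)
    try:
        parsed = parse_expr(
            str(expr), local_dict={**_FUNCTIONS, **dict(symbols)}, global_dict=dict(_GLOBALS)
        )
    except Exception as err:  # sympy raises a zoo of error types here
        raise ModelDefinitionError(f"{context}: cannot parse expression {expr!r}: {err}") from err
    declared = set(symbols.values())
    unknown = sorted(str(s) for s in parsed.free_symbols if s not in declared)
    if unknown:
        raise ModelDefinitionError(f"{context}: undeclared symbol '{unknown[0]}' in {expr!r}")
    return parsed


@dataclasses.dataclass
class ReactionNetwork:
    """Validated symbolic model: species, stoichiometry, rates and maps.

    ``f_exprs`` assembles the right-hand side as ``S v`` plus any raw ODE
    contributions; species order is declaration order throughout.
    """

    species: list[str]
    parameters: list[str]
    inputs: list[str]
    stoichiometry: np.ndarray  # (n_x, n_r) integer
    rates: list[sp.Expr]
    raw_odes: dict[str, sp.Expr]
    initials: list[sp.Expr]
    observables: dict[str, sp.Expr]
    n_u_base: int | None = None  # inputs before any appended total-defining copies
    reduced: bool = False
    conservation: object | None = None
    definition: dict | None = None  # original YAML dict, kept for round-trips

    def __post_init__(self) -> None:
        if self.n_u_base is None:
            self.n_u_base = len(self.inputs)

    # -- symbol accessors ---------------------------------------------------
    @property
    def x_syms(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(n) for n in self.species)

    @property
    def theta_syms(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(n) for n in self.parameters)

    @property
    def u_syms(self) -> tuple[sp.Symbol, ...]:
        return tuple(sp.Symbol(n) for n in self.inputs)

    @property
    def n_x(self) -> int:
        return len(self.species)

    @property
    def n_theta(self) -> int:
        return len(self.parameters)

    @property
    def n_u(self) -> int:
        return len(self.inputs)

    @property
    def f_exprs(self) -> list[sp.Expr]:
        """Right-hand side ``f = S v`` plus raw contributions, in species order."""
        n_x, n_r = self.stoichiometry.shape
        exprs = []
        for i, name in enumerate(self.species):
            e = sp.Integer(0)
            for r in range(n_r):
                coef = int(self.stoichiometry[i, r])
                if coef:
                    e = e + coef * self.rates[r]
            if name in self.raw_odes:
                e = e + self.raw_odes[name]
            exprs.append(sp.expand(e))
        return exprs


def parse_model(definition: dict | str) -> ReactionNetwork:
    """Parse a model definition (YAML text or already-loaded dict)."""
    if isinstance(definition, str):
        data = yaml.safe_load(definition)
    elif isinstance(definition, Mapping):
        data = dict(definition)
    else:
        raise TypeError("definition must be YAML text or a mapping")
    if not isinstance(data, Mapping):
        raise ModelDefinitionError("model definition must be a mapping")
    if "format" in data and data["format"] != FORMAT_KEY:
        raise ModelDefinitionError(
            f"unsupported model format {data['format']!r}; expected {FORMAT_KEY!r}"
        )

    def _names(key: str) -> list[str]:
        raw = data.get(key) or []
        names = [str(n) for n in raw]
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise ModelDefinitionError(f"duplicate {key[:-1]} '{n}'")
            seen.add(n)
        return names

    species = _names("species")
    parameters = _names("parameters")
    inputs = _names("inputs")
    if not species:
        raise ModelDefinitionError("model declares no species")
    pools = species + parameters + inputs
    if len(set(pools)) != len(pools):
        dup = next(n for n in pools if pools.count(n) > 1)
        raise ModelDefinitionError(f"name '{dup}' declared in more than one role")
    symbols = {n: sp.Symbol(n) for n in pools}
    sp_index = {n: i for i, n in enumerate(species)}

    reactions = data.get("reactions") or []
    S = np.zeros((len(species), len(reactions)), dtype=int)
    rates: list[sp.Expr] = []
    for r_i, rxn in enumerate(reactions):
        ctx = f"reaction {r_i}"
        if "rate" not in rxn:
            raise ModelDefinitionError(f"{ctx}: missing rate expression")
        for side, sign in (("reactants", -1), ("products", +1)):
            for name, coef in (rxn.get(side) or {}).items():
                if name not in sp_index:
                    raise ModelDefinitionError(f"{ctx}: undeclared species '{name}' in {side}")
                S[sp_index[name], r_i] += sign * int(coef)
        rates.append(_sympify(rxn["rate"], symbols, ctx))

    raw_odes: dict[str, sp.Expr] = {}
    for name, expr in (data.get("odes") or {}).items():
        if name not in sp_index:
            raise ModelDefinitionError(f"ode for undeclared species '{name}'")
        raw_odes[name] = _sympify(expr, symbols, f"ode for {name}")

    init_map = data.get("initials") or {}
    for name in init_map:
        if name not in sp_index:
            raise ModelDefinitionError(f"initial for undeclared species '{name}'")
    initials = [_sympify(init_map.get(n, 0), symbols, f"initial of {n}") for n in species]

    obs_map = data.get("observables")
    if obs_map:
        observables = {
            str(k): _sympify(v, symbols, f"observable {k}") for k, v in obs_map.items()
        }
    else:
        observables = {f"obs_{n}": symbols[n] for n in species}

    return ReactionNetwork(
        species=species,
        parameters=parameters,
        inputs=inputs,
        stoichiometry=S,
        rates=rates,
        raw_odes=raw_odes,
        initials=initials,
        observables=observables,
        definition=dict(data),
    )


def load_model(path: str | Path) -> ReactionNetwork:
    return parse_model(Path(path).read_text())


def with_observables(network: ReactionNetwork, observables: Mapping[str, object]) -> ReactionNetwork:
    """Return a copy of ``network`` with the observation map replaced."""
    symbols = {str(s): s for s in (*network.x_syms, *network.theta_syms, *network.u_syms)}
    parsed = {
        str(k): _sympify(v, symbols, f"observable {k}") if not isinstance(v, sp.Expr) else v
        for k, v in observables.items()
    }
    return dataclasses.replace(network, observables=parsed)


# ---------------------------------------------------------------------------
# compilation to numerical callables
# ---------------------------------------------------------------------------


def _compile_matrix(
    exprs, x_syms, theta_syms, u_syms, shape: tuple[int, ...]
) -> Callable[..., np.ndarray]:
    matrix = sp.ImmutableMatrix(exprs) if not isinstance(exprs, sp.MatrixBase) else sp.ImmutableMatrix(exprs)
    fn = sp.lambdify((x_syms, theta_syms, u_syms), matrix, modules="numpy")
    size = int(np.prod(shape)) if shape else 1

    def call(x, theta, u) -> np.ndarray:
        out = np.asarray(
            fn(np.asarray(x, dtype=float), np.asarray(theta, dtype=float), np.asarray(u, dtype=float)),
            dtype=float,
        )
        if out.size != size:  # constant expressions may broadcast oddly
            out = np.broadcast_to(out, shape)
        return out.reshape(shape)

    return call


@dataclasses.dataclass(frozen=True)
class ModelFunctions:
    """Compiled model: right-hand side, observation map and exact derivatives.

    All callables share the signature ``(x, theta, u) -> ndarray`` (``x0`` and
    ``dx0dtheta`` take ``(theta, u)``), with ``u`` being the *extended* input
    vector for moiety-reduced models (base inputs followed by the
    initial-phase copies that define conserved totals).
    """

    species_ids: tuple[str, ...]
    parameter_ids: tuple[str, ...]
    input_ids: tuple[str, ...]
    observable_ids: tuple[str, ...]
    n_u_base: int
    reduced: bool
    conservation: object | None
    network: ReactionNetwork
    f: Callable[..., np.ndarray]
    jac: Callable[..., np.ndarray]
    dfdtheta: Callable[..., np.ndarray]
    x0: Callable[..., np.ndarray]
    dx0dtheta: Callable[..., np.ndarray]
    h: Callable[..., np.ndarray]
    dhdx: Callable[..., np.ndarray]
    dhdtheta: Callable[..., np.ndarray]

    @property
    def n_x(self) -> int:
        return len(self.species_ids)

    @property
    def n_theta(self) -> int:
        return len(self.parameter_ids)

    @property
    def n_u(self) -> int:
        return len(self.input_ids)

    @property
    def n_y(self) -> int:
        return len(self.observable_ids)

    def extend_inputs(self, u, u_init=None) -> np.ndarray:
        """Assemble the full input vector for one simulation phase.

        For a reduced model the conserved totals are functions of the inputs
        that were active when the initial state was set (``u_init``); the
        extended vector is ``[u, u_init]``.  Unreduced models pass ``u``
        through unchanged.
        """
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if not self.reduced:
            return u
        ui = u[: self.n_u_base] if u_init is None else np.atleast_1d(np.asarray(u_init, dtype=float))
        return np.concatenate([u[: self.n_u_base], ui])


def compile_model(network: ReactionNetwork) -> ModelFunctions:
    """Generate all callables of a model, with exact symbolic derivatives."""
    x = network.x_syms
    th = network.theta_syms
    u = network.u_syms
    n_x, n_th = network.n_x, network.n_theta

    f_vec = sp.Matrix(network.f_exprs)
    x0_vec = sp.Matrix(network.initials)
    h_vec = sp.Matrix(list(network.observables.values()))
    n_y = h_vec.shape[0]

    xm = sp.Matrix(x)
    thm = sp.Matrix(th) if n_th else sp.Matrix(0, 1, [])

    def _jacobian(vec: sp.Matrix, wrt: sp.Matrix, what: str) -> sp.Matrix:
        jac = vec.jacobian(wrt) if wrt.shape[0] else sp.Matrix(vec.shape[0], 0, [])
        if jac.atoms(sp.Derivative):
            raise ModelDefinitionError(f"{what} contains a non-differentiable expression")
        return jac

    jac_expr = _jacobian(f_vec, xm, "f")
    dfdth_expr = _jacobian(f_vec, thm, "f")
    dx0dth_expr = _jacobian(x0_vec, thm, "x0")
    dhdx_expr = _jacobian(h_vec, xm, "h")
    dhdth_expr = _jacobian(h_vec, thm, "h")

    x0_fn = _compile_matrix(x0_vec, (), th, u, (n_x,))
    dx0_fn = _compile_matrix(dx0dth_expr, (), th, u, (n_x, n_th))

    return ModelFunctions(
        species_ids=tuple(network.species),
        parameter_ids=tuple(network.parameters),
        input_ids=tuple(network.inputs),
        observable_ids=tuple(network.observables),
        n_u_base=int(network.n_u_base),
        reduced=network.reduced,
        conservation=network.conservation,
        network=network,
        f=_compile_matrix(f_vec, x, th, u, (n_x,)),
        jac=_compile_matrix(jac_expr, x, th, u, (n_x, n_x)),
        dfdtheta=_compile_matrix(dfdth_expr, x, th, u, (n_x, n_th)),
        x0=lambda theta, uu, _fn=x0_fn: _fn((), theta, uu),
        dx0dtheta=lambda theta, uu, _fn=dx0_fn: _fn((), theta, uu),
        h=_compile_matrix(h_vec, x, th, u, (n_y,)),
        dhdx=_compile_matrix(dhdx_expr, x, th, u, (n_y, n_x)),
        dhdtheta=_compile_matrix(dhdth_expr, x, th, u, (n_y, n_th)),
    )


# ---------------------------------------------------------------------------
# parameter scales
# ---------------------------------------------------------------------------

_LN10 = math.log(10.0)


def _check_scales(scales: Sequence[str]) -> None:
    for s in scales:
        if s not in ("lin", "log10"):
            raise ValueError(f"unknown parameter scale {s!r}; expected 'lin' or 'log10'")


def apply_scale(theta_scaled, scales: Sequence[str]) -> np.ndarray:
    """Map parameters from the estimation scale to the linear (model) scale."""
    _check_scales(scales)
    out = np.array(theta_scaled, dtype=float)
    for i, s in enumerate(scales):
        if s == "log10":
            out[i] = 10.0 ** out[i]
    return out


def to_estimation_scale(theta_linear, scales: Sequence[str]) -> np.ndarray:
    """Inverse of :func:`apply_scale`; log10 entries must be positive."""
    _check_scales(scales)
    out = np.array(theta_linear, dtype=float)
    for i, s in enumerate(scales):
        if s == "log10":
            if out[i] <= 0:
                raise ScaleDomainError(
                    f"parameter {i} is log10-scaled but has non-positive value {out[i]}"
                )
            out[i] = math.log10(out[i])
    return out


def chain_rule(grad_linear, theta_linear, scales: Sequence[str]) -> np.ndarray:
    """Convert a linear-scale gradient to the estimation scale.

    For a log10-scaled entry, d/ds J(10**s) = (dJ/dtheta) * theta * ln(10).
    """
    _check_scales(scales)
    out = np.array(grad_linear, dtype=float)
    th = np.asarray(theta_linear, dtype=float)
    for i, s in enumerate(scales):
        if s == "log10":
            out[i] *= th[i] * _LN10
    return out


@dataclasses.dataclass
class ParameterSet:
    """Estimated parameters: ids, nominal linear values, scales and bounds.

    Bounds are stored on the linear scale (as in the tabular problem format)
    and exposed on the estimation scale for the optimizer.
    """

    ids: list[str]
    nominal: np.ndarray  # linear scale
    scales: list[str]
    lower: np.ndarray  # linear scale
    upper: np.ndarray
    estimate: np.ndarray | None = None  # boolean mask; default all True

    def __post_init__(self) -> None:
        self.nominal = np.asarray(self.nominal, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.estimate is None:
            self.estimate = np.ones(len(self.ids), dtype=bool)
        else:
            self.estimate = np.asarray(self.estimate, dtype=bool)
        _check_scales(self.scales)
        n = len(self.ids)
        for arr, name in ((self.nominal, "nominal"), (self.lower, "lower"), (self.upper, "upper")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        for i, s in enumerate(self.scales):
            if s == "log10" and self.lower[i] <= 0:
                raise ScaleDomainError(
                    f"parameter '{self.ids[i]}' is log10-scaled but lower bound is not positive"
                )
            if not (self.lower[i] <= self.nominal[i] <= self.upper[i]):
                raise ValueError(
                    f"parameter '{self.ids[i]}' nominal value {self.nominal[i]} "
                    f"outside bounds [{self.lower[i]}, {self.upper[i]}]"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    def nominal_estimation(self) -> np.ndarray:
        return to_estimation_scale(self.nominal, self.scales)

    def bounds_estimation(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            to_estimation_scale(self.lower, self.scales),
            to_estimation_scale(self.upper, self.scales),
        )

    def to_linear(self, theta_est) -> np.ndarray:
        return apply_scale(theta_est, self.scales)

    def to_estimation(self, theta_linear) -> np.ndarray:
        return to_estimation_scale(theta_linear, self.scales)
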