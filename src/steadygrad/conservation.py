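"""Conserved-moiety detection and model reduction.

A conserved quantity (moiety) is a linear combination ``L x`` of states that
is constant along every trajectory; it exists exactly when ``L S = 0`` for
the stoichiometric matrix ``S``.  Conserved quantities make the steady-state
Jacobian singular, which blocks the linear-solve formulation of the adjoint
method; eliminating one state per conserved law restores a nonsingular
Jacobian for exponentially stable steady states.

The left null space is computed exactly over the rationals (integer-scaled
rows), which is adequate at the model sizes this package targets.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import sympy as sp

from .model import ModelFunctions, ReactionNetwork, compile_model

__all__ = [
    "SingularJacobian",
    "ReductionError",
    "ConservationAnalysis",
    "find_conserved_quantities",
    "reduce_network",
    "reduce_model",
    "assert_nonsingular",
    "conservation_report",
]


class SingularJacobian(RuntimeError):
    """Steady-state Jacobian is numerically singular."""

    def __init__(self, message: str, rcond: float):
        super().__init__(message)
        self.rcond = rcond


class ReductionError(RuntimeError):
    """A conserved law has no state that can be eliminated."""


@dataclasses.dataclass
class ConservationAnalysis:
    """Conservation laws of a network.

    ``L`` has one integer row per law (smallest-integer scaling, first
    nonzero coefficient positive); ``L S = 0`` exactly.  ``eliminated_indices``
    holds one state per law, chosen as the state with the largest absolute
    coefficient (ties broken towards the highest declaration index) such that
    the eliminated submatrix of ``L`` stays invertible.
    """

    L: np.ndarray  # (n_c, n_x) integer
    kept_indices: tuple[int, ...]
    eliminated_indices: tuple[int, ...]

    @property
    def n_c(self) -> int:
        return int(self.L.shape[0])

    def totals(self, x0_values) -> np.ndarray:
        """Values ``L x0`` of the conserved quantities for a given initial state."""
        return self.L @ np.asarray(x0_values, dtype=float)


def _integer_row(vec: sp.Matrix) -> np.ndarray:
    entries = [sp.nsimplify(e, rational=True) for e in vec]
    denoms = [sp.Rational(e).q for e in entries]
    lcm = math.lcm(*denoms) if denoms else 1
    ints = [int(sp.Rational(e) * lcm) for e in entries]
    g = math.gcd(*(abs(i) for i in ints if i)) or 1
    ints = [i // g for i in ints]
    first = next((i for i in ints if i), 1)
    if first < 0:
        ints = [-i for i in ints]
    return np.array(ints, dtype=int)


def find_conserved_quantities(S) -> ConservationAnalysis:
    """Exact rational left null space of the stoichiometric matrix.

    ``n_c = n_x - rank(S)``; ``n_c = 0`` is a valid result.  Also selects the
    state to eliminate per law (see :class:`ConservationAnalysis`).
    """
    S = np.asarray(S, dtype=int)
    n_x = S.shape[0]
    if S.shape[1] == 0:
        basis = [sp.eye(n_x)[:, i] for i in range(n_x)]
    else:
        basis = sp.Matrix(S.T.tolist()).nullspace()
    rows = [_integer_row(v) for v in basis]
    L = np.array(rows, dtype=int).reshape(len(rows), n_x)
    return _reselect(L, n_x)


def reduce_network(
    network: ReactionNetwork, analysis: ConservationAnalysis | None = None
) -> tuple[ReactionNetwork, ConservationAnalysis]:
    """Eliminate one state per conserved law, symbolically.

    Each eliminated state is expressed through the conserved total and the
    kept states.  Totals ``T = L x0(theta, u_init)`` are substituted as
    symbolic expressions in ``theta`` and in *copies* of the input symbols
    (named ``<input>__init``) that represent the condition under which the
    initial state was set — for pre-equilibrated experiments the time course
    inherits the totals of the pre-equilibration condition.  Because the
    substitution is symbolic, the dependence of the totals on ``theta``
    propagates exactly into all derivatives of the reduced model.
    """
    if network.reduced:
        return network, network.conservation  # type: ignore[return-value]
    if network.stoichiometry.shape[1] == 0 and network.raw_odes:
        warnings.warn(
            "model has no reaction structure; conserved-moiety detection skipped",
            stacklevel=2,
        )
        empty = ConservationAnalysis(
            L=np.zeros((0, network.n_x), dtype=int),
            kept_indices=tuple(range(network.n_x)),
            eliminated_indices=(),
        )
        return network, empty
    if analysis is None:
        analysis = find_conserved_quantities(network.stoichiometry)

    # raw contributions can break a law inferred from S alone
    if analysis.n_c and network.raw_odes:
        f = sp.Matrix(network.f_exprs)
        valid = [
            i
            for i in range(analysis.n_c)
            if sp.simplify((sp.Matrix([analysis.L[i].tolist()]) * f)[0]) == 0
        ]
        if len(valid) < analysis.n_c:
            L = np.asarray([analysis.L[i] for i in valid], dtype=int).reshape(
                len(valid), network.n_x
            )
            analysis = _reselect(L, network.n_x)

    if analysis.n_c == 0:
        return network, analysis

    x_syms = network.x_syms
    u_syms = network.u_syms
    elim = list(analysis.eliminated_indices)
    kept = list(analysis.kept_indices)

    u_init_names = [f"{n}__init" for n in network.inputs]
    u_init_syms = [sp.Symbol(n) for n in u_init_names]
    subs_u = dict(zip(u_syms, u_init_syms))

    x0_init = sp.Matrix([e.subs(subs_u) for e in network.initials])
    Lm = sp.Matrix(analysis.L.tolist())
    T = Lm * x0_init  # totals, symbolic in theta and the __init inputs

    LE = Lm.extract(range(analysis.n_c), elim)
    LK = Lm.extract(range(analysis.n_c), kept)
    xK = sp.Matrix([x_syms[k] for k in kept])
    xE = LE.solve(T - LK * xK)
    subs_map = {x_syms[e]: sp.expand(xE[c]) for c, e in enumerate(elim)}

    f_exprs = network.f_exprs
    raw_odes = {network.species[k]: sp.expand(f_exprs[k].subs(subs_map)) for k in kept}
    observables = {name: e.subs(subs_map) for name, e in network.observables.items()}

    reduced = ReactionNetwork(
        species=[network.species[k] for k in kept],
        parameters=list(network.parameters),
        inputs=list(network.inputs) + u_init_names,
        stoichiometry=np.zeros((len(kept), 0), dtype=int),
        rates=[],
        raw_odes=raw_odes,
        initials=[network.initials[k] for k in kept],
        observables=observables,
        n_u_base=len(network.inputs),
        reduced=True,
        conservation=analysis,
        definition=None,
    )
    return reduced, analysis


def _reselect(L: np.ndarray, n_x: int) -> ConservationAnalysis:
    """Re-run elimination selection for a given (already validated) L."""
    tmp = ConservationAnalysis(L=L, kept_indices=(), eliminated_indices=())
    eliminated: list[int] = []
    Lm = sp.Matrix(L.tolist()) if L.shape[0] else sp.Matrix(0, n_x, [])
    for i in range(L.shape[0]):
        candidates = sorted(
            (j for j in range(n_x) if L[i, j] != 0 and j not in eliminated),
            key=lambda j: (abs(L[i, j]), j),
            reverse=True,
        )
        chosen = None
        for j in candidates:
            sub = Lm[: i + 1, :].extract(range(i + 1), eliminated + [j])
            if sub.rank() == i + 1:
                chosen = j
                break
        if chosen is None:
            raise ReductionError(f"conservation law {i} ({L[i]}) has no eliminable state")
        eliminated.append(chosen)
    tmp.eliminated_indices = tuple(eliminated)
    tmp.kept_indices = tuple(j for j in range(n_x) if j not in eliminated)
    return tmp


def reduce_model(
    network: ReactionNetwork, analysis: ConservationAnalysis | None = None
) -> tuple[ModelFunctions, ConservationAnalysis]:
    """Detect conserved quantities, reduce, and compile the reduced model."""
    reduced, analysis = reduce_network(network, analysis)
    return compile_model(reduced), analysis


def assert_nonsingular(jac_at_ss, tolerance: float = 1e-10) -> float:
    """Check the steady-state Jacobian for (numerical) nonsingularity.

    Returns the reciprocal condition estimate (smallest/largest singular
    value); raises :class:`SingularJacobian` below ``tolerance``.
    """
    A = np.asarray(jac_at_ss, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("Jacobian must be a square matrix")
    sv = np.linalg.svd(A, compute_uv=False)
    rcond = float(sv[-1] / sv[0]) if sv.size and sv[0] > 0 else 0.0
    if not np.isfinite(rcond) or rcond < tolerance:
        raise SingularJacobian(
            "steady-state Jacobian is singular (reciprocal condition estimate "
            f"{rcond:.3e} < {tolerance:.1e}); removing conserved quantities from "
            "the model restores a nonsingular Jacobian and makes the "
            "steady-state adjoint linear solve applicable",
            rcond,
        )
    return rcond


def conservation_report(
    analysis: ConservationAnalysis,
    species_ids,
    totals_by_condition: dict | None = None,
) -> pd.DataFrame:
    """Tabular report: one row per law with species coefficients and totals."""
    rows = []
    for i in range(analysis.n_c):
        row = {"law": i}
        for j, name in enumerate(species_ids):
            row[name] = int(analysis.L[i, j])
        row["eliminated"] = species_ids[analysis.eliminated_indices[i]]
        for cid, totals in (totals_by_condition or {}).items():
            row[f"total_{cid}"] = float(np.asarray(totals)[i])
        rows.append(row)
    return pd.DataFrame(rows)
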