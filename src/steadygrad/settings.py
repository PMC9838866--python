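"""Solver configuration shared by all gradient methods."""

from __future__ import annotations

import dataclasses

from .equilibration import EquilibrationSettings

__all__ = ["SolverSettings"]


@dataclasses.dataclass
class SolverSettings:
    """Numerical settings for simulation and sensitivity computation.

    Forward/backward integration tolerances default to 1e-10/1e-12 — tighter
    than the equilibration tolerances so that gradient-method comparisons are
    not limited by integrator noise.  The finite-difference oracle integrates
    tighter still (1e-12/1e-14) so that central differences at ``fd_step`` are
    not noise-limited either.
    """

    rtol: float = 1e-10
    atol: float = 1e-12
    equilibration: EquilibrationSettings = dataclasses.field(default_factory=EquilibrationSettings)
    fd_step: float = 1e-5
    fd_rtol: float = 1e-12
    fd_atol: float = 1e-14
    nonsingular_tol: float = 1e-10
    allow_asa_fallback: bool = False
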