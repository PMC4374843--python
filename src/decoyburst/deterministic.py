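"""Deterministic rate-equation reduction and bistability analysis.

Averaging the jump-drift model and neglecting fluctuations gives the scalar
autonomous ODE

    dx/dt = b*a(x) - c(x),

whose steady states satisfy, in the free-protein coordinate,

    b*a0 + b*a1*xf/(kp+xf) = xf + gamma_b*y*xf/(xf+kb).

With no decoys (y = 0), or with bound protein fully protected from decay
(gamma_b = 0), this balance has exactly one solution and bistability cannot
occur.  For equal decay (gamma_b = 1) the steady-state balance is b times
the log-scale extremum condition of the stationary density, so the
deterministic model is bistable exactly when the stochastic model is
bimodal on the log10 scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    GeneCircuitParams,
    burst_rate,
    degradation_rate,
    total_from_free,
)
from .modality import Scale, count_modes

__all__ = ["Stability", "SteadyStateSet", "ode_rhs", "steady_states",
           "bistability_equivalence_check"]

SCAN_LO, SCAN_HI, SCAN_N = 1e-4, 1e6, 2000
ROOT_RTOL = 1e-10


class Stability(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"


@dataclass(frozen=True)
class SteadyStateSet:
    """Steady states of the rate equation, in the free-protein coordinate.

    For generic parameters the root count is odd and stability alternates,
    starting and ending with a stable state.
    """

    roots_xf: tuple
    roots_x: tuple
    stability: tuple
    bistable: bool


def ode_rhs(x: float, params: GeneCircuitParams) -> float:
    """Right-hand side b*a(x) - c(x) of the deterministic rate equation."""
    return params.b * burst_rate(x, params) - degradation_rate(x, params)


def _balance_free(xf, params: GeneCircuitParams):
    """Steady-state balance b*a - c expressed in free protein (vectorized)."""
    return (
        params.b * params.a0
        + params.b * params.a1 * xf / (params.kp + xf)
        - xf
        - params.gamma_b * params.y * xf / (xf + params.kb)
    )


def steady_states(params: GeneCircuitParams) -> SteadyStateSet:
    """All steady states of the rate equation with stability classification.

    Roots are found by a log-spaced sign scan plus bisection in xf (the same
    scheme the modality analysis uses, so root sets are directly
    comparable).  Stability is judged from the sign of the rhs at
    x*(1 +/- 1e-4) around each root in the total-protein coordinate.
    """
    grid = np.geomspace(SCAN_LO, SCAN_HI, SCAN_N)
    f = _balance_free(grid, params)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(float(grid[i]))
        elif f[i] * f[i + 1] < 0:
            roots.append(
                brentq(_balance_free, grid[i], grid[i + 1], args=(params,),
                       rtol=ROOT_RTOL)
            )
    roots_x = [total_from_free(r, params) for r in roots]
    stab = []
    for x in roots_x:
        below = ode_rhs(x * (1.0 - 1e-4), params)
        above = ode_rhs(x * (1.0 + 1e-4), params)
        stab.append(
            Stability.STABLE if (below > 0 and above < 0) else Stability.UNSTABLE
        )
    n_stable = sum(1 for s in stab if s is Stability.STABLE)
    return SteadyStateSet(
        roots_xf=tuple(roots),
        roots_x=tuple(roots_x),
        stability=tuple(stab),
        bistable=n_stable >= 2,
    )


def bistability_equivalence_check(params: GeneCircuitParams) -> tuple:
    """(bistable, log_bimodal) classification pair for gamma_b = 1.

    The two flags agree for every parameter set: the deterministic balance
    equals b times the log-scale extremum condition.
    """
    if params.gamma_b != 1.0:
        raise ValueError("the equivalence holds for gamma_b = 1")
    ss = steady_states(params)
    report = count_modes(params, Scale.LOG10)
    return ss.bistable, report.n_modes >= 2
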