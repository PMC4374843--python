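"""Reduced model of a bursty, self-regulating gene with decoy binding sites.

A transcription factor is produced in random bursts, activates its own
promoter (non-cooperatively) and binds reversibly to ``y`` decoy sites on
the DNA.  Binding and unbinding are assumed fast compared with protein
turnover, so at any instant the free protein level ``xf``, the bound level
``xb`` and the total level ``x = xf + xb`` are linked algebraically through
the decoy dissociation constant ``kb``:

    xb = y * xf / (xf + kb)          (quasi-steady-state occupancy)
    x  = xf + y * xf / (xf + kb)

Time is measured in units of the free-protein lifetime, so the free-protein
decay rate constant is fixed at 1; ``gamma_b`` is the decay rate constant of
bound protein relative to free.  This module holds the parameter container
and the elementary maps every other module builds on: total<->free protein
conversion, the aggregate degradation rate c(x) and the autoregulated burst
rate a(x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GeneCircuitParams",
    "ProteinState",
    "free_from_total",
    "total_from_free",
    "bound_from_free",
    "degradation_rate",
    "burst_rate",
]


@dataclass(frozen=True)
class GeneCircuitParams:
    """Parameters of the reduced gene circuit.

    Attributes
    ----------
    a0 : float
        Basal transcription (burst) rate, bursts per free-protein lifetime.
    a1 : float
        Regulable transcription rate increment: the burst rate rises from
        ``a0`` to ``a0 + a1`` at full promoter occupancy.
    kp : float
        Promoter dissociation constant, molecules (free protein at promoter
        half-occupancy).
    b : float
        Mean burst size, molecules; burst sizes are exponentially
        distributed.
    y : float
        Total decoy binding-site concentration, molecules (constant).
    kb : float
        Decoy-site dissociation constant, molecules.
    gamma_b : float
        Bound-protein decay rate constant relative to free protein
        (``gamma_f == 1`` by the choice of time unit).
    """

    a0: float
    a1: float
    kp: float
    b: float
    y: float = 0.0
    kb: float = 1.0
    gamma_b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "kp", "b", "y", "kb", "gamma_b"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.a0 < 0 or self.a1 < 0:
            raise ValueError("burst rates a0, a1 must be non-negative")
        if self.kp <= 0 or self.kb <= 0:
            raise ValueError("dissociation constants kp, kb must be positive")
        if self.b <= 0:
            raise ValueError("mean burst size b must be positive")
        if self.y < 0:
            raise ValueError("decoy concentration y must be non-negative")
        if self.gamma_b < 0:
            raise ValueError("gamma_b must be non-negative")

    def with_(self, **kwargs) -> "GeneCircuitParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ProteinState:
    """A consistent (total, free, bound) protein triple.

    ``x = xf + xb`` holds exactly; constructed from either the total or the
    free concentration via the quasi-steady-state maps.
    """

    x: float
    xf: float
    xb: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.x < 0 or self.xf < 0 or self.xb < 0:
            raise ValueError("protein concentrations must be non-negative")
        if not math.isclose(self.x, self.xf + self.xb, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("total protein must equal free plus bound")

    @classmethod
    def from_total(cls, x: float, params: GeneCircuitParams) -> "ProteinState":
        xf = free_from_total(x, params)
        return cls(x=x, xf=xf, xb=x - xf)

    @classmethod
    def from_free(cls, xf: float, params: GeneCircuitParams) -> "ProteinState":
        xb = bound_from_free(xf, params)
        return cls(x=xf + xb, xf=xf, xb=xb)


def free_from_total(x: float, params: GeneCircuitParams) -> float:
    """Free protein ``xf`` given total protein ``x``.

    Inverts ``x = xf + y*xf/(xf+kb)`` in closed form.  For ``x`` well above
    the decoy capacity the textbook root formula subtracts nearly equal
    numbers, so the algebraically equivalent rationalized branch
    ``2*kb*x / (kb + y - x + sqrt(...))`` is used there.
    """
    if x < 0:
        raise ValueError(f"total protein must be non-negative, got {x}")
    if x == 0.0:
        return 0.0
    y, kb = params.y, params.kb
    if y == 0.0:
        return x
    d = kb + y - x
    s = math.sqrt(d * d + 4.0 * kb * x)
    if x > y + kb:
        xf = 2.0 * kb * x / (d + s)
    else:
        xf = 0.5 * (x - y - kb + s)
    # one Newton step on the occupancy residual polishes the last ~1e-10
    # of relative error left by cancellation at extreme x
    r = xf + kb
    g = xf + y * xf / r - x
    xf -= g / (1.0 + y * kb / (r * r))
    return max(xf, 0.0)


def total_from_free(xf: float, params: GeneCircuitParams) -> float:
    """Total protein ``x = xf + y*xf/(xf+kb)`` given free protein ``xf``."""
    if xf < 0:
        raise ValueError(f"free protein must be non-negative, got {xf}")
    return xf + params.y * xf / (xf + params.kb)


def bound_from_free(xf: float, params: GeneCircuitParams) -> float:
    """Decoy-bound protein ``xb = y*xf/(xf+kb)``; saturates at ``y``."""
    if xf < 0:
        raise ValueError(f"free protein must be non-negative, got {xf}")
    return params.y * xf / (xf + params.kb)


def degradation_rate(x: float, params: GeneCircuitParams) -> float:
    """Aggregate degradation rate ``c(x) = xf + gamma_b*(x - xf)``.

    Free protein decays at unit rate (the time unit); bound protein at
    ``gamma_b``.  Nondecreasing in ``x`` and zero at ``x = 0``.
    """
    if x < 0:
        raise ValueError(f"total protein must be non-negative, got {x}")
    xf = free_from_total(x, params)
    return xf + params.gamma_b * (x - xf)


def burst_rate(x: float, params: GeneCircuitParams) -> float:
    """Autoregulated burst rate ``a(x) = a0 + a1*xf/(kp + xf)``.

    Non-cooperative (Michaelis-Menten) activation by free protein; bounded
    in ``[a0, a0 + a1]``.
    """
    if x < 0:
        raise ValueError(f"total protein must be non-negative, got {x}")
    xf = free_from_total(x, params)
    return params.a0 + params.a1 * xf / (params.kp + xf)


def burst_rate_free(xf: float, params: GeneCircuitParams) -> float:
    """Burst rate expressed in the free-protein coordinate."""
    if xf < 0:
        raise ValueError(f"free protein must be non-negative, got {xf}")
    return params.a0 + params.a1 * xf / (params.kp + xf)


def degradation_rate_free(xf: float, params: GeneCircuitParams) -> float:
    """Degradation rate in the free-protein coordinate:
    ``c = xf*(xf + kb + gamma_b*y)/(xf + kb)``."""
    if xf < 0:
        raise ValueError(f"free protein must be non-negative, got {xf}")
    return xf * (xf + params.kb + params.gamma_b * params.y) / (xf + params.kb)


def binding_jacobian(xf: float, params: GeneCircuitParams) -> float:
    """dx/dxf = 1 + y*kb/(xf+kb)^2, the total-vs-free change of variables."""
    r = (xf + params.kb)
    return 1.0 + params.y * params.kb / (r * r)
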