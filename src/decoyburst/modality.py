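"""Mode counting and bimodality phase diagrams.

Whether the stationary protein distribution has one mode or two depends on
the scale it is viewed on.  On the linear scale, extrema of p(x) occur where

    a0 + a1*xf/(kp+xf) - xf/b - y*xf/(b*(xf+kb)) - 1 = 0

(in the free-protein coordinate, for equal free/bound decay, gamma_b = 1);
on the log10 scale the condition is the same expression without the final
``-1``.  A mode appears or disappears when the extremum function crosses
zero tangentially, i.e. when additionally

    a1*kp/(kp+xf)^2 - 1/b - y*kb/(b*(xf+kb)^2) = 0.

Solving the tangency condition for kp (a quadratic) and then the extremum
condition for a0, for a sweep of xf values, traces the boundary between the
unimodal and bimodal regions of the (a0, kp) parameter plane.  Because the
two extremum functions differ by the constant 1, the log-scale boundary is
the linear-scale boundary translated by exactly 1 leftward along the a0
axis.

On the linear scale the density can additionally diverge at the origin
(when the origin exponent q1 < 1); that singular peak at zero protein is
counted as a (low-expression) mode.  For gamma_b != 1, where the analytic
conditions above do not apply, modes are located numerically on the
normalized density grid.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .model_core import GeneCircuitParams, total_from_free
from .stationary_density import normalize, origin_exponent

__all__ = [
    "Scale",
    "ExtremumKind",
    "OriginBehavior",
    "ExtremumSet",
    "ModalityReport",
    "BoundaryCurve",
    "extremum_function",
    "tangency_function",
    "find_extrema",
    "count_modes",
    "boundary_curve",
    "phase_diagram",
]

# Root scan settings: the extremum functions are smooth with few roots, so a
# dense log-spaced sign scan followed by bisection is robust.
SCAN_LO, SCAN_HI, SCAN_N = 1e-4, 1e6, 2000
ROOT_RTOL = 1e-10
TANGENCY_ATOL = 1e-8


class Scale(str, enum.Enum):
    LINEAR = "linear"
    LOG10 = "log10"


class ExtremumKind(str, enum.Enum):
    MAXIMUM = "maximum"
    MINIMUM = "minimum"


class OriginBehavior(str, enum.Enum):
    SINGULAR = "singular"  # density diverges as x -> 0
    FINITE = "finite"  # finite positive limit
    VANISHING = "vanishing"  # density -> 0


@dataclass(frozen=True)
class ExtremumSet:
    """Roots of the extremum equation with their classification."""

    scale: Scale
    roots_xf: tuple
    kinds: tuple
    origin_behavior: OriginBehavior


@dataclass(frozen=True)
class ModalityReport:
    """Mode count of the stationary density on the stated scale.

    ``mode_locations_x`` are total-protein positions of the maxima; the
    singular origin peak (linear scale, q1 < 1) is reported as location 0.
    """

    scale: Scale
    n_modes: int
    mode_locations_x: tuple


@dataclass(frozen=True)
class BoundaryCurve:
    """One branch of the unimodal/bimodal boundary in the (a0, kp) plane.

    Points are parameterized by the free-protein level xf at which the
    density's extremum structure degenerates (tangential zero crossing).
    """

    scale: Scale
    branch: str
    xf: np.ndarray
    a0: np.ndarray
    kp: np.ndarray
    fixed: dict = field(default_factory=dict)


def _require_gamma_one(params: GeneCircuitParams) -> None:
    if params.gamma_b != 1.0:
        raise ValueError(
            "analytic extremum conditions hold for gamma_b = 1 only; "
            "use count_modes, which falls back to the density grid"
        )


def extremum_function(xf, params: GeneCircuitParams, scale: Scale = Scale.LINEAR):
    """Extremum condition for the stationary density at free protein xf.

    Zero where dp/dx (linear) or dp_log/dz (log10) vanishes; requires
    gamma_b = 1.  Accepts a scalar or an array of xf values.
    """
    _require_gamma_one(params)
    if np.any(np.asarray(xf) <= 0):
        raise ValueError("extremum function defined for xf > 0")
    v = (
        params.a0
        + params.a1 * xf / (params.kp + xf)
        - xf / params.b
        - params.y * xf / (params.b * (xf + params.kb))
    )
    if Scale(scale) is Scale.LINEAR:
        v = v - 1.0
    return v


def tangency_function(xf, params: GeneCircuitParams):
    """Derivative of the extremum function w.r.t. xf (both scales share it).

    Zero when the extremum function crosses zero tangentially — the
    condition for a mode to appear or disappear.  Scalar or array xf.
    """
    _require_gamma_one(params)
    if np.any(np.asarray(xf) <= 0):
        raise ValueError("tangency function defined for xf > 0")
    return (
        params.a1 * params.kp / (params.kp + xf) ** 2
        - 1.0 / params.b
        - params.y * params.kb / (params.b * (xf + params.kb) ** 2)
    )


def _origin_behavior(params: GeneCircuitParams) -> OriginBehavior:
    e = origin_exponent(params)
    if e < 0:
        return OriginBehavior.SINGULAR
    if e == 0:
        return OriginBehavior.FINITE
    return OriginBehavior.VANISHING


def find_extrema(
    params: GeneCircuitParams, scale: Scale = Scale.LINEAR
) -> ExtremumSet:
    """Locate and classify all roots of the extremum function.

    Sign scan on a log-spaced xf grid followed by bisection.  Consecutive
    roots alternate between maxima and minima; the first kind follows from
    the sign of the extremum function as xf -> 0+ (positive: density rising,
    so the first root is a maximum).  Tangential (double) roots, where the
    tangency function also vanishes, are inflections and are dropped.
    """
    scale = Scale(scale)
    grid = np.geomspace(SCAN_LO, SCAN_HI, SCAN_N)
    f = extremum_function(grid, params, scale)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if f[i] == 0.0:
            roots.append(grid[i])
        elif f[i] * f[i + 1] < 0:
            r = brentq(
                extremum_function,
                grid[i],
                grid[i + 1],
                args=(params, scale),
                rtol=ROOT_RTOL,
            )
            roots.append(r)
    # drop tangential double roots (inflections, not extremum pairs)
    roots = [r for r in roots if abs(tangency_function(r, params)) > TANGENCY_ATOL
             or abs(extremum_function(r, params, scale)) > TANGENCY_ATOL]
    # limit of the extremum function as xf -> 0+
    f0 = params.a0 - (1.0 if scale is Scale.LINEAR else 0.0)
    kinds: list[ExtremumKind] = []
    rising = f0 > 0
    for _ in roots:
        kinds.append(ExtremumKind.MAXIMUM if rising else ExtremumKind.MINIMUM)
        rising = not rising
    return ExtremumSet(
        scale=scale,
        roots_xf=tuple(roots),
        kinds=tuple(kinds),
        origin_behavior=_origin_behavior(params),
    )


def _count_modes_numeric(
    params: GeneCircuitParams, scale: Scale
) -> ModalityReport:
    """Mode count from the normalized density grid (any gamma_b).

    Local maxima are detected by neighbor comparison with a relative
    prominence floor; on the linear scale a singular origin (q1 < 1) adds
    the low-expression peak at x = 0.
    """
    from .stationary_density import density_log10

    grid = normalize(params)
    if scale is Scale.LOG10:
        grid = density_log10(grid, params)
    v = grid.values
    floor = v.max() * 1e-12
    locs: list[float] = []
    for i in range(1, len(v) - 1):
        if v[i] > floor and v[i] > v[i - 1] and v[i] >= v[i + 1]:
            # skip plateaus counted twice
            if locs and np.isclose(grid.abscissae[i], locs[-1]):
                continue
            locs.append(float(grid.abscissae[i]))
    if scale is Scale.LOG10:
        locs = [10.0 ** z for z in locs]
    n = len(locs)
    if scale is Scale.LINEAR and origin_exponent(params) < 0:
        locs = [0.0] + locs
        n += 1
    return ModalityReport(scale=scale, n_modes=n, mode_locations_x=tuple(locs))


def count_modes(params: GeneCircuitParams, scale: Scale = Scale.LINEAR) -> ModalityReport:
    """Number of modes of the stationary density on the given scale.

    For gamma_b = 1 the analytic extremum equation is solved; interior
    maxima are counted, plus the singular origin peak on the linear scale
    when the origin exponent q1 is below 1 (at q1 exactly 1 the density has
    a finite origin limit and the origin is not counted).  For other
    gamma_b the count comes from the density grid directly.
    """
    if params.a0 <= 0:
        raise ValueError("modality undefined at a0 = 0 (non-normalizable)")
    scale = Scale(scale)
    if params.gamma_b != 1.0:
        return _count_modes_numeric(params, scale)
    ext = find_extrema(params, scale)
    maxima = [
        r
        for r, k in zip(ext.roots_xf, ext.kinds)
        if k is ExtremumKind.MAXIMUM
    ]
    locs = [total_from_free(r, params) for r in maxima]
    n = len(locs)
    if scale is Scale.LINEAR and ext.origin_behavior is OriginBehavior.SINGULAR:
        locs = [0.0] + locs
        n += 1
    if scale is Scale.LOG10 and n == 0:
        # density vanishes at both ends of the z axis yet integrates to one,
        # so a rounded (gridded) maximum must exist even if the analytic
        # extremum equation found no transversal root (tangential case)
        n = 1
        locs = []
    return ModalityReport(scale=scale, n_modes=n, mode_locations_x=tuple(locs))


def _tangency_kp_roots(xf: float, params_fixed: GeneCircuitParams) -> list[float]:
    """Positive kp solving the tangency condition at the given xf.

    The condition a1*kp/(kp+xf)^2 = R with R = (1/b)*(1 + y*kb/(xf+kb)^2)
    is the quadratic R*kp^2 + (2*R*xf - a1)*kp + R*xf^2 = 0.
    """
    b, y, kb, a1 = (
        params_fixed.b,
        params_fixed.y,
        params_fixed.kb,
        params_fixed.a1,
    )
    R = (1.0 / b) * (1.0 + y * kb / (xf + kb) ** 2)
    A, B, C = R, 2.0 * R * xf - a1, R * xf * xf
    disc = B * B - 4.0 * A * C
    if disc < 0:
        return []
    s = math.sqrt(disc)
    roots = sorted(((-B - s) / (2.0 * A), (-B + s) / (2.0 * A)))
    return [r for r in roots if r > 0]


def boundary_curve(
    fixed: GeneCircuitParams,
    xf_grid: Sequence[float],
    scale: Scale = Scale.LINEAR,
) -> list[BoundaryCurve]:
    """Trace the unimodal/bimodal boundary in the (a0, kp) plane.

    For each xf on the sweep, the tangency condition fixes up to two
    positive kp values (branches "low" and "high"); the extremum condition
    then yields the a0 at which the mode structure degenerates there.
    Points with a0 <= 0 are dropped.  The log-scale curves equal the
    linear-scale curves shifted by -1 in a0.

    ``fixed`` supplies a1, b, y, kb (gamma_b must be 1); its a0 and kp
    entries are ignored.
    """
    _require_gamma_one(fixed)
    scale = Scale(scale)
    shift = 1.0 if scale is Scale.LINEAR else 0.0
    # points per quadratic root index (0: smaller kp, 1: larger kp)
    per_root: dict[int, list[tuple[float, float, float]]] = {0: [], 1: []}
    for xf in xf_grid:
        if xf <= 0:
            raise ValueError("xf sweep must be positive")
        kps = _tangency_kp_roots(xf, fixed)
        for idx, kp in enumerate(kps):
            # a0 from the extremum condition at (xf, kp)
            a0 = (
                shift
                + xf / fixed.b
                + fixed.y * xf / (fixed.b * (xf + fixed.kb))
                - fixed.a1 * xf / (kp + xf)
            )
            if a0 > 0:
                per_root[idx].append((xf, a0, kp))
    # Each quadratic root traces an arc kp(xf) that may rise and fall; the
    # figure-level "branches" enclosing the bimodal region are the monotone
    # legs of these arcs, so split each arc at turning points of kp.
    segments: list[np.ndarray] = []
    for pts in per_root.values():
        if len(pts) < 2:
            if pts:
                segments.append(np.array(pts))
            continue
        arr = np.array(pts)
        direction = np.sign(np.diff(arr[:, 2]))
        cuts = [0]
        for i in range(1, len(direction)):
            if direction[i] != 0 and direction[i - 1] != 0 and direction[i] != direction[i - 1]:
                cuts.append(i + 1)
        cuts.append(len(arr))
        for s, e in zip(cuts, cuts[1:]):
            if e - s >= 1:
                segments.append(arr[s:e])
    segments.sort(key=lambda a: a[:, 2].mean())
    names = ["low", "high"] if len(segments) == 2 else [
        f"branch{i + 1}" for i in range(len(segments))
    ]
    if len(segments) == 1:
        names = ["low"]
    fixed_meta = {
        "a1": fixed.a1,
        "b": fixed.b,
        "y": fixed.y,
        "kb": fixed.kb,
        "gamma_b": fixed.gamma_b,
    }
    return [
        BoundaryCurve(
            scale=scale,
            branch=name,
            xf=arr[:, 0],
            a0=arr[:, 1],
            kp=arr[:, 2],
            fixed=fixed_meta,
        )
        for name, arr in zip(names, segments)
    ]


def phase_diagram(
    fixed: GeneCircuitParams,
    a0_range: tuple,
    kp_range: tuple,
    resolution: int = 30,
    scale: Scale = Scale.LINEAR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mode counts over a rectangular (a0, kp) grid.

    Returns (a0_values, kp_values, counts) with counts[i, j] the number of
    modes at (a0_values[i], kp_values[j]).  Uses the analytic path for
    gamma_b = 1 and the density-grid fallback otherwise.
    """
    a0s = np.linspace(a0_range[0], a0_range[1], resolution)
    kps = np.linspace(kp_range[0], kp_range[1], resolution)
    a0s = a0s[a0s > 0]
    kps = kps[kps > 0]
    counts = np.zeros((len(a0s), len(kps)), dtype=int)
    for i, a0 in enumerate(a0s):
        for j, kp in enumerate(kps):
            p = fixed.with_(a0=float(a0), kp=float(kp))
            counts[i, j] = count_modes(p, scale).n_modes
    return a0s, kps, counts
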