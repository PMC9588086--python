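"""Fickian drug penetration into a hydrogel slab (semi-infinite erf model).

A hydrogel held at constant surface concentration ``c0`` (the perfused drug
solution) and initially drug-free follows the classic semi-infinite solution
of Fick's second law,

    c(x, t) = c0 * (1 - erf( x / (2 sqrt(D t)) )),

with ``D`` the drug diffusivity in the gel (measured here by FCS).  The model
assumes no drug consumption or binding and ignores the far boundary of the
slab, which is conservative for penetration estimates at early times.

The profile depends on depth and time only through the similarity variable
x / sqrt(D t); doubling the depth and quadrupling the time gives the same
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

from chipscreen.exceptions import InvalidInputError


@dataclass(frozen=True)
class PenetrationSpec:
    """State of the erf model: boundary concentration, gel diffusivity, depth, time.

    ``c0`` carries the drug's own units (mM, uM, ...); ``diffusivity`` m^2/s,
    ``depth`` m, ``time`` s.
    """

    c0: float
    diffusivity: float
    depth: float
    time: float

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise InvalidInputError(f"c0 must be >= 0, got {self.c0}")
        if not (self.diffusivity > 0):
            raise InvalidInputError(f"diffusivity must be > 0, got {self.diffusivity}")
        if self.depth < 0:
            raise InvalidInputError(f"depth must be >= 0, got {self.depth}")
        if self.time < 0:
            raise InvalidInputError(f"time must be >= 0, got {self.time}")


def concentration_at(spec: PenetrationSpec) -> float:
    """c(x, t) = c0 (1 - erf(x / 2 sqrt(D t))), in the units of ``c0``.

    The boundary is held at ``c0`` (x = 0 returns ``c0`` exactly); at t = 0
    with x > 0 the limiting value 0 is returned.
    """
    if spec.depth == 0.0:
        return spec.c0
    if spec.time == 0.0:
        return 0.0
    arg = spec.depth / (2.0 * np.sqrt(spec.diffusivity * spec.time))
    return float(spec.c0 * (1.0 - erf(arg)))


def penetration_profile(
    c0: float, diffusivity: float, depths, times
) -> np.ndarray:
    """Concentration matrix over a depth grid (rows) and time grid (columns)."""
    depths = np.asarray(depths, dtype=float)
    times = np.asarray(times, dtype=float)
    if depths.size == 0 or times.size == 0:
        raise InvalidInputError("depth and time grids must be non-empty")
    if np.any(depths < 0) or np.any(times < 0):
        raise InvalidInputError("depths and times must be >= 0")
    out = np.empty((depths.size, times.size))
    for i, x in enumerate(depths):
        for j, t in enumerate(times):
            out[i, j] = concentration_at(PenetrationSpec(c0, diffusivity, x, t))
    return out


def time_to_threshold(c_target: float, x: float, diffusivity: float, c0: float) -> float:
    """Time (s) at which depth ``x`` first reaches concentration ``c_target``.

    Solves c(x, t) = c_target by bracketing bisection (Brent) on t; the
    solution is unique because c is strictly increasing in t at fixed x > 0.

    Raises
    ------
    InvalidInputError
        If ``c_target`` is not strictly between 0 and ``c0`` (the boundary
        value is only reached in the infinite-time limit), or ``x <= 0``.
    """
    if not (x > 0):
        raise InvalidInputError(f"x must be > 0, got {x}")
    if not (diffusivity > 0):
        raise InvalidInputError(f"diffusivity must be > 0, got {diffusivity}")
    if not (0 < c_target < c0):
        raise InvalidInputError(
            f"c_target must satisfy 0 < c_target < c0 ({c0}), got {c_target}"
        )

    def shortfall(t: float) -> float:
        return concentration_at(PenetrationSpec(c0, diffusivity, x, t)) - c_target

    # characteristic diffusion time sets the scale; expand outward until bracketed
    t_scale = x**2 / (4.0 * diffusivity)
    lo, hi = t_scale * 1e-12, t_scale
    while shortfall(hi) < 0:
        hi *= 10.0
        if hi > t_scale * 1e12:  # pragma: no cover - c_target < c0 guarantees a root
            raise InvalidInputError("failed to bracket the threshold time")
    return float(brentq(shortfall, lo, hi, rtol=1e-9))
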