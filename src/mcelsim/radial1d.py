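"""Quasi-1D radial analytical model of the necrotic radius.

At zeroth order in the Michaelis–Menten half-rate constant, consumption is
constant wherever solute is present and the concentration is C1-regular:
zero value and zero gradient at the necrotic radius ``rn``.  Solving the
radial diffusion–reaction balance with interface concentration ``gamma*``
gives one transcendental equation per supply regime (``rn* = rn/a``):

* maximal supply (``gamma* = 1``), cylinder:
  ``1 = Da/4*(1 - rn*^2) + Da/2*rn*^2*ln(rn*)``
* static culture, the interface concentration follows from the diffusive
  supply balance, ``gamma* = 1 - (1 - rn*^2)/Sd``
* microfluidic culture, from the convective balance,
  ``gamma* = 1 + (exp(-Pe1) - 1)/Sc*(1 - rn*^2)``

A root in (0, 1) exists only when the interface concentration cannot sustain
the whole section; otherwise ``rn* = 0`` (the construct is fully supplied —
necrosis prevented).  The onset of rate-induced necrosis at maximal supply is
``Da = 4`` for a cylinder and ``Da = 6`` for a sphere.

The sphere variants use the spherical zeroth-order interior solution and the
per-solid-angle consumption ``(1 - rn*^3)``; supply numbers then carry the
factor 3: ``Sd = 3*Rd/Da``, ``Sc = 3*Rd*Pe1/Da``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, TextIO

import numpy as np
from scipy.optimize import brentq

from .params import Shape


class Regime(str, Enum):
    maximal_supply = "maximal_supply"
    static = "static"
    microfluidic = "microfluidic"


@dataclass(frozen=True)
class RadialSolution:
    """Root of one regime's necrotic-radius equation.

    ``phi_live = 1 - rn*^2`` (cylinder) or ``1 - rn*^3`` (sphere);
    ``gamma_star`` is the interface concentration implied by the supply
    balance at the root; ``delta_star = 1 - rn*`` is the live-rim thickness.
    """

    rn_star: float
    phi_live: float
    gamma_star: float
    delta_star: float
    regime: Regime
    shape: Shape
    converged: bool
    residual: float


_RTOL = 1e-10
_SCAN_POINTS = 200


def _interior_term(rn: float, Da: float, shape: Shape) -> float:
    """Interface concentration required by the interior solution: the value
    of ``gamma*`` such that c(rn)=0, c'(rn)=0 and c(1)=gamma*."""
    if shape is Shape.cylinder:
        if rn == 0.0:
            return Da / 4.0
        return Da / 4.0 * (1.0 - rn * rn) + Da / 2.0 * rn * rn * math.log(rn)
    # sphere: c(r) = Da*((r^2 - rn^2)/6 + rn^3/3*(1/r - 1/rn))
    return Da * ((1.0 - rn * rn) / 6.0 - rn * rn * (1.0 - rn) / 3.0)


def _gamma_supply(rn: float, regime: Regime, shape: Shape,
                  Sd: float = math.inf, Sc: float = math.inf,
                  Pe1: float = math.inf) -> float:
    """Interface concentration delivered by the external supply balance."""
    m = 2 if shape is Shape.cylinder else 3
    consumed = 1.0 - rn**m
    if regime is Regime.maximal_supply:
        return 1.0
    if regime is Regime.static:
        return 1.0 - consumed / Sd
    return 1.0 + (math.exp(-Pe1) - 1.0) / Sc * consumed


def _residual(rn: float, Da: float, regime: Regime, shape: Shape,
              Sd: float, Sc: float, Pe1: float) -> float:
    return _gamma_supply(rn, regime, shape, Sd, Sc, Pe1) \
        - _interior_term(rn, Da, shape)


def _solve(Da: float, regime: Regime, shape: Shape,
           Sd: float = math.inf, Sc: float = math.inf,
           Pe1: float = math.inf) -> RadialSolution:
    """Sign-scan on log-spaced points in (0, 1) then Brent bisection.

    The transcendental has at most one admissible root in (0, 1) but is flat
    near 0, which defeats naive Newton; a bracketed scan is robust.
    """
    if Da <= 0:
        raise ValueError(f"Da must be strictly positive, got {Da!r}")
    f = lambda r: _residual(r, Da, regime, shape, Sd, Sc, Pe1)
    lo = 1e-9
    f_lo = f(lo)
    if f_lo >= 0.0:
        # supply meets demand everywhere: no necrotic core
        gamma = _gamma_supply(0.0, regime, shape, Sd, Sc, Pe1)
        return RadialSolution(rn_star=0.0, phi_live=1.0, gamma_star=gamma,
                              delta_star=1.0, regime=regime, shape=shape,
                              converged=True, residual=0.0)
    grid = np.concatenate([
        np.geomspace(lo, 0.5, _SCAN_POINTS // 2),
        1.0 - np.geomspace(1e-12, 0.5, _SCAN_POINTS // 2)[::-1]])
    vals = np.array([f(r) for r in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return RadialSolution(rn_star=float("nan"), phi_live=float("nan"),
                              gamma_star=float("nan"), delta_star=float("nan"),
                              regime=regime, shape=shape, converged=False,
                              residual=float(np.min(np.abs(vals))))
    i = sign_change[-1]
    rn = brentq(f, grid[i], grid[i + 1], xtol=_RTOL, rtol=8.9e-16)
    m = 2 if shape is Shape.cylinder else 3
    return RadialSolution(
        rn_star=float(rn), phi_live=float(1.0 - rn**m),
        gamma_star=_gamma_supply(rn, regime, shape, Sd, Sc, Pe1),
        delta_star=float(1.0 - rn), regime=regime, shape=shape,
        converged=True, residual=abs(f(rn)))


def rn_maximal(Da: float, shape: Shape | str = Shape.cylinder) -> RadialSolution:
    """Necrotic radius at maximal supply (interface held at the source value).

    Returns ``rn* = 0`` for ``Da <= 4`` (cylinder) / ``Da <= 6`` (sphere).
    """
    return _solve(Da, Regime.maximal_supply, Shape(shape))


def rn_static(Da: float, Sd: float,
              shape: Shape | str = Shape.cylinder) -> RadialSolution:
    """Necrotic radius in static culture with diffusive supply number ``Sd``.

    ``rn* = 0`` whenever ``Sd*(1 - Da/4) >= 1`` (cylinder; factor per shape).
    """
    if Sd <= 0:
        raise ValueError(f"Sd must be strictly positive, got {Sd!r}")
    return _solve(Da, Regime.static, Shape(shape), Sd=Sd)


def rn_microfluidic(Da: float, Sc: float, Pe1: float,
                    shape: Shape | str = Shape.cylinder) -> RadialSolution:
    """Necrotic radius in microfluidic culture with convective supply ``Sc``.

    ``rn* = 0`` is guaranteed by ``Sc*(1 - Da/4) > 1`` (the supply prefactor
    ``1 - exp(-Pe1)`` is below one, so the condition is sufficient).
    """
    if Sc <= 0 or Pe1 <= 0:
        raise ValueError("Sc and Pe1 must be strictly positive")
    return _solve(Da, Regime.microfluidic, Shape(shape), Sc=Sc, Pe1=Pe1)


def asymptotic_maximal(Da: float) -> tuple[float, float]:
    """High-Da closed forms for the cylinder at maximal supply:
    ``rn* = 1 - sqrt(2/Da)`` and ``phi_live = 2*(-1/Da + sqrt(2/Da))``.

    Valid for ``Da >= 2`` (below which the formula returns a negative
    radius and a :class:`ValueError` is raised).
    """
    if Da < 2.0:
        raise ValueError(
            f"asymptotic form out of range: Da={Da!r} < 2 gives rn* < 0")
    rn = 1.0 - math.sqrt(2.0 / Da)
    phi = 2.0 * (-1.0 / Da + math.sqrt(2.0 / Da))
    return rn, phi


def phi_ratio_static(Rd: float, Sd: float) -> float:
    """Live fraction in static culture relative to its maximal-supply value,
    for rate-induced necrosis with ample supply:
    ``phi0/phi_inf = -(Rd*Sd)^{-1/2} + (1 + (Rd*Sd)^{-1})^{1/2}``.

    Monotone increasing in ``Rd*Sd`` with limit 1 (maximal supply).
    """
    x = Rd * Sd
    if x <= 0:
        raise ValueError(f"Rd*Sd must be strictly positive, got {x!r}")
    return -x**-0.5 + math.sqrt(1.0 + 1.0 / x)


def find_da_onset_1d(shape: Shape | str = Shape.cylinder,
                     tol: float = 1e-6) -> float:
    """Smallest Da with a strictly positive maximal-supply root, by bisection.

    Analytically 4 (cylinder) and 6 (sphere); recovered here to ``tol``.
    """
    shape = Shape(shape)
    lo, hi = 0.5, 50.0
    assert rn_maximal(lo, shape).rn_star == 0.0
    assert rn_maximal(hi, shape).rn_star > 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rn_maximal(mid, shape).rn_star > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def write_table(rows: Iterable[RadialSolution], fp: TextIO,
                Da: Iterable[float] | None = None,
                Sd: Iterable[float] | None = None,
                Sc: Iterable[float] | None = None,
                Pe1: Iterable[float] | None = None) -> None:
    """Emit a CSV table (regime, Da, Sd, Sc, Pe1, rn_star, phi_live)."""
    rows = list(rows)
    n = len(rows)
    def col(x):
        return list(x) if x is not None else [""] * n
    fp.write("regime,Da,Sd,Sc,Pe1,rn_star,phi_live\n")
    for sol, da, sd, sc, pe in zip(rows, col(Da), col(Sd), col(Sc), col(Pe1)):
        fp.write(f"{sol.regime.value},{da},{sd},{sc},{pe},"
                 f"{sol.rn_star:.12g},{sol.phi_live:.12g}\n")
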