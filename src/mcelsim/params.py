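"""Dimensional parameters, dimensionless groups, and closed-form design rules.

The model currency is a small set of dimensionless numbers built from the
chamber, fluid, construct and solute properties:

* ``Re``  — Reynolds number of the channel flow, ``rho*v0*a/mu``.
* ``Pe1`` — channel Péclet number, ``v0*L/D1`` (convection over the
  inlet–construct distance vs. diffusion in the medium).
* ``Pe2`` — construct Péclet number, ``k*v0/(a*D2)``; transpiration through
  the porous construct vs. internal diffusion.  ``Pe2 < 0.1`` justifies a
  diffusion–reaction description inside the construct.
* ``Da``  — Damköhler number, ``Rmax*a**2/(c0*D2)``; consumption kinetics vs.
  internal diffusion.  Above a shape-dependent onset ``Da_inf`` (4 for a
  cylinder, 6 for a sphere) necrosis is *rate-induced* and no amount of
  external supply prevents it.
* ``Rd``  — gradient-scale ratio ``a*D1/(L*D2)``: supply-limited (low) vs.
  rate-limited (high) diffusion into the construct.
* ``Sd``, ``Sc`` — diffusive and convective supply numbers: the excess of
  solute delivered to the fluid–construct interface relative to what the
  construct consumes.  ``Sd = 2*Rd/Da`` and ``Sc = Sd*Pe1`` for a cylinder
  (factor 3 instead of 2 for a sphere).

The design rules evaluated here are the necrosis-prevention conditions
``Sd*(1 - Da/Da_inf) >= 1`` (static culture) and ``Sc*(1 - Da/4) > 1``
(microfluidic culture), the inlet-velocity threshold they imply, the
convection level of maximum supply asymmetry ``sqrt(Da)*Sc = 4*sqrt(2)``,
and the corner-recirculation (Moffatt-eddy) supply numbers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from enum import Enum
from typing import TextIO


class Shape(str, Enum):
    """Cross-sectional idealization of the construct in the 1D radial model."""

    cylinder = "cylinder"
    sphere = "sphere"


#: Onset Damköhler number of rate-induced necrosis per shape (maximal supply).
DA_ONSET = {Shape.cylinder: 4.0, Shape.sphere: 6.0}

#: Supply numbers carry a shape factor: Sd = F*Rd/Da, Sc = F*Rd*Pe1/Da.
SHAPE_FACTOR = {Shape.cylinder: 2.0, Shape.sphere: 3.0}


class ParameterError(ValueError):
    """A physical parameter violates its domain; the offending symbol is named."""


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional (SI) description of one chamber/construct/solute setup.

    Attributes
    ----------
    rho : fluid density [kg m^-3]
    mu : dynamic viscosity [Pa s]
    v0 : peak inlet velocity [m s^-1]
    a : construct radius [m]
    L : inlet–construct distance [m]
    h : channel half-height [m]
    k : Darcy permeability of the construct [m^2]
    D1, D2 : solute diffusivity in the channel / in the construct [m^2 s^-1]
    Rmax : maximum volumetric consumption rate [mol m^-3 s^-1]
    K_half : Michaelis–Menten half-rate concentration [same units as c0]
    c0 : inlet solute concentration [mol m^-3]
    cn : necrosis threshold concentration; defaults to ``1e-3 * c0``
    q : corner-eddy velocity ratio (peak speed of the largest recirculation
        eddy over ``v0``); dimensionless, default ``1e-3``
    """

    rho: float
    mu: float
    v0: float
    a: float
    L: float
    h: float
    k: float
    D1: float
    D2: float
    Rmax: float
    K_half: float
    c0: float
    cn: float | None = None
    q: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "v0", "a", "L", "h", "k", "D1", "D2",
                     "Rmax", "K_half", "c0"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and value > 0):
                raise ParameterError(
                    f"parameter {name!r} must be strictly positive, got {value!r}")
        if self.q < 0:
            raise ParameterError(f"parameter 'q' must be non-negative, got {self.q!r}")
        if self.cn is None:
            object.__setattr__(self, "cn", 1e-3 * self.c0)
        if not 0 < self.cn < self.c0:
            raise ParameterError(
                f"parameter 'cn' must lie in (0, c0), got {self.cn!r}")
        if self.K_half / self.c0 > 0.1:
            warnings.warn(
                "K_half/c0 = %.3g > 0.1: the zeroth-order (sharp-cutoff) "
                "analytical layer degrades for non-small half-rate constants"
                % (self.K_half / self.c0), stacklevel=2)


@dataclass(frozen=True)
class DimensionlessSet:
    """Every dimensionless group of the model, plus diffusion velocity scales.

    ``vdif1 = 2*D1/L`` and ``vdif2 = 2*D2/a`` are the diffusion velocity
    scales of the channel and of the construct (scale ``2*D/d`` over a
    distance ``d``); they convert supply conditions into inlet-velocity
    requirements.
    """

    Re: float
    Pe1: float
    Pe2: float
    Da: float
    Rd: float
    Sd: float
    Sc: float
    K_half_star: float
    cn_star: float
    Pe_rho: float
    Sc_rho: float
    q: float
    shape: Shape
    vdif1: float
    vdif2: float


def peclet_corner(Rd: float, Sd: float, Pe1: float, q: float,
                  rn0_star: float | None = None) -> float:
    """Corner Péclet number of the largest recirculation eddy.

    The eddy peak speed is ``q*v0``; the concentration gradient feeding the
    corner is taken from the quasi-1D no-flow solution.  With the necrotic
    radius of that solution, ``Pe_rho = q*Pe1*(Sd/(1 - rn0*^2) - 1)``.
    Eliminating ``rn0*`` with the static boundary-layer thickness valid at
    high Da gives the closed form

        ``Pe_rho = q*Pe1*(sqrt(1 + Rd*Sd) - 1)/2``.

    Parameters
    ----------
    rn0_star : optional static necrotic radius in [0, 1).  When given, the
        explicit form above is used; otherwise the closed form.
    """
    if q < 0:
        raise ParameterError(f"parameter 'q' must be non-negative, got {q!r}")
    if rn0_star is not None:
        if not 0.0 <= rn0_star < 1.0:
            raise ParameterError(
                f"rn0_star must lie in [0, 1), got {rn0_star!r}")
        return q * Pe1 * (Sd / (1.0 - rn0_star**2) - 1.0)
    return q * Pe1 * (math.sqrt(1.0 + Rd * Sd) - 1.0) / 2.0


def peclet_corner_deficient(Rd: float, Sc: float, q: float) -> float:
    """Deficient-diffusive-supply scaling of the corner Péclet number.

    ``Pe_rho ~ q*Rd*Sc`` for ``Rd*Sd << 1``; an order-of-magnitude scaling
    (the exact small-``Rd*Sd`` limit of :func:`peclet_corner` carries an
    extra factor 1/4).
    """
    return q * Rd * Sc


def corner_numbers(d: "DimensionlessSet", rn0_star: float | None = None,
                   ) -> tuple[float, float]:
    """Return ``(Pe_rho, Sc_rho)`` for a dimensionless set.

    ``Sc_rho = q*Rd*Sd*Sc`` balances convective supply through the corner
    eddy against consumption; it plays the role of ``Sc`` for the interface
    portion screened by recirculation.
    """
    pe_rho = peclet_corner(d.Rd, d.Sd, d.Pe1, d.q, rn0_star)
    sc_rho = d.q * d.Rd * d.Sd * d.Sc
    return pe_rho, sc_rho


def compute_dimensionless(p: PhysicalParams,
                          shape: Shape | str = Shape.cylinder) -> DimensionlessSet:
    """Compute every dimensionless group from a dimensional parameter set.

    All groups are exact ratios of the inputs (no rounded intermediates).
    A warning is issued if ``Pe2 >= 0.1``, where the diffusion-only
    description of the construct interior is stressed.
    """
    shape = Shape(shape)
    Re = p.rho * p.v0 * p.a / p.mu
    Pe1 = p.v0 * p.L / p.D1
    Pe2 = p.k * p.v0 / (p.a * p.D2)
    Da = p.Rmax * p.a**2 / (p.c0 * p.D2)
    Rd = p.a * p.D1 / (p.L * p.D2)
    Sd = SHAPE_FACTOR[shape] * Rd / Da
    Sc = Sd * Pe1
    if Pe2 >= 0.1:
        warnings.warn(
            "Pe2 = %.3g >= 0.1: transpiration through the construct is not "
            "negligible and the internal diffusion-reaction approximation is "
            "stressed" % Pe2, stacklevel=2)
    pe_rho = peclet_corner(Rd, Sd, Pe1, p.q)
    return DimensionlessSet(
        Re=Re, Pe1=Pe1, Pe2=Pe2, Da=Da, Rd=Rd, Sd=Sd, Sc=Sc,
        K_half_star=p.K_half / p.c0, cn_star=p.cn / p.c0,
        Pe_rho=pe_rho, Sc_rho=p.q * Rd * Sd * Sc, q=p.q, shape=shape,
        vdif1=2.0 * p.D1 / p.L, vdif2=2.0 * p.D2 / p.a)


class NecrosisType(str, Enum):
    none = "none"
    supply_induced = "supply-induced"
    rate_induced = "rate-induced"


@dataclass(frozen=True)
class BalanceReport:
    """Solute-quantity balance over one angular section of the interface.

    ``nd``, ``nc`` and ``nR`` are the diffusive supply, convective supply and
    consumption quantities (normalized by ``c0*D2*dtheta``); with unit
    interface gradients and full consumption they reduce to the supply
    numbers: ``nd/nR = Sd`` and ``nc/nR = Sc``.
    """

    nd: float
    nc: float
    nR: float
    regime_diffusive: str
    regime_convective: str


def balance_report(d: DimensionlessSet, rn_star: float = 0.0,
                   grad_c1: float = 1.0, v_normal: float = 1.0,
                   gamma_star: float = 1.0) -> BalanceReport:
    """Per-section supply/consumption balance at the interface.

    With ``grad_c1`` the channel-side normal concentration gradient (in units
    ``c0/L``) and ``v_normal`` the normal fluid velocity (in units ``v0``),
    the supply-to-consumption ratios are ``Sd*grad_c1/(1-rn*^2)`` and
    ``Sc*gamma**v_normal/(1-rn*^2)``.
    """
    live = 1.0 - rn_star**2
    nd = d.Sd * grad_c1
    nc = d.Sc * gamma_star * v_normal
    nR = live
    return BalanceReport(
        nd=nd, nc=nc, nR=nR,
        regime_diffusive="rate-limited" if nd >= nR else "supply-limited",
        regime_convective="rate-limited" if nc >= nR else "supply-limited")


@dataclass(frozen=True)
class DesignReport:
    """Evaluation of the closed-form chamber design rules for one setup."""

    static_prevention_ok: bool
    static_margin: float
    microfluidic_prevention_ok: bool
    microfluidic_margin: float
    microfluidic_unsatisfiable: bool
    v0_required: float
    asymmetry_predictor: float
    asymmetry_peak: float
    v0_asymptote_scale: float
    necrosis_type: NecrosisType

    def to_json(self, fp: TextIO | None = None) -> str:
        payload = asdict(self)
        payload["necrosis_type"] = self.necrosis_type.value
        text = json.dumps(payload, indent=2)
        if fp is not None:
            fp.write(text)
        return text


#: Convection level of maximum supply asymmetry: sqrt(Da)*Sc = 4*sqrt(2).
ASYMMETRY_PEAK = 4.0 * math.sqrt(2.0)


def asymmetry_predictor(p: PhysicalParams) -> float:
    """``sqrt(Da)*Sc = 2*v0*sqrt(c0/(Rmax*D2))`` — depends on construct
    kinetics and inlet velocity only, not on ``a`` or ``L``."""
    return 2.0 * p.v0 * math.sqrt(p.c0 / (p.Rmax * p.D2))


def v0_required(d: DimensionlessSet, constant_divide: bool = True) -> float:
    """Inlet velocity above which convective supply prevents necrosis.

    The threshold is proportional to ``vdif2*(1/Da - 1/4)``; the
    proportionality constant is 1/4 by default (``constant_divide=True``,
    following the derivation path from the prevention condition with
    ``Sc = 2*c0*v0/(Rmax*a)``), or 4 with ``constant_divide=False``.
    Returns ``inf`` when ``Da >= 4`` (rate-induced necrosis; no velocity
    suffices).
    """
    if d.Da >= 4.0:
        return math.inf
    factor = 0.25 if constant_divide else 4.0
    return d.vdif2 * factor * (1.0 / d.Da - 0.25)


def v0_asymptote_scale(d: DimensionlessSet) -> float:
    """Velocity scale ``vdif2/Sd**2`` at which convection overcomes the
    diffusion-dominated screens (boundary layer, corner eddies) and the
    live fraction approaches its maximal-supply value."""
    return d.vdif2 / d.Sd**2


def evaluate_design_rules(d: DimensionlessSet,
                          da_onset: float | None = None,
                          constant_divide: bool = True) -> DesignReport:
    """Evaluate every closed-form design rule for one dimensionless set.

    Parameters
    ----------
    da_onset : onset Damköhler number of rate-induced necrosis for the
        geometry at hand (4 unconfined cylinder, 6 sphere, ~3.4 confined
        cylinder).  Defaults to the shape's unconfined value.
    constant_divide : convention for the velocity-threshold constant, see
        :func:`v0_required`.
    """
    if da_onset is None:
        da_onset = DA_ONSET[d.shape]
    if da_onset <= 0:
        raise ParameterError(f"da_onset must be positive, got {da_onset!r}")
    static_margin = d.Sd * (1.0 - d.Da / da_onset) - 1.0
    micro_margin = d.Sc * (1.0 - d.Da / 4.0) - 1.0
    unsat = d.Da >= 4.0
    static_ok = static_margin >= 0.0
    micro_ok = (not unsat) and micro_margin > 0.0
    if d.Da > da_onset:
        ntype = NecrosisType.rate_induced
    elif static_ok or micro_ok:
        ntype = NecrosisType.none
    else:
        ntype = NecrosisType.supply_induced
    pred = math.sqrt(d.Da) * d.Sc
    return DesignReport(
        static_prevention_ok=static_ok,
        static_margin=static_margin,
        microfluidic_prevention_ok=micro_ok,
        microfluidic_margin=micro_margin,
        microfluidic_unsatisfiable=unsat,
        v0_required=v0_required(d, constant_divide),
        asymmetry_predictor=pred,
        asymmetry_peak=ASYMMETRY_PEAK,
        v0_asymptote_scale=v0_asymptote_scale(d),
        necrosis_type=ntype)


# ---------------------------------------------------------------------------
# Declarative configs: flat "key = value" text with [section] headers.

_PHYS_KEYS = {f.name for f in PhysicalParams.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def read_params_config(path: str) -> tuple[PhysicalParams, Shape]:
    """Read a flat key-value config mapping symbol names to SI values.

    Recognized keys are the :class:`PhysicalParams` field names plus an
    optional ``shape`` (``cylinder``/``sphere``).  Section headers and
    ``#`` comments are ignored.
    """
    values: dict[str, float] = {}
    shape = Shape.cylinder
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ParameterError(f"malformed config line: {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key == "shape":
                shape = Shape(val)
            elif key in _PHYS_KEYS:
                values[key] = float(val)
            else:
                raise ParameterError(f"unknown config key: {key!r}")
    return PhysicalParams(**values), shape
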