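"""Chamber geometry specifications and parameter-sweep fixtures.

Two canonical layouts, both nondimensionalized by the construct radius
(``a = 1``) with the chamber floor (wall or symmetry line) at ``y = 0``:

* ``unconfined`` — the construct is a disc centred on the channel mid-line,
  surrounded by fluid.  The flow is symmetric about the mid-line, so the
  computational domain is the upper half: a rectangle ``[-L, L] x [0, H/2]``
  with the upper half-disc as the construct and ``y = 0`` a symmetry
  boundary.
* ``confined`` — the construct is a disc truncated so that its height above
  the channel floor is 90% of its diameter; it touches the floor along a
  chord.  With the circle centre at ``0.8*a`` above the wall the contact
  points sit at ``x = +/-0.6*a`` (circle–chord geometry), and the fluid
  wedge at each contact point hosts the corner-recirculation (Moffatt) eddies
  that screen part of the interface from convective supply.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence


class GeometryKind(str, Enum):
    unconfined = "unconfined"
    confined = "confined"


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class GeometrySpec:
    """Validated description of one chamber layout (lengths in units of a).

    ``channel_height`` is the full channel height ``2h``; defaults are
    ``3`` (unconfined: half-unit clearance on each side of the disc) and
    ``2.2`` (confined: ``0.4`` clearance above the construct apex, which
    preserves the constriction between the interface and the channel
    ceiling).  ``confined_height_ratio`` is fixed at 0.9 by construction.
    """

    kind: GeometryKind
    a: float = 1.0
    L: float = 10.0
    channel_height: float | None = None
    confined_height_ratio: float = 0.9
    use_symmetry: bool = True

    # -- derived quantities --------------------------------------------

    @property
    def centre_y(self) -> float:
        """Circle-centre height above the floor (0 on the symmetry line)."""
        if self.kind is GeometryKind.unconfined:
            return 0.0
        return 2.0 * self.confined_height_ratio - 1.0

    @property
    def apex_y(self) -> float:
        return self.centre_y + 1.0

    @property
    def contact_half_width(self) -> float:
        """Half-width of the wall-contact chord (0.6 for the 0.9 ratio)."""
        if self.kind is GeometryKind.unconfined:
            return 0.0
        return math.sqrt(1.0 - self.centre_y**2)

    @property
    def domain_height(self) -> float:
        """Height of the meshed domain above y = 0."""
        ch = self.channel_height if self.channel_height is not None else \
            (3.0 if self.kind is GeometryKind.unconfined else 2.2)
        if self.kind is GeometryKind.unconfined and self.use_symmetry:
            return ch / 2.0
        return ch

    @property
    def gap(self) -> float:
        """Clearance between the construct apex and the channel ceiling
        (per side for the unconfined disc)."""
        ch = self.channel_height if self.channel_height is not None else \
            (3.0 if self.kind is GeometryKind.unconfined else 2.2)
        if self.kind is GeometryKind.unconfined:
            return (ch - 2.0) / 2.0
        return ch - self.apex_y

    @property
    def construct_area(self) -> float:
        """Analytic area of the meshed construct region.

        Unconfined with symmetry: the half disc ``pi/2``.  Confined: the
        circular segment above the wall,
        ``pi - (acos(d) - d*sqrt(1-d^2))`` with ``d = centre_y``.
        """
        if self.kind is GeometryKind.unconfined:
            return math.pi / 2.0 if self.use_symmetry else math.pi
        d = self.centre_y
        return math.pi - (math.acos(d) - d * math.sqrt(1.0 - d * d))

    def validated(self) -> "GeometrySpec":
        return build_geometry(self)


def build_geometry(spec: GeometrySpec) -> GeometrySpec:
    """Validate a geometry spec and return it (derived quantities are
    exposed as properties on the returned object)."""
    if spec.a <= 0 or spec.L <= 0:
        raise GeometryError("a and L must be strictly positive")
    if spec.kind is GeometryKind.confined:
        if not 0.5 < spec.confined_height_ratio < 1.0:
            raise GeometryError(
                "confined_height_ratio must lie in (0.5, 1): the construct "
                "must exceed a half disc but remain a truncated disc")
        if spec.use_symmetry:
            spec = replace(spec, use_symmetry=False)
    if spec.gap <= 0:
        raise GeometryError(
            f"construct does not fit the channel: apex-to-ceiling gap "
            f"{spec.gap:.3g} <= 0")
    if spec.L <= 1.0:
        raise GeometryError("inlet distance L must exceed the radius")
    return spec


def unconfined(L: float = 10.0, channel_height: float = 3.0,
               use_symmetry: bool = True) -> GeometrySpec:
    return build_geometry(GeometrySpec(GeometryKind.unconfined, L=L,
                                       channel_height=channel_height,
                                       use_symmetry=use_symmetry))


def confined(L: float = 10.0, channel_height: float = 2.2) -> GeometrySpec:
    return build_geometry(GeometrySpec(GeometryKind.confined, L=L,
                                       channel_height=channel_height))


# ---------------------------------------------------------------------------
# parameter-sweep fixtures

def _content_hash(payload: Mapping) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def make_sweep(name: str, grids: Mapping[str, Sequence[float]],
               paired: bool = False,
               base: Mapping | None = None) -> list[dict]:
    """Expand parameter grids into a stable, content-addressed run list.

    Parameters
    ----------
    grids : mapping from dimensionless-group name (``Da``, ``Rd``, ``Sd``,
        ``Sc``, ``Pe1``) to its grid of values.
    paired : zip the grids position-by-position instead of taking the
        cartesian product (all grids must then share one length).
    base : extra key-value pairs copied into every run config.

    Returns a list of dicts, each with the sweep ``name``, a content-hash
    ``id`` stable under key reordering, and the parameter values.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("sweep grids must be non-empty")
    keys = list(grids)
    if paired:
        lengths = {len(v) for v in grids.values()}
        if len(lengths) != 1:
            raise ValueError(
                f"paired sweep requires equal grid lengths, got {lengths}")
        combos: Iterable[tuple] = zip(*(grids[k] for k in keys))
    else:
        combos = itertools.product(*(grids[k] for k in keys))
    runs = []
    for values in combos:
        cfg = dict(base or {})
        cfg.update({k: float(v) for k, v in zip(keys, values)})
        cfg["sweep"] = name
        cfg["id"] = _content_hash(cfg)
        runs.append(cfg)
    return runs
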