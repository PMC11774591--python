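"""Observables of a concentration field and threshold searches.

The necrotic boundary is the level set ``c = cn`` inside the construct; the
live fraction is the construct-area fraction above the threshold; the
necrotic barycentre locates the core (mass-normalized by default: first
moments divided by the necrotic area, so it is a position; the variant
normalized by the whole construct area is available for completeness).
Level-set geometry is computed exactly per element from the linear (P1)
interpolant, so no contouring grid is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .meshing import Mesh, generate_construct_mesh
from .geometry import GeometrySpec
from .transport import (ConcentrationField, TransportMode, TransportProblem,
                        solve_transport)


@dataclass
class TransportMetrics:
    """Necrosis observables of one concentration field."""

    phi_live: float
    necrotic_area: float
    barycentre: tuple[float, float] | None
    barycentre_printed: tuple[float, float] | None
    boundary_segments: np.ndarray        # (S, 2, 2) level-set segments
    asymmetry: float                     # barycentre x-shift / a (0 if empty)


def _sublevel_clip(p: np.ndarray, c: np.ndarray, t: float
                   ) -> tuple[float, float, float, list[np.ndarray]]:
    """Area and first moments of {c < t} within one triangle, plus the
    level-set segment endpoints.  ``p``: (3,2) vertices, ``c``: (3,) values."""
    below = c < t
    nb = int(below.sum())
    if nb == 0:
        return 0.0, 0.0, 0.0, []
    if nb == 3:
        a = 0.5 * abs((p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1])
                      - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1]))
        cx, cy = p.mean(axis=0)
        return a, a * cx, a * cy, []
    poly: list[np.ndarray] = []
    seg: list[np.ndarray] = []
    for i in range(3):
        j = (i + 1) % 3
        if below[i]:
            poly.append(p[i])
        if below[i] != below[j]:
            w = (t - c[i]) / (c[j] - c[i])
            x = p[i] + w * (p[j] - p[i])
            poly.append(x)
            seg.append(x)
    # shoelace area and centroid of the clipped polygon
    q = np.asarray(poly)
    x, y = q[:, 0], q[:, 1]
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return 0.0, 0.0, 0.0, [np.asarray(seg)] if len(seg) == 2 else []
    mx = ((x + xs) * cross).sum() / 6.0
    my = ((y + ys) * cross).sum() / 6.0
    sgn = np.sign(a)
    return abs(a), sgn * mx, sgn * my, \
        [np.asarray(seg)] if len(seg) == 2 else []


def live_fraction(field: ConcentrationField,
                  cn_star: float | None = None) -> float:
    """Construct-area fraction with ``c > cn`` (sub-element interpolation)."""
    return necrotic_metrics(field, cn_star).phi_live


def necrotic_metrics(field: ConcentrationField,
                     cn_star: float | None = None) -> TransportMetrics:
    """Live fraction, necrotic area/boundary/barycentre of one field."""
    t = field.problem.cn_star if cn_star is None else cn_star
    mesh, c = field.mesh, field.c
    in2 = mesh.tri_region == 2
    tris = mesh.tris[in2]
    area_tot = mesh.tri_areas()[in2].sum()
    # fast path: fully-live / fully-dead triangles vectorized
    cvals = c[tris]
    any_below = (cvals < t).any(axis=1)
    a_n = mx = my = 0.0
    segments: list[np.ndarray] = []
    p_all = mesh.nodes[tris]
    for k in np.nonzero(any_below)[0]:
        a, sx, sy, seg = _sublevel_clip(p_all[k], cvals[k], t)
        a_n += a
        mx += sx
        my += sy
        segments.extend(seg)
    phi = 1.0 - a_n / area_tot
    if a_n <= 0.0:
        return TransportMetrics(phi_live=1.0, necrotic_area=0.0,
                                barycentre=None, barycentre_printed=None,
                                boundary_segments=np.empty((0, 2, 2)),
                                asymmetry=0.0)
    bary = (mx / a_n, my / a_n)
    bary_printed = (mx / area_tot, my / area_tot)
    return TransportMetrics(
        phi_live=float(phi), necrotic_area=float(a_n),
        barycentre=bary, barycentre_printed=bary_printed,
        boundary_segments=(np.asarray(segments)
                           if segments else np.empty((0, 2, 2))),
        asymmetry=float(bary[0]))


def find_da_onset_fem(spec: GeometrySpec,
                      resolution: str | float = "default",
                      cn_star: float = 1e-3, tol: float = 0.01,
                      bracket: tuple[float, float] = (1.0, 10.0),
                      mesh: Mesh | None = None, seed: int = 0) -> float:
    """Smallest Da with necrosis at maximal supply, by bisection on Da.

    Necrosis is detected as ``min c < cn`` over the construct (no level set
    has to exist, avoiding contouring noise near the onset).
    """
    if mesh is None:
        mesh = generate_construct_mesh(spec, resolution, seed=seed)

    def necrotic(Da: float) -> bool:
        f = solve_transport(
            TransportProblem(TransportMode.maximal_supply, Da=Da), mesh)
        return f.min_c2() < cn_star

    lo, hi = bracket
    if necrotic(lo) or not necrotic(hi):
        # widen once before giving up
        lo, hi = lo / 4.0, hi * 4.0
        if necrotic(lo) or not necrotic(hi):
            raise RuntimeError("onset not bracketed in the scan range")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if necrotic(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def gamma_profile(field: ConcentrationField) -> pd.DataFrame:
    """Interface concentration versus angular position.

    Angles are measured from the downstream (+x) direction around the
    construct circle centre; the table is sorted by angle.
    """
    mesh = field.mesh
    idx = mesh.interface_nodes
    cc = np.array([0.0, mesh.spec.centre_y])
    d = mesh.nodes[idx] - cc
    theta = np.arctan2(d[:, 1], d[:, 0])
    df = pd.DataFrame({"theta": theta, "gamma": field.c[idx],
                       "x": mesh.nodes[idx, 0], "y": mesh.nodes[idx, 1]})
    return df.sort_values("theta").reset_index(drop=True)


@dataclass
class ThresholdResult:
    value: float | None
    per_group: dict
    reached: bool
    criterion: str


def _log_crossing(x: np.ndarray, y: np.ndarray, y0: float,
                  increasing: bool, logy: bool = False) -> float | None:
    """Interpolate in log-x the first crossing of y through y0.

    With ``logy`` the ordinate is log-transformed before interpolating —
    the right scale for quantities that decay exponentially across the
    crossing, like the concentration minimum through the necrosis
    threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if logy:
        y = np.log(np.maximum(y, 1e-300))
        y0 = np.log(max(y0, 1e-300))
    above = y >= y0 if increasing else y <= y0
    if not above.any():
        return None
    if above[0]:
        return float(x[0])
    i = int(np.argmax(above))
    x0, x1 = np.log(x[i - 1]), np.log(x[i])
    y0_, y1_ = y[i - 1], y[i]
    w = (y0 - y0_) / (y1_ - y0_) if y1_ != y0_ else 1.0
    return float(np.exp(x0 + w * (x1 - x0)))


def threshold_search(df: pd.DataFrame, criterion: str,
                     cn_star: float = 1e-3, da_onset: float = 4.0,
                     ratio_target: float = 0.9) -> ThresholdResult:
    """Extract a design-rule constant from a sweep result table.

    Supported criteria (the table must carry the referenced columns):

    * ``"static_margin"`` — smallest M such that every run with
      ``Sd*(1 - Da/da_onset) > M`` is fully supplied (``min_c >= cn``);
      per Da the crossing of ``min_c`` through ``cn`` is log-interpolated
      along the margin axis and the maximum over Da is reported.
    * ``"convective_margin"`` — same with ``Sc*(1 - Da/4)``.
    * ``"supply_product"`` — ``Rd*Sd*Sc`` at which ``phi_ratio`` (live
      fraction over its maximal-supply value) crosses ``ratio_target``.
    * ``"asymmetry_peak"`` — location of the maximum barycentre x-shift
      along a Pe1 sweep, reported as ``sqrt(Da)*Sc``.
    """
    per: dict = {}
    if criterion in ("static_margin", "convective_margin"):
        for da, g in df.groupby("Da"):
            if criterion == "static_margin":
                margin = g["Sd"] * (1.0 - da / da_onset)
            else:
                margin = g["Sc"] * (1.0 - da / 4.0)
            pos = margin > 0
            if not pos.any():
                per[da] = None
                continue
            per[da] = _log_crossing(margin[pos].to_numpy(),
                                    g.loc[pos, "min_c"].to_numpy(),
                                    cn_star, increasing=True, logy=True)
        vals = [v for v in per.values() if v is not None]
        ok = len(vals) > 0
        return ThresholdResult(max(vals) if ok else None, per, ok, criterion)
    if criterion == "supply_product":
        for da, g in df.groupby("Da"):
            prod = (g["Rd"] * g["Sd"] * g["Sc"]).to_numpy()
            per[da] = _log_crossing(prod, g["phi_ratio"].to_numpy(),
                                    ratio_target, increasing=True)
        vals = [v for v in per.values() if v is not None]
        ok = len(vals) > 0
        return ThresholdResult(float(np.mean(vals)) if ok else None,
                               per, ok, criterion)
    if criterion == "asymmetry_peak":
        for da, g in df.groupby("Da"):
            g = g.sort_values("Pe1")
            shift = g["asymmetry"].to_numpy()
            if not (shift > 0).any():
                per[da] = None
                continue
            i = int(np.argmax(shift))
            pred = np.sqrt(da) * g["Sc"].to_numpy()
            if 0 < i < len(shift) - 1:
                # log-parabolic refinement of the peak location
                lx = np.log(pred[i - 1:i + 2])
                ly = shift[i - 1:i + 2]
                denom = (ly[0] - 2 * ly[1] + ly[2])
                if denom < 0:
                    dx = 0.5 * (ly[0] - ly[2]) / denom
                    per[da] = float(np.exp(lx[1] + dx * (lx[1] - lx[0])))
                    continue
            per[da] = float(pred[i])
        vals = [v for v in per.values() if v is not None]
        ok = len(vals) > 0
        return ThresholdResult(float(np.mean(vals)) if ok else None,
                               per, ok, criterion)
    raise ValueError(f"unknown criterion {criterion!r}")
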