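"""Graded two-region triangular meshes for the chamber geometries.

The mesher builds unstructured Delaunay triangulations of the chamber
(rectangular channel with the construct as an internal region) or of the
construct alone.  Boundary and interface curves are discretized first with a
graded spacing (geometric refinement towards the confinement contact points);
interior points are then placed level-by-level from a jittered multi-resolution
grid honouring a sizing field, smoothed by a few Lloyd iterations, and
triangulated with ``scipy.spatial.Delaunay``.

Interface conformity is guaranteed rather than hoped for: every interface
segment keeps its diametral circle empty of other points (the Gabriel
condition, under which a segment is necessarily a Delaunay edge), enforced by
protection radii during sampling and by a repair pass afterwards.

Region 1 is the fluid channel, region 2 the construct.  Boundary edge tags:
``inlet``, ``outlet``, ``wall_top``, ``wall_bottom``, ``symmetry``,
``interface``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import GeometrySpec, GeometryKind

#: Resolution levels: multiplicative factor on all characteristic sizes.
RESOLUTIONS = {"coarse": 1.6, "default": 1.0, "fine": 0.5}


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh:
    """A tagged two-region triangular mesh (nondimensional, construct radius 1).

    Attributes
    ----------
    nodes : (N, 2) float array of coordinates
    tris : (M, 3) int connectivity
    tri_region : (M,) int array with values 1 (channel) / 2 (construct)
    edges : tag -> (E, 2) int array of boundary/interface edges
    interface_nodes : node indices ordered along the interface
    spec : the geometry the mesh discretizes
    sizes : characteristic sizes used (interface, far field, corner)
    """

    nodes: np.ndarray
    tris: np.ndarray
    tri_region: np.ndarray
    edges: dict[str, np.ndarray]
    interface_nodes: np.ndarray
    spec: GeometrySpec
    sizes: dict[str, float] = field(default_factory=dict)

    # -- convenience measures -------------------------------------------

    def tri_areas(self) -> np.ndarray:
        p = self.nodes[self.tris]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def region_area(self, region: int) -> float:
        return float(self.tri_areas()[self.tri_region == region].sum())

    def boundary_length(self, tag: str) -> float:
        e = self.edges[tag]
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def min_angle(self) -> float:
        """Smallest interior angle over all triangles, in degrees."""
        p = self.nodes[self.tris]
        angles = []
        for i in range(3):
            u = p[:, (i + 1) % 3] - p[:, i]
            v = p[:, (i + 2) % 3] - p[:, i]
            cosang = (u * v).sum(1) / (np.linalg.norm(u, axis=1)
                                       * np.linalg.norm(v, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))

    def element_sizes(self) -> np.ndarray:
        """Longest edge per triangle (SUPG/PSPG length scale)."""
        p = self.nodes[self.tris]
        e = np.stack([np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
                      np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
                      np.linalg.norm(p[:, 0] - p[:, 2], axis=1)])
        return e.max(axis=0)


# ---------------------------------------------------------------------------
# curve discretization

def _march_curve(points: np.ndarray, h_of: Callable[[np.ndarray], float],
                 ) -> np.ndarray:
    """Resample a dense polyline with locally varying target spacing.

    Marches along arc length taking steps of the local target size, then
    rescales the steps so the last point lands exactly on the curve end.
    """
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]

    def at(t: float) -> np.ndarray:
        i = np.searchsorted(s, t, side="right") - 1
        i = min(max(i, 0), len(seg) - 1)
        w = (t - s[i]) / seg[i] if seg[i] > 0 else 0.0
        return points[i] * (1 - w) + points[i + 1] * w

    ts = [0.0]
    while ts[-1] < total:
        step = max(h_of(at(ts[-1])), 1e-6)
        ts.append(ts[-1] + step)
    ts = np.asarray(ts)
    if len(ts) < 3:
        ts = np.array([0.0, 0.5, 1.0]) * total
    else:
        ts = ts * (total / ts[-1])
    return np.array([at(t) for t in ts])


def _arc(center: np.ndarray, radius: float, th0: float, th1: float,
         n: int = 2000) -> np.ndarray:
    th = np.linspace(th0, th1, n)
    return center + radius * np.stack([np.cos(th), np.sin(th)], axis=1)


def _line(p0, p1, n: int = 400) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(p0) * (1 - t) + np.asarray(p1) * t


# ---------------------------------------------------------------------------
# sizing fields

@dataclass
class _Sizing:
    h_int: float
    h_far: float
    h_corner: float
    grade: float
    corners: np.ndarray          # refinement centres (contact / junction points)
    circle_center: np.ndarray
    circle_radius: float
    gap_cap: float = np.inf      # resolves the construct-ceiling constriction

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        d_int = np.abs(np.linalg.norm(xy - self.circle_center, axis=1)
                       - self.circle_radius)
        h = np.minimum(self.h_far, self.h_int + self.grade * d_int)
        if np.isfinite(self.gap_cap):
            # keep several elements across the gap everywhere near the
            # interface, where the constriction accelerates the flow
            h = np.minimum(h, self.gap_cap + 0.5 * np.maximum(
                0.0, d_int - 5.0 * self.gap_cap))
        if len(self.corners):
            d_c = np.min(np.linalg.norm(
                xy[:, None, :] - self.corners[None, :, :], axis=2), axis=1)
            h = np.minimum(h, self.h_corner + 0.3 * d_c)
        return np.maximum(h, 0.25 * self.h_corner)

    def scalar(self, xy) -> float:
        return float(self(np.asarray(xy, dtype=float).reshape(1, 2))[0])


# ---------------------------------------------------------------------------
# interior sampling, smoothing, triangulation

def _interior_points(bbox: tuple[float, float, float, float],
                     sizing: _Sizing,
                     inside: Callable[[np.ndarray], np.ndarray],
                     fixed: np.ndarray, fixed_h: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Jittered multi-level grid sampling honouring the sizing field."""
    x0, x1, y0, y1 = bbox
    n_levels = max(1, int(math.ceil(math.log2(sizing.h_far / sizing.h_corner))) + 1)
    tree_fixed = cKDTree(fixed)
    accepted: list[np.ndarray] = []
    for lev in range(n_levels):          # fine -> coarse
        p = sizing.h_far / 2 ** (n_levels - 1 - lev)
        if p < 0.5 * sizing.h_int and len(sizing.corners):
            # sub-interface sizes only occur in the corner-refinement discs:
            # restrict the candidate grid to boxes around them
            half = 5.0 * p / 0.3  # h_corner + 0.3*d < 1.44*p  =>  d < ~5p
            boxes = [(max(x0, cx - half), min(x1, cx + half),
                      max(y0, cy - half), min(y1, cy + half))
                     for cx, cy in sizing.corners]
        else:
            boxes = [(x0, x1, y0, y1)]
        cand_list = []
        for bx0, bx1, by0, by1 in boxes:
            nx = max(2, int((bx1 - bx0) / p))
            ny = max(2, int((by1 - by0) / p))
            gx, gy = np.meshgrid(np.linspace(bx0 + p / 2, bx1 - p / 2, nx),
                                 np.linspace(by0 + p / 2, by1 - p / 2, ny))
            cand_list.append(np.stack([gx.ravel(), gy.ravel()], axis=1))
        cand = np.concatenate(cand_list)
        cand = cand + rng.uniform(-0.22 * p, 0.22 * p, cand.shape)
        h_c = sizing(cand)
        lev_sel = (h_c >= 0.72 * p) & (h_c < 1.44 * p)
        if lev == n_levels - 1:
            lev_sel = h_c >= 0.72 * p
        cand, h_c = cand[lev_sel], h_c[lev_sel]
        if not len(cand):
            continue
        cand_in = inside(cand)
        cand, h_c = cand[cand_in], h_c[cand_in]
        if not len(cand):
            continue
        # protection around fixed boundary/interface points
        d_f, idx = tree_fixed.query(cand)
        keep = d_f >= 0.78 * np.maximum(h_c * 0.72, fixed_h[idx])
        cand, h_c = cand[keep], h_c[keep]
        if accepted:
            tree_acc = cKDTree(np.concatenate(accepted))
            d_a, _ = tree_acc.query(cand)
            keep = d_a >= 0.60 * h_c
            cand, h_c = cand[keep], h_c[keep]
        if len(cand):
            accepted.append(cand)
    if not accepted:
        return np.empty((0, 2))
    return np.concatenate(accepted)


def _relax(points: np.ndarray, n_fixed: int, sizing: _Sizing,
           project: Callable[[np.ndarray, np.ndarray], np.ndarray],
           iterations: int = 60, step: float = 0.2,
           fscale: float = 1.2) -> np.ndarray:
    """Truss-style relaxation of the movable points (distmesh scheme).

    Edges act as compressed springs with rest length proportional to the
    local sizing; repulsive-only forces spread points until spacing matches
    the sizing field.  The triangulation is refreshed whenever points have
    moved appreciably.  ``project`` pushes escaped movable points back into
    the domain interior (given the points and their local target sizes).
    """
    pts = points.copy()
    tri_pts = None
    edges = None
    for _ in range(iterations):
        if tri_pts is None or np.max(
                np.linalg.norm(pts - tri_pts, axis=1) / sizing(pts)) > 0.12:
            simp = Delaunay(pts).simplices
            e = np.concatenate([simp[:, [0, 1]], simp[:, [1, 2]],
                                simp[:, [2, 0]]])
            e.sort(axis=1)
            edges = np.unique(e, axis=0)
            tri_pts = pts.copy()
        vec = pts[edges[:, 1]] - pts[edges[:, 0]]
        ln = np.linalg.norm(vec, axis=1)
        hmid = sizing(0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]]))
        l0 = hmid * fscale * math.sqrt((ln**2).sum() / (hmid**2).sum())
        force = np.maximum(l0 - ln, 0.0) / np.maximum(ln, 1e-12)
        fvec = force[:, None] * vec
        disp = np.zeros_like(pts)
        np.add.at(disp, edges[:, 0], -fvec)
        np.add.at(disp, edges[:, 1], fvec)
        disp[:n_fixed] = 0.0
        pts = pts + step * disp
        pts[n_fixed:] = project(pts[n_fixed:], sizing(pts[n_fixed:]))
    return pts



def _lloyd_polish(pts: np.ndarray, n_fixed: int, sizing: _Sizing,
                  project, iterations: int = 6) -> np.ndarray:
    """Centroidal smoothing pass after relaxation (movable points only)."""
    pts = pts.copy()
    n = len(pts)
    for _ in range(iterations):
        simp = Delaunay(pts).simplices
        p = pts[simp]
        areas = 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        cent = p.mean(axis=1)
        acc = np.zeros((n, 2))
        wsum = np.zeros(n)
        for k in range(3):
            np.add.at(acc, simp[:, k], cent * areas[:, None])
            np.add.at(wsum, simp[:, k], areas)
        target = acc / np.maximum(wsum, 1e-300)[:, None]
        pts[n_fixed:] = project(target[n_fixed:], sizing(pts[n_fixed:]))
    return pts


def _edge_set(tris: np.ndarray) -> set[tuple[int, int]]:
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e.sort(axis=1)
    return {tuple(row) for row in e}


def _triangulate_conforming(pts: np.ndarray, n_fixed: int,
                            chains: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Delaunay triangulation that must contain every chained segment.

    Interior points sitting inside the diametral circle of a missing segment
    are removed and the triangulation repeated (at most five passes).
    """
    for _ in range(5):
        tri = Delaunay(pts)
        edges = _edge_set(tri.simplices)
        missing = [(a, b) for chain in chains
                   for a, b in zip(chain[:-1], chain[1:])
                   if (min(a, b), max(a, b)) not in edges]
        if not missing:
            return pts, tri.simplices
        bad: set[int] = set()
        for a, b in missing:
            mid = 0.5 * (pts[a] + pts[b])
            rad = 0.5 * np.linalg.norm(pts[a] - pts[b])
            d = np.linalg.norm(pts[n_fixed:] - mid, axis=1)
            bad.update((np.nonzero(d < rad * 1.05)[0] + n_fixed).tolist())
        if not bad:
            raise MeshingError(
                f"interface segments {missing[:3]} not recoverable; "
                "refine the interface spacing")
        keep = np.ones(len(pts), dtype=bool)
        keep[list(bad)] = False
        pts = pts[keep]
    raise MeshingError("conformity repair did not converge")


# ---------------------------------------------------------------------------
# public mesh builders


def _wedge_seeds(corner: np.ndarray, th_lo: float, th_hi: float,
                 h0: float, r_max: float, ratio: float = 1.6) -> np.ndarray:
    """Seed points on interior rays of a corner wedge at geometric radii.

    Narrow wedges (< ~100 deg) get their bisector, wide ones two rays; the
    radii grow geometrically from the corner scale ``h0`` out to ``r_max``
    where the background sizing takes over.  Seeding the wedges explicitly
    keeps the Moffatt-corner refinement bands well-shaped, which random
    sampling plus relaxation cannot guarantee in a sub-40-degree wedge.
    """
    span = th_hi - th_lo
    if span < 1.05:
        # narrow (Moffatt) wedge: the graded wall and arc nodes share radii,
        # so single triangles spanning the wedge beat any interior ray
        return np.empty((0, 2))
    fracs = [0.5] if span < 1.8 else [1.0 / 3.0, 2.0 / 3.0]
    pts = []
    r = 2.0 * h0
    while r < r_max:
        for f in fracs:
            th = th_lo + f * span
            pts.append(corner + r * np.array([math.cos(th), math.sin(th)]))
        r *= ratio
    return np.array(pts) if pts else np.empty((0, 2))


def _junction_seeds(spec: GeometrySpec, h_corner: float, h_int: float,
                    fluid_side: bool) -> np.ndarray:
    """Wedge seeds at both interface-wall junctions of a geometry."""
    if spec.kind is GeometryKind.unconfined:
        xw, th_t = 1.0, math.pi / 2.0      # arc tangent is vertical
    else:
        xw = spec.contact_half_width
        th_t = math.atan2(xw, spec.centre_y)  # tangent angle at the contact
    r_max = 0.8 * (h_int - h_corner) / 0.3
    chunks = []
    for s in (1.0, -1.0):
        corner = np.array([s * xw, 0.0])
        if s > 0:
            wedges = ([(0.0, th_t)] if fluid_side else []) + [(th_t, math.pi)]
        else:
            wedges = ([(math.pi - th_t, math.pi)] if fluid_side else []) \
                + [(0.0, math.pi - th_t)]
        for lo, hi in wedges:
            chunks.append(_wedge_seeds(corner, lo, hi, h_corner, r_max))
    out = [c for c in chunks if len(c)]
    return np.concatenate(out) if out else np.empty((0, 2))


def _corner_size(h_int: float, n_bands: int = 4, ratio: float = 0.5) -> float:
    return h_int * ratio ** n_bands


def generate_mesh(spec: GeometrySpec, resolution: str | float = "default",
                  seed: int = 0) -> Mesh:
    """Mesh the full chamber (channel + construct) for a geometry spec.

    ``resolution`` is a named level (``coarse``/``default``/``fine``) or a
    direct multiplicative factor on the characteristic sizes.
    """
    spec = spec.validated()
    fac = RESOLUTIONS.get(resolution, None) if isinstance(resolution, str) \
        else float(resolution)
    if fac is None:
        raise MeshingError(f"unknown resolution {resolution!r}")
    h_int = 0.08 * fac
    h_far = 0.30 * fac
    # Moffatt-eddy resolution demands geometric corner bands in confinement;
    # the unconfined interface-symmetry junction only needs mild refinement.
    h_corner = _corner_size(h_int) if spec.kind is GeometryKind.confined \
        else 0.5 * h_int
    L, H = spec.L, spec.domain_height
    cc = np.array([0.0, spec.centre_y])
    rng = np.random.default_rng(seed)

    # -- boundary and interface discretization
    if spec.kind is GeometryKind.unconfined:
        th0, th1 = 0.0, math.pi          # upper semicircle
        junctions = np.array([[1.0, 0.0], [-1.0, 0.0]])
    else:
        th_c = math.atan2(-spec.centre_y, spec.contact_half_width)
        th0, th1 = th_c, math.pi - th_c  # arc above the wall
        junctions = np.array([[spec.contact_half_width, 0.0],
                              [-spec.contact_half_width, 0.0]])
    gap_cap = max(h_int, spec.gap / 5.0)
    sizing = _Sizing(h_int=h_int, h_far=h_far, h_corner=h_corner,
                     grade=0.4, corners=junctions,
                     circle_center=cc, circle_radius=1.0, gap_cap=gap_cap)
    h_b = sizing.scalar
    gamma_pts = _march_curve(_arc(cc, 1.0, th0, th1), h_b)

    # split the floor at the interface junctions so they are exact nodes
    xw = 1.0 if spec.kind is GeometryKind.unconfined else spec.contact_half_width
    bottom = np.concatenate([
        _march_curve(_line([-L, 0.0], [-xw, 0.0], 2000), h_b),
        _march_curve(_line([-xw, 0.0], [xw, 0.0], 2000), h_b),
        _march_curve(_line([xw, 0.0], [L, 0.0], 2000), h_b)])
    top = _march_curve(_line([-L, H], [L, H]), h_b)
    inlet = _march_curve(_line([-L, 0.0], [-L, H]), h_b)
    outlet = _march_curve(_line([L, 0.0], [L, H]), h_b)

    seeds = _junction_seeds(spec, h_corner, h_int, fluid_side=True)
    fixed = np.concatenate([gamma_pts, bottom, top, inlet, outlet, seeds])

    def project(p, h):
        m = 0.35 * h
        p[:, 0] = np.clip(p[:, 0], -L + m, L - m)
        p[:, 1] = np.clip(p[:, 1], m, H - m)
        return p

    return _assemble(spec, fixed, gamma_pts, sizing, rng,
                     bbox=(-L, L, 0.0, H),
                     inside=lambda p: ((p[:, 0] > -L) & (p[:, 0] < L)
                                       & (p[:, 1] > 0) & (p[:, 1] < H)),
                     sizes={"interface": h_int, "far": h_far,
                            "corner": h_corner},
                     project=project)


def generate_construct_mesh(spec: GeometrySpec,
                            resolution: str | float = "default",
                            seed: int = 0) -> Mesh:
    """Mesh the construct alone (for maximal-supply solves).

    Unconfined: the upper half-disc with the diameter as symmetry boundary
    (equivalent to the full disc by symmetry).  Confined: the truncated disc
    with the contact chord as a no-flux wall.
    """
    spec = spec.validated()
    fac = RESOLUTIONS.get(resolution, None) if isinstance(resolution, str) \
        else float(resolution)
    if fac is None:
        raise MeshingError(f"unknown resolution {resolution!r}")
    h_int = 0.05 * fac
    h_far = 0.09 * fac
    cc = np.array([0.0, spec.centre_y])
    if spec.kind is GeometryKind.unconfined:
        th0, th1 = 0.0, math.pi
        xw = 1.0
        h_corner = h_int * 0.5
    else:
        th_c = math.atan2(-spec.centre_y, spec.contact_half_width)
        th0, th1 = th_c, math.pi - th_c
        xw = spec.contact_half_width
        h_corner = _corner_size(h_int, n_bands=3)
    junctions = np.array([[xw, 0.0], [-xw, 0.0]])
    sizing = _Sizing(h_int=h_int, h_far=h_far, h_corner=h_corner,
                     grade=0.4, corners=junctions,
                     circle_center=cc, circle_radius=1.0)
    gamma_pts = _march_curve(_arc(cc, 1.0, th0, th1), sizing.scalar)
    chord = _march_curve(_line([-xw, 0.0], [xw, 0.0], 2000), sizing.scalar)
    seeds = _junction_seeds(spec, h_corner, h_int, fluid_side=False)
    fixed = np.concatenate([gamma_pts, chord, seeds])
    rng = np.random.default_rng(seed)
    eps = 1e-12

    def project(p, h):
        m = 0.35 * h
        p[:, 1] = np.maximum(p[:, 1], m)
        d = p - cc
        r = np.linalg.norm(d, axis=1)
        over = r > 1.0 - m
        p[over] = cc + d[over] * ((1.0 - m[over]) / r[over])[:, None]
        return p

    return _assemble(
        spec, fixed, gamma_pts, sizing, rng,
        bbox=(-1.0, 1.0, 0.0, spec.apex_y),
        inside=lambda p: ((np.linalg.norm(p - cc, axis=1) < 1.0 - eps)
                          & (p[:, 1] > 0)),
        sizes={"interface": h_int, "far": h_far, "corner": h_corner},
        project=project, construct_only=True)


def _assemble(spec, fixed, gamma_pts, sizing, rng, bbox, inside, sizes,
              project, construct_only: bool = False) -> Mesh:
    fixed = _dedupe(fixed)
    fixed_h = sizing(fixed)
    tree_fixed = cKDTree(fixed)
    interior = _interior_points(bbox, sizing, inside, fixed,
                                0.62 * fixed_h, rng)
    # structured first layer along the interface normals: movable points that
    # give the relaxation the right topology next to the pinned arc nodes
    gam = np.asarray(gamma_pts)
    radial = gam - sizing.circle_center
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    h_g = sizing(gam)[:, None]
    layers = [gam[1:-1] - 0.8 * h_g[1:-1] * radial[1:-1]]
    if not construct_only:
        layers.append(gam[1:-1] + 0.8 * h_g[1:-1] * radial[1:-1])
    offsets = np.concatenate(layers)
    offsets = offsets[inside(offsets)]
    interior = np.concatenate([offsets, interior]) if len(interior) \
        else offsets
    pts = np.concatenate([fixed, interior]) if len(interior) else fixed
    pts = _relax(pts, len(fixed), sizing, project)
    pts = _lloyd_polish(pts, len(fixed), sizing, project)
    # indices of the interface chain in the (deduplicated) fixed block
    _, gamma_idx = tree_fixed.query(gamma_pts)
    chains = [gamma_idx]
    pts, tris = _triangulate_conforming(pts, len(fixed), chains)
    tris = _drop_outside(pts, tris, spec, construct_only)
    mesh = _tag(spec, pts, tris, gamma_idx, construct_only)
    mesh.sizes = sizes
    return mesh


def _dedupe(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol)
    drop = {max(a, b) for a, b in pairs}
    keep = np.ones(len(points), dtype=bool)
    keep[list(drop)] = False
    return points[keep]


def _drop_outside(pts, tris, spec, construct_only) -> np.ndarray:
    """Remove slivers outside the meshed domain (construct-only meshes have a
    convex-hull boundary that can bridge the arc chord; the full rectangle is
    convex so nothing is dropped there)."""
    if not construct_only:
        return tris
    cc = np.array([0.0, spec.centre_y])
    cent = pts[tris].mean(axis=1)
    inside = (np.linalg.norm(cent - cc, axis=1) < 1.0) & (cent[:, 1] > 0)
    return tris[inside]


def _tag(spec, pts, tris, gamma_idx, construct_only) -> Mesh:
    cc = np.array([0.0, spec.centre_y])
    cent = pts[tris].mean(axis=1)
    in_circle = np.linalg.norm(cent - cc, axis=1) < 1.0
    tri_region = np.where(in_circle & (cent[:, 1] > 0), 2, 1)
    if construct_only:
        tri_region[:] = 2

    # boundary edges: appear in exactly one triangle
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e_sorted = np.sort(e, axis=1)
    uniq, counts = np.unique(e_sorted, axis=0, return_counts=True)
    bnd = uniq[counts == 1]

    L = spec.L
    H = spec.domain_height if not construct_only else None
    tol = 1e-9
    mids = 0.5 * (pts[bnd[:, 0]] + pts[bnd[:, 1]])
    edges: dict[str, np.ndarray] = {}
    if construct_only:
        on_bottom = mids[:, 1] < tol
        bottom_tag = ("symmetry" if spec.kind is GeometryKind.unconfined
                      else "wall_bottom")
        edges[bottom_tag] = bnd[on_bottom]
        edges["interface"] = bnd[~on_bottom]
    else:
        sel_in = np.abs(mids[:, 0] + L) < tol
        sel_out = np.abs(mids[:, 0] - L) < tol
        sel_top = np.abs(mids[:, 1] - H) < tol
        sel_bot = (mids[:, 1] < tol) & ~sel_in & ~sel_out
        edges["inlet"] = bnd[sel_in]
        edges["outlet"] = bnd[sel_out]
        edges["wall_top"] = bnd[sel_top]
        bottom_tag = ("symmetry" if spec.kind is GeometryKind.unconfined
                      else "wall_bottom")
        edges[bottom_tag] = bnd[sel_bot]
        other = ~(sel_in | sel_out | sel_top | sel_bot)
        if other.any():
            raise MeshingError("untagged boundary edges found")
        # the interface is interior: collect the chained segments directly
        edges["interface"] = np.stack([gamma_idx[:-1], gamma_idx[1:]], axis=1)
    return Mesh(nodes=pts, tris=tris, tri_region=tri_region, edges=edges,
                interface_nodes=np.asarray(gamma_idx), spec=spec)


def extract_region(mesh: Mesh, region: int) -> tuple[Mesh, np.ndarray]:
    """Submesh of one region; returns it with the old->new node index map."""
    sel = mesh.tri_region == region
    tris = mesh.tris[sel]
    used = np.unique(tris)
    remap = -np.ones(len(mesh.nodes), dtype=int)
    remap[used] = np.arange(len(used))
    new_edges = {}
    for tag, e in mesh.edges.items():
        if len(e) == 0:
            continue
        keep = np.isin(e, used).all(axis=1)
        if keep.any():
            new_edges[tag] = remap[e[keep]]
    iface = mesh.interface_nodes[np.isin(mesh.interface_nodes, used)]
    sub = Mesh(nodes=mesh.nodes[used], tris=remap[tris],
               tri_region=np.full(sel.sum(), region),
               edges=new_edges, interface_nodes=remap[iface],
               spec=mesh.spec, sizes=dict(mesh.sizes))
    return sub, remap
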