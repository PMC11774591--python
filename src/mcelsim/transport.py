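"""Steady solute transport: advection–diffusion in the channel coupled to
Michaelis–Menten diffusion–reaction in the construct.

Nondimensionalization: lengths by the construct radius ``a``, concentration
by the inlet value ``c0``.  The construct equation is then

    0 = lap(c) - Da * c / (c + K*)          in the construct,

and the channel equation

    0 = (Rd * L/a) * lap(c) - Rd * Pe1 * v . grad(c)    in the channel,

with ``v`` the flow field scaled by the peak inlet velocity.  The
diffusivity contrast ``D1/D2 = Rd * L/a`` also enforces the interface flux
continuity naturally in the single-field weak form.  Convection inside the
construct is omitted (transpiration Péclet number below 0.1).

Three supply modes:

* ``maximal_supply`` — construct only, interface held at the source value
  (``c* = 1`` on the interface); the theoretical best case.
* ``static`` — no flow; diffusion from the reservoirs at inlet and outlet
  (``c* = 1`` there).
* ``microfluidic`` — static plus convection by a solved flow field, with
  streamline (SUPG) stabilization in the channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from . import fem
from .meshing import Mesh, extract_region
from .params import Shape


class TransportMode(str, Enum):
    maximal_supply = "maximal_supply"
    static = "static"
    microfluidic = "microfluidic"


class SolverError(RuntimeError):
    pass


@dataclass
class TransportProblem:
    """One transport solve: supply mode plus the dimensionless groups.

    ``K_half_star`` defaults to 1e-4: an order of magnitude below the
    necrosis threshold ``cn* = 1e-3``, so the Michaelis–Menten softening
    cannot masquerade as survival right at the threshold.  (With
    ``K* >= cn*`` the measured necrosis onset drifts far above its
    sharp-kinetics value: the concentration floor scales with ``K*``.)  ``flow`` (a :class:`mcelsim.flow.FlowField`) is required
    in microfluidic mode and ignored otherwise.
    """

    mode: TransportMode
    Da: float
    Pe1: float = 0.0
    Rd: float = 1.0
    K_half_star: float = 1e-4
    cn_star: float = 1e-3
    flow: object | None = None

    def __post_init__(self) -> None:
        self.mode = TransportMode(self.mode)
        if self.Da < 0:
            raise ValueError("Da must be non-negative")
        if self.mode is TransportMode.microfluidic and self.flow is None:
            raise ValueError("microfluidic mode requires a FlowField")

    @property
    def Sd(self) -> float:
        return 2.0 * self.Rd / self.Da if self.Da > 0 else np.inf

    @property
    def Sc(self) -> float:
        return self.Sd * self.Pe1


@dataclass
class ConcentrationField:
    """Nodal solute concentration (inlet scale) on a mesh."""

    mesh: Mesh
    c: np.ndarray
    problem: TransportProblem
    converged: bool
    newton_iters: int
    residual: float

    @property
    def omega2_mask(self) -> np.ndarray:
        return fem.node_mask_of_region(self.mesh.tris, self.mesh.tri_region,
                                       2, len(self.mesh.nodes))

    def min_c2(self) -> float:
        return float(self.c[self.omega2_mask].min())


def _mm_terms(c: np.ndarray, tris: np.ndarray, area: np.ndarray,
              Da: float, K: float, n: int
              ) -> tuple[np.ndarray, sp.csr_matrix]:
    """Michaelis–Menten sink: residual vector and Jacobian block.

    The nonlinearity is evaluated with ``max(c, 0)`` so Newton stays
    well-defined if an iterate undershoots, and with lumped (nodal)
    quadrature: together with the Delaunay Laplacian this keeps the discrete
    operator an M-matrix, so the solution honours the maximum principle.
    """
    w = np.zeros(n)
    np.add.at(w, tris.ravel(), np.repeat(Da * area / 3.0, 3))
    cp = np.maximum(c, 0.0)
    g = cp / (cp + K)
    gp = np.where(c > 0.0, K / (cp + K) ** 2, 0.0)
    vec = w * g
    jac = sp.diags(w * gp).tocsr()
    return vec, jac


def solve_transport(problem: TransportProblem, mesh: Mesh,
                    newton_tol: float = 1e-10, max_iter: int = 60
                    ) -> ConcentrationField:
    """Newton-solve the steady transport problem on a mesh.

    In maximal-supply mode a full chamber mesh is reduced to its construct
    region automatically.  Newton uses backtracking damping; if it fails, a
    ramp over Da (simple continuation) is attempted before giving up and
    returning a non-converged field.
    """
    if problem.mode is TransportMode.maximal_supply \
            and (mesh.tri_region == 1).any():
        mesh, _ = extract_region(mesh, 2)

    nodes, tris = mesh.nodes, mesh.tris
    n = len(nodes)
    area, _ = fem.tri_geometry(nodes, tris)
    in2 = mesh.tri_region == 2
    tris2, area2 = tris[in2], area[in2]

    L_star = mesh.spec.L
    diff = np.where(in2, 1.0, problem.Rd * L_star)
    A = fem.stiffness(nodes, tris, diff)

    if problem.mode is TransportMode.microfluidic:
        vel = problem.flow.velocity
        # convect only in the channel; the construct is diffusion-reaction
        coeff = np.where(in2, 0.0, problem.Rd * problem.Pe1)
        A = A + fem.advection(nodes, tris, vel, coeff)
        h = mesh.element_sizes()
        A = A + fem.supg(nodes, tris, vel, diff, h,
                         np.where(in2, 0.0, problem.Rd * problem.Pe1))

    if problem.mode is TransportMode.maximal_supply:
        dir_nodes = np.unique(mesh.edges["interface"])
    else:
        dir_nodes = np.unique(np.concatenate(
            [mesh.edges["inlet"].ravel(), mesh.edges["outlet"].ravel()]))
    dir_vals = np.ones(len(dir_nodes))

    free = np.ones(n, dtype=bool)
    free[dir_nodes] = False

    def residual(c):
        vec, _ = _mm_terms(c, tris2, area2, problem.Da,
                           problem.K_half_star, n)
        return (A @ c) + vec

    def newton(c, Da_now, tol):
        for it in range(max_iter):
            vec, jac = _mm_terms(c, tris2, area2, Da_now,
                                 problem.K_half_star, n)
            F = (A @ c) + vec
            rnorm = np.linalg.norm(F[free], np.inf)
            if rnorm < tol:
                return c, True, it, rnorm
            J = A + jac
            Jr, Fr = fem.apply_dirichlet(J, -F, dir_nodes,
                                         np.zeros(len(dir_nodes)))
            dc = spsolve(Jr.tocsc(), Fr)
            lam = 1.0
            for _ in range(10):
                c_try = c + lam * dc
                F_try = _mm_terms(c_try, tris2, area2, Da_now,
                                  problem.K_half_star, n)[0] + A @ c_try
                if np.linalg.norm(F_try[free], np.inf) < rnorm * (1 - 1e-4 * lam):
                    break
                lam *= 0.5
            c = c + lam * dc
        vec, _ = _mm_terms(c, tris2, area2, Da_now, problem.K_half_star, n)
        F = (A @ c) + vec
        return c, False, max_iter, np.linalg.norm(F[free], np.inf)

    c0 = np.ones(n)
    c0[dir_nodes] = dir_vals
    c, ok, iters, rnorm = newton(c0, problem.Da, newton_tol)
    if not ok and problem.Da > 0:
        # continuation in the half-rate constant: solve with a soft
        # nonlinearity first and sharpen towards the target K
        K_target = problem.K_half_star
        ladder = [1.0, 3e-1, 1e-1, 3e-2, 1e-2, 3e-3, 1e-3, 3e-4, 1e-4,
                  3e-5, 1e-5]
        ladder = [k for k in ladder if k > K_target] + [K_target]
        c = np.ones(n)
        c[dir_nodes] = dir_vals
        total = 0
        orig_K = problem.K_half_star
        try:
            for K_now in ladder:
                problem.K_half_star = K_now
                c, ok, it, rnorm = newton(c, problem.Da, newton_tol)
                total += it
                if not ok:
                    break
        finally:
            problem.K_half_star = orig_K
        iters = total
    return ConcentrationField(mesh=mesh, c=c, problem=problem,
                              converged=bool(ok), newton_iters=iters,
                              residual=float(rnorm))


def flux_audit(field: ConcentrationField) -> dict[str, float]:
    """Conservation audit: consumption in the construct vs. interface influx.

    ``influx_consistent`` is the variationally consistent boundary flux (the
    discrete reaction at the interface/Dirichlet nodes); ``influx_gradient``
    re-integrates ``D grad(c) . n`` along the interface from the
    construct-side element gradients — an independent, lower-order measure.
    """
    mesh, c, pb = field.mesh, field.c, field.problem
    nodes, tris = mesh.nodes, mesh.tris
    n = len(nodes)
    area, grads = fem.tri_geometry(nodes, tris)
    in2 = mesh.tri_region == 2
    vec, _ = _mm_terms(c, tris[in2], area[in2], pb.Da, pb.K_half_star, n)
    consumption = float(vec.sum())

    # consistent flux: residual of the construct-only operator at the
    # interface nodes
    A2 = fem.stiffness(nodes, tris[in2], 1.0)
    r = A2 @ c + vec
    iface = np.unique(mesh.edges["interface"])
    influx_consistent = float(r[iface].sum())

    # direct line integral of the normal gradient, construct side
    grad_c = np.einsum("eid,ei->ed", grads[in2], c[tris[in2]])
    cent2 = nodes[tris[in2]].mean(axis=1)
    cc = np.array([0.0, mesh.spec.centre_y])
    tree_src = cent2
    influx_gradient = 0.0
    for a_idx, b_idx in mesh.edges["interface"]:
        pa, pb_ = nodes[a_idx], nodes[b_idx]
        mid = 0.5 * (pa + pb_)
        ln = np.linalg.norm(pb_ - pa)
        nrm = mid - cc
        nrm = nrm / np.linalg.norm(nrm)          # outward from the construct
        k = np.argmin(np.linalg.norm(tree_src - mid, axis=1))
        influx_gradient += float(grad_c[k] @ nrm) * ln
    return {"consumption": consumption,
            "influx_consistent": influx_consistent,
            "influx_gradient": influx_gradient}


def radial_oracle(Da: float, K_half_star: float, gamma_star: float = 1.0,
                  shape: Shape | str = Shape.cylinder,
                  n_points: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Radially symmetric Michaelis-Menten profile on a fine 1D grid.

    Independent ground truth for the 2D FEM in radial symmetry: solves
    ``(1/r^(m-1)) (r^(m-1) c')' = Da c/(c+K)`` with ``c'(0)=0`` and
    ``c(1)=gamma_star`` by a conservative finite-volume discretization on a
    nonuniform grid strongly refined around the sharp-cutoff radius (where
    the Michaelis-Menten layer of width ``sqrt(K/Da)`` lives), Newton with
    a continuation ladder in K.  Returns ``(r, c)`` resampled on a uniform
    grid of ``n_points``.
    """
    shape = Shape(shape)
    if not 0.0 < gamma_star <= 1.0:
        raise ValueError("gamma_star must lie in (0, 1]")
    if Da < 0:
        raise ValueError("Da must be non-negative")
    m = 2 if shape is Shape.cylinder else 3
    r_out = np.linspace(0.0, 1.0, n_points)
    if Da == 0:
        return r_out, np.full_like(r_out, gamma_star)

    K = K_half_star
    from .radial1d import rn_maximal
    rn = rn_maximal(Da / gamma_star, shape).rn_star

    # grid: uniform backbone plus a dense band across the cutoff layer
    r = np.linspace(0.0, 1.0, 4 * n_points)
    if rn > 0:
        ell = max(np.sqrt(K / max(Da, 1e-12)), 1e-7)
        band = rn + np.linspace(-80, 80, 8000) * (ell / 4.0)
        r = np.unique(np.concatenate([r, band[(band > 0) & (band < 1)]]))
    n = len(r)
    h = np.diff(r)
    r_mid = 0.5 * (r[:-1] + r[1:])
    w_face = r_mid ** (m - 1) / h                  # conductances
    # control volumes (trapezoid of r^(m-1))
    vol = np.zeros(n)
    vol[:-1] += 0.5 * h * r[:-1] ** (m - 1)
    vol[1:] += 0.5 * h * r[1:] ** (m - 1)

    import scipy.sparse as _sp
    from scipy.sparse.linalg import spsolve as _spsolve
    main = np.zeros(n)
    main[:-1] += w_face
    main[1:] += w_face
    A = _sp.diags([main, -w_face, -w_face], [0, -1, 1], format="csr")

    def solve_at(K_now, c):
        for _ in range(80):
            cpos = np.maximum(c, 0.0)
            g = cpos / (cpos + K_now)
            gp = np.where(c > 0, K_now / (cpos + K_now) ** 2, 0.0)
            F = A @ c + Da * vol * g
            F[-1] = c[-1] - gamma_star
            if np.linalg.norm(F[:-1], np.inf) < 1e-9:
                return c, True
            J = (A + _sp.diags(Da * vol * gp)).tolil()
            J[-1, :] = 0.0
            J[-1, -1] = 1.0
            dc = _spsolve(J.tocsr().tocsc(), -F)
            lam = 1.0
            base = np.linalg.norm(F[:-1], np.inf)
            for _ in range(12):
                ct = c + lam * dc
                cpos_t = np.maximum(ct, 0.0)
                Ft = A @ ct + Da * vol * (cpos_t / (cpos_t + K_now))
                if np.linalg.norm(Ft[:-1], np.inf) < base * (1 - 1e-4 * lam):
                    break
                lam *= 0.5
            c = c + lam * dc
        cpos = np.maximum(c, 0.0)
        F = A @ c + Da * vol * (cpos / (cpos + K_now))
        # accept a stagnated iterate still well below field accuracy
        return c, bool(np.linalg.norm(F[:-1], np.inf) < 1e-7)

    c = np.full(n, gamma_star)
    c[-1] = gamma_star
    ladder = [k for k in (1e-1, 3e-2, 1e-2, 3e-3, 1e-3, 3e-4, 1e-4, 3e-5,
                          1e-5) if k > K] + [K]
    for K_now in ladder:
        c, ok = solve_at(K_now, c)
        if not ok:
            raise SolverError(
                f"radial Newton did not converge at K={K_now}")
    return r_out, np.interp(r_out, r, c)
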