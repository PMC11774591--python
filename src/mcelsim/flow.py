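"""Steady channel flow over and through the porous construct.

A single-domain Navier–Stokes–Brinkman formulation: the construct appears
as a resistive term ``(1/k*) v`` (``k* = k/a^2`` the nondimensional Darcy
permeability) added to the momentum equation, so the pressure and velocity
continuity conditions at the fluid–construct interface are satisfied
naturally and the Darcy limit ``v = -k* grad(p)`` is recovered inside the
construct for small ``k*``.

Discretization: equal-order P1 velocity/pressure with PSPG-type pressure
stabilization (the stabilization parameter degenerates to the permeability
in the Darcy region, the standard stabilized-Darcy limit); convective term
by Picard (Oseen) iteration — adequate for the creeping-to-transitional
regime (Re up to ~10) of microfluidic chambers.

Boundary conditions: parabolic inlet profile with unit peak, no-slip walls,
symmetry (zero normal velocity) on the mid-line for the unconfined
half-domain, and zero tangential velocity plus natural (pseudo-traction)
outflow at the outlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from . import fem
from .geometry import GeometryKind
from .meshing import Mesh


class FlowError(RuntimeError):
    pass


@dataclass
class FlowField:
    """Velocity (peak-inlet scale) and pressure on a chamber mesh."""

    mesh: Mesh
    velocity: np.ndarray          # (N, 2)
    pressure: np.ndarray          # (N,)
    Re: float
    k_star: float
    picard_iters: int
    residual: float

    def _tag_normal(self, tag: str, mid: np.ndarray) -> np.ndarray:
        """Outward unit normal of a tagged boundary at an edge midpoint."""
        if tag == "inlet":
            return np.array([-1.0, 0.0])
        if tag == "outlet":
            return np.array([1.0, 0.0])
        if tag == "wall_top":
            return np.array([0.0, 1.0])
        if tag in ("wall_bottom", "symmetry"):
            return np.array([0.0, -1.0])
        # interface: radially outward from the construct circle centre
        cc = np.array([0.0, self.mesh.spec.centre_y])
        d = mid - cc
        return d / np.linalg.norm(d)

    def edge_flux(self, tag: str) -> float:
        """Net outward volume flux through a tagged boundary (trapezoid
        rule, exact for the P1 velocity)."""
        edges = self.mesh.edges[tag]
        total = 0.0
        for a, b in edges:
            pa, pb = self.mesh.nodes[a], self.mesh.nodes[b]
            mid = 0.5 * (pa + pb)
            ds = np.linalg.norm(pb - pa)
            um = 0.5 * (self.velocity[a] + self.velocity[b])
            total += (um @ self._tag_normal(tag, mid)) * ds
        return total

    def interface_flux(self) -> float:
        """One-way transpiration flux through the construct interface
        (half the absolute normal-flux integral; in = out at steady
        state)."""
        edges = self.mesh.edges["interface"]
        total = 0.0
        for a, b in edges:
            pa, pb = self.mesh.nodes[a], self.mesh.nodes[b]
            mid = 0.5 * (pa + pb)
            ds = np.linalg.norm(pb - pa)
            um = 0.5 * (self.velocity[a] + self.velocity[b])
            total += abs(um @ self._tag_normal("interface", mid)) * ds
        return 0.5 * total


def _gradient_matrices(nodes, tris) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """B_x[i,j] = int phi_i d(phi_j)/dx  (and y) — divergence/gradient."""
    area, g = fem.tri_geometry(nodes, tris)
    n = len(nodes)
    w = area / 3.0
    bx = np.einsum("e,ej->ej", w, g[:, :, 0])[:, None, :] \
        * np.ones((1, 3, 1))
    by = np.einsum("e,ej->ej", w, g[:, :, 1])[:, None, :] \
        * np.ones((1, 3, 1))
    Bx = fem._scatter(tris, np.broadcast_to(bx, (len(tris), 3, 3)).copy(), n)
    By = fem._scatter(tris, np.broadcast_to(by, (len(tris), 3, 3)).copy(), n)
    return Bx, By


def solve_flow(mesh: Mesh, Re: float = 0.1, k_star: float = 1e-8,
               tol: float = 1e-9, max_picard: int = 40) -> FlowField:
    """Solve the steady Navier–Stokes–Brinkman system on a chamber mesh."""
    if Re < 0:
        raise FlowError("Re must be non-negative")
    if k_star <= 0:
        raise FlowError("k_star must be strictly positive")
    k_floor = 1e-12
    if k_star < k_floor:
        import warnings
        warnings.warn(f"k_star={k_star:.2e} floored to {k_floor:.2e} to "
                      "keep the system regular", stacklevel=2)
        k_star = k_floor

    nodes, tris = mesh.nodes, mesh.tris
    n = len(nodes)
    area, grads = fem.tri_geometry(nodes, tris)
    in2 = mesh.tri_region == 2
    sigma = np.where(in2, 1.0 / k_star, 0.0)
    h = mesh.element_sizes()

    Kv = fem.stiffness(nodes, tris, 1.0)
    Ms = fem.mass(nodes, tris, sigma, lumped=True)
    Bx, By = _gradient_matrices(nodes, tris)

    spec = mesh.spec
    H = spec.domain_height
    L = spec.L

    # Dirichlet sets ---------------------------------------------------
    def nodes_of(tag):
        e = mesh.edges.get(tag)
        return np.unique(e) if e is not None and len(e) else \
            np.empty(0, dtype=int)

    inlet = nodes_of("inlet")
    outlet = nodes_of("outlet")
    wall = np.unique(np.concatenate([nodes_of("wall_top"),
                                     nodes_of("wall_bottom")]))
    symm = nodes_of("symmetry")

    y_in = nodes[inlet, 1]
    if spec.kind is GeometryKind.unconfined and spec.use_symmetry:
        u_in = 1.0 - (y_in / H) ** 2          # half parabola, peak on S
    else:
        u_in = 4.0 * y_in * (H - y_in) / H ** 2

    # u dofs: Dirichlet on inlet (parabola) and walls (0)
    u_dir = np.concatenate([inlet, wall])
    u_val = np.concatenate([u_in, np.zeros(len(wall))])
    # v dofs: zero on inlet, walls, symmetry, outlet
    v_dir = np.unique(np.concatenate([inlet, wall, symm, outlet]))
    v_val = np.zeros(len(v_dir))
    # deduplicate u (corner nodes appear in both lists; walls win)
    _, first = np.unique(u_dir, return_index=True)
    u_dir_u = u_dir[np.sort(first)]
    u_val_u = np.array([u_val[np.nonzero(u_dir == d)[0][-1]]
                        for d in u_dir_u])

    vel = np.zeros((n, 2))
    picard = 0
    res = np.inf
    for picard in range(1, max_picard + 1):
        speed = np.linalg.norm(vel[tris].mean(axis=1), axis=1)
        tau = 1.0 / (4.0 / h**2 + sigma + 2.0 * Re * speed / h)
        A_mom = Kv + Ms
        if Re > 0:
            A_mom = A_mom + fem.advection(nodes, tris, vel, Re)
        # pressure blocks: -(p, dw/dx) = -Bx^T p ; continuity Bx u + By v
        Cp = fem.stiffness(nodes, tris, tau)   # PSPG (grad q, tau grad p)
        # (grad q, tau*sigma*u): same sparsity as Bx with weight tau*sigma
        area_w = tau * sigma
        gx = np.einsum("e,ei->ei", area_w * area / 3.0, grads[:, :, 0])
        gy = np.einsum("e,ei->ei", area_w * area / 3.0, grads[:, :, 1])
        Tx = fem._scatter(tris, np.broadcast_to(
            gx[:, :, None], (len(tris), 3, 3)).copy(), n)
        Ty = fem._scatter(tris, np.broadcast_to(
            gy[:, :, None], (len(tris), 3, 3)).copy(), n)

        Z = sp.csr_matrix((n, n))
        A = sp.bmat([[A_mom, Z, -Bx.T],
                     [Z, A_mom, -By.T],
                     [Bx + Tx, By + Ty, Cp]], format="csr")
        b = np.zeros(3 * n)

        dofs = np.concatenate([u_dir_u, v_dir + n])
        vals = np.concatenate([u_val_u, v_val])
        A_bc, b_bc = fem.apply_dirichlet(A, b, dofs, vals)
        sol = spsolve(A_bc.tocsc(), b_bc)
        vel_new = np.stack([sol[:n], sol[n:2 * n]], axis=1)
        p_new = sol[2 * n:]
        dv = np.linalg.norm(vel_new - vel) / max(np.linalg.norm(vel_new),
                                                 1e-300)
        vel = vel_new
        res = dv
        if Re == 0 or dv < tol:
            break
    return FlowField(mesh=mesh, velocity=vel, pressure=p_new, Re=Re,
                     k_star=k_star, picard_iters=picard, residual=float(res))


def eddy_profile(flow: FlowField, y_probe: float | None = None,
                 n_samples: int = 400) -> list[dict]:
    """Recirculation eddies along the floor near the confinement corners.

    Samples the wall-parallel velocity just above the bottom wall on both
    sides of the construct contact points and reports each contiguous
    interval of reversed (or forward) flow as one eddy, with its peak
    speed.  Returns an empty list for the unconfined geometry (no contact
    corner) and ``[{"status": "unresolved"}]`` when the mesh is too coarse
    to show any reversal.
    """
    mesh = flow.mesh
    if mesh.spec.kind is not GeometryKind.confined:
        return []
    from matplotlib.tri import Triangulation, LinearTriInterpolator

    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.tris)
    fu = LinearTriInterpolator(tri, flow.velocity[:, 0])
    xc = mesh.spec.contact_half_width
    if y_probe is None:
        y_probe = 2.5 * mesh.sizes.get("corner", 0.01)
    eddies: list[dict] = []
    for side in (+1, -1):
        x0 = side * xc
        xs = x0 + side * np.geomspace(1e-3, 1.5, n_samples)
        us = np.asarray(fu(xs, np.full_like(xs, y_probe)))
        valid = ~np.isnan(us)
        xs, us = xs[valid], us[valid]
        if len(xs) < 4:
            continue
        sign = np.sign(us)
        sign[sign == 0] = 1
        changes = np.nonzero(np.diff(sign))[0]
        # walk from the corner outward: segments between sign changes
        bounds = np.concatenate([[0], changes + 1, [len(xs)]])
        segs = []
        for k in range(len(bounds) - 1):
            sl = slice(bounds[k], bounds[k + 1])
            segs.append({"side": "downstream" if side > 0 else "upstream",
                         "index": k,
                         "max_speed": float(np.max(np.abs(us[sl]))),
                         "x_range": (float(xs[sl][0]), float(xs[sl][-1])),
                         "reversed": bool(np.mean(us[sl]) * side < 0)})
        # eddies are the segments before the last (primary-flow) one
        if len(segs) > 1:
            eddies.extend(segs[:-1])
    if not eddies:
        return [{"status": "unresolved",
                 "note": "no flow reversal detected at this resolution"}]
    return eddies
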