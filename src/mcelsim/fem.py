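"""Linear (P1) triangular finite-element primitives.

Assembly helpers shared by the flow and transport solvers: element
geometry, stiffness/mass/advection matrices, streamline (SUPG) and pressure
(PSPG/Brezzi–Pitkäranta-type) stabilization blocks, and Dirichlet
elimination.  Quadrature is the 3-point edge-midpoint rule, exact for
quadratics on a triangle.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def tri_geometry(nodes: np.ndarray, tris: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Areas (M,) and constant shape-function gradients (M, 3, 2)."""
    p = nodes[tris]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    area = 0.5 * np.abs(det)
    # grad phi_i = rotated opposite edge / (2A), with orientation from det
    g = np.empty((len(tris), 3, 2))
    inv = 1.0 / det
    g[:, 1, 0] = d2[:, 1] * inv
    g[:, 1, 1] = -d2[:, 0] * inv
    g[:, 2, 0] = -d1[:, 1] * inv
    g[:, 2, 1] = d1[:, 0] * inv
    g[:, 0] = -g[:, 1] - g[:, 2]
    return area, g


def _scatter(tris: np.ndarray, ke: np.ndarray, n: int) -> sp.csr_matrix:
    """Assemble per-element 3x3 blocks into a global sparse matrix."""
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return sp.csr_matrix((ke.ravel(), (rows, cols)), shape=(n, n))


def stiffness(nodes: np.ndarray, tris: np.ndarray,
              coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    """Assemble ``(coeff * grad u, grad v)`` with a per-element coefficient."""
    area, g = tri_geometry(nodes, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), area.shape)
    ke = (c * area)[:, None, None] * np.einsum("eid,ejd->eij", g, g)
    return _scatter(tris, ke, len(nodes))


#: barycentric coordinates of the edge-midpoint quadrature points
QP = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])


def mass(nodes: np.ndarray, tris: np.ndarray,
         coeff: np.ndarray | float = 1.0, lumped: bool = False
         ) -> sp.csr_matrix:
    area, _ = tri_geometry(nodes, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), area.shape)
    w = c * area / 3.0
    if lumped:
        n = len(nodes)
        diag = np.zeros(n)
        np.add.at(diag, tris.ravel(), np.repeat(w, 3))
        return sp.diags(diag).tocsr()
    ke = np.einsum("qi,qj->ij", QP, QP)[None, :, :] * w[:, None, None]
    return _scatter(tris, ke, len(nodes))


def advection(nodes: np.ndarray, tris: np.ndarray, vel: np.ndarray,
              coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    """Assemble ``(coeff * (v . grad u), w)`` with nodal velocities ``vel``."""
    area, g = tri_geometry(nodes, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), area.shape)
    v_e = vel[tris]                             # (M, 3, 2) nodal velocities
    v_q = np.einsum("qi,eid->eqd", QP, v_e)      # velocity at quad points
    # (v.grad phi_j) at quad point q, times phi_i(q), weight A/3
    a_qj = np.einsum("eqd,ejd->eqj", v_q, g)
    ke = np.einsum("qi,eqj->eij", QP, a_qj) * (c * area / 3.0)[:, None, None]
    return _scatter(tris, ke, len(nodes))


def supg(nodes: np.ndarray, tris: np.ndarray, vel: np.ndarray,
         diffusivity: np.ndarray | float, h: np.ndarray,
         coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    """Streamline-upwind stabilization ``sum_K tau_K (v.grad u, v.grad w)``.

    ``tau`` uses the optimal 1D rule ``(h/2|v|) * (coth(Pe) - 1/Pe)`` with
    the element Péclet number ``Pe = |v| h / (2 D)``; elements with
    negligible velocity contribute nothing.
    """
    area, g = tri_geometry(nodes, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), area.shape)
    D = np.broadcast_to(np.asarray(diffusivity, dtype=float), area.shape)
    v_e = c[:, None, None] * vel[tris]
    v_bar = v_e.mean(axis=1)
    speed = np.linalg.norm(v_bar, axis=1)
    pe = speed * h / (2.0 * np.maximum(D, 1e-300))
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        xi = np.where(pe > 1e-8, 1.0 / np.tanh(np.minimum(pe, 50.0))
                      - 1.0 / np.maximum(pe, 1e-8), 0.0)
    tau = np.where(speed > 1e-12, h / (2.0 * np.maximum(speed, 1e-12)) * xi,
                   0.0)
    a_j = np.einsum("ed,ejd->ej", v_bar, g)      # v.grad phi_j (constant)
    ke = np.einsum("ei,ej->eij", a_j, a_j) * (tau * area)[:, None, None]
    return _scatter(tris, ke, len(nodes))


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray,
                    dofs: np.ndarray, values: np.ndarray
                    ) -> tuple[sp.csr_matrix, np.ndarray]:
    """Eliminate Dirichlet dofs symmetrically (lifting into the rhs)."""
    n = A.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[dofs] = True
    x0 = np.zeros(n)
    x0[dofs] = values
    b = b - A @ x0
    keep = sp.diags((~mask).astype(float))
    pin = sp.diags(mask.astype(float))
    A = (keep @ A @ keep + pin).tocsr()
    b[mask] = x0[mask]
    return A, b


def node_mask_of_region(tris: np.ndarray, tri_region: np.ndarray,
                        region: int, n_nodes: int) -> np.ndarray:
    mask = np.zeros(n_nodes, dtype=bool)
    mask[np.unique(tris[tri_region == region])] = True
    return mask
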