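"""Linear (P1) triangle finite-element kernels shared by the solvers.

All assembly happens in SI units: mesh coordinates arriving in micrometres
are converted once via :func:`si_coords`.  Vector fields use the blocked dof
ordering ``[u_x(all nodes), u_y(all nodes)]``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import TaggedMesh
from .units import UM

__all__ = [
    "P1Basis", "si_coords", "stiffness", "lumped_mass", "consistent_mass",
    "divergence", "elasticity_mu", "cell_gradients", "apply_dirichlet",
    "boundary_lumped_loads", "LUSolver",
]


def si_coords(mesh: TaggedMesh) -> np.ndarray:
    return mesh.vertices * UM


class P1Basis:
    """Per-cell shape-function gradients and areas for a triangle mesh (SI)."""

    def __init__(self, mesh: TaggedMesh):
        self.mesh = mesh
        xy = si_coords(mesh)
        tri = mesh.cells
        x = xy[tri, 0]  # (m, 3)
        y = xy[tri, 1]
        self.b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0],
                           y[:, 0] - y[:, 1]], axis=1)
        self.c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2],
                           x[:, 1] - x[:, 0]], axis=1)
        self.area = 0.5 * (x[:, 0] * self.b[:, 0] + x[:, 1] * self.b[:, 1]
                           + x[:, 2] * self.b[:, 2])
        if np.any(self.area <= 0):
            raise ValueError("mesh contains inverted or degenerate cells")
        self.n_nodes = len(mesh.vertices)
        self.n_cells = len(tri)
        # dN_i = (b_i, c_i) / (2A)
        self.gradx = self.b / (2 * self.area[:, None])
        self.grady = self.c / (2 * self.area[:, None])
        self.longest_edge = self._longest_edge(x, y)

    @staticmethod
    def _longest_edge(x, y):
        e = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            e.append(np.hypot(x[:, i] - x[:, j], y[:, i] - y[:, j]))
        return np.max(e, axis=0)

    def _coo(self, local: np.ndarray) -> sp.csr_matrix:
        """Assemble from per-cell 3x3 blocks ``local`` (m, 3, 3)."""
        tri = self.mesh.cells
        rows = np.repeat(tri, 3, axis=1).ravel()
        cols = np.tile(tri, (1, 3)).ravel()
        return sp.coo_matrix((local.ravel(), (rows, cols)),
                             shape=(self.n_nodes, self.n_nodes)).tocsr()


def stiffness(basis: P1Basis, coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    """Scalar stiffness  K_ij = sum_K coeff_K grad N_i . grad N_j |K|."""
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), (basis.n_cells,))
    gb = basis.gradx
    gc = basis.grady
    local = (np.einsum("ki,kj->kij", gb, gb) + np.einsum("ki,kj->kij", gc, gc))
    local *= (coeff * basis.area)[:, None, None]
    return basis._coo(local)


def lumped_mass(basis: P1Basis, coeff: np.ndarray | float = 1.0) -> np.ndarray:
    """Diagonal (lumped) mass vector, node-wise."""
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), (basis.n_cells,))
    w = coeff * basis.area / 3.0
    out = np.zeros(basis.n_nodes)
    np.add.at(out, basis.mesh.cells.ravel(), np.repeat(w, 3))
    return out


def consistent_mass(basis: P1Basis, coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), (basis.n_cells,))
    base = (np.ones((3, 3)) + np.eye(3)) / 12.0
    local = base[None, :, :] * (coeff * basis.area)[:, None, None]
    return basis._coo(local)


def divergence(basis: P1Basis, coeff: np.ndarray | float = 1.0) -> sp.csr_matrix:
    """D (n x 2n) with (D u)_i = int coeff N_i div u, for blocked vector dofs."""
    tri = basis.mesh.cells
    n = basis.n_nodes
    coeff = np.broadcast_to(np.asarray(coeff, dtype=float), (basis.n_cells,))
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    w = (coeff * basis.area)[:, None, None] / 3.0
    wx = np.repeat(w * basis.gradx[:, None, :], 3, axis=1).ravel()
    wy = np.repeat(w * basis.grady[:, None, :], 3, axis=1).ravel()
    Dx = sp.coo_matrix((wx, (rows, cols)), shape=(n, n))
    Dy = sp.coo_matrix((wy, (rows, cols)), shape=(n, n))
    return sp.hstack([Dx, Dy]).tocsr()


def divergence_weighted(basis: P1Basis, coeff) -> sp.csr_matrix:
    return divergence(basis, coeff)


def convection(basis: P1Basis, w: np.ndarray) -> sp.csr_matrix:
    """Scalar advection  C_ij = int N_i (w . grad N_j), w nodal (n,2).

    Uses the cell-mean advecting velocity and lumped test weights.
    """
    wc = w[basis.mesh.cells].mean(axis=1)  # (m,2)
    adv = (wc[:, 0:1] * basis.gradx + wc[:, 1:2] * basis.grady)  # (m,3)
    local = np.repeat((basis.area / 3.0)[:, None, None], 3, axis=1) \
        * adv[:, None, :]
    return basis._coo(local)


def elasticity_mu(basis: P1Basis, two_mu: np.ndarray) -> sp.csr_matrix:
    """Vector form  int 2 mu eps(u):eps(v)  (blocked dofs), per-cell 2mu."""
    m, n = basis.n_cells, basis.n_nodes
    # B maps nodal (ux1..3, uy1..3) -> (exx, eyy, gxy)
    B = np.zeros((m, 3, 6))
    B[:, 0, 0:3] = basis.gradx
    B[:, 1, 3:6] = basis.grady
    B[:, 2, 0:3] = basis.grady
    B[:, 2, 3:6] = basis.gradx
    D = np.zeros((m, 3, 3))
    D[:, 0, 0] = two_mu
    D[:, 1, 1] = two_mu
    D[:, 2, 2] = 0.5 * two_mu  # shear: sigma_xy = mu * gamma_xy
    local = np.einsum("kpi,kpq,kqj->kij", B, D, B) * basis.area[:, None, None]
    tri = basis.mesh.cells
    dofs = np.hstack([tri, tri + n])  # (m, 6)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)),
                         shape=(2 * n, 2 * n)).tocsr()


def cell_gradients(basis: P1Basis, nodal: np.ndarray) -> np.ndarray:
    """Piecewise-constant gradient (m, 2) of a nodal scalar field."""
    v = nodal[basis.mesh.cells]  # (m,3)
    return np.stack([(v * basis.gradx).sum(axis=1),
                     (v * basis.grady).sum(axis=1)], axis=1)


def boundary_lumped_loads(mesh: TaggedMesh, facet_idx: np.ndarray) -> np.ndarray:
    """Nodal weights (n,) equal to int N_i ds over the given facets (SI)."""
    w = np.zeros(len(mesh.vertices))
    lens = mesh.facet_lengths(facet_idx) * UM
    f = mesh.facets[facet_idx]
    np.add.at(w, f[:, 0], 0.5 * lens)
    np.add.at(w, f[:, 1], 0.5 * lens)
    return w


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs: np.ndarray,
                    values: np.ndarray):
    """Return (A', b') with rows/cols of ``dofs`` eliminated symmetrically."""
    n = A.shape[0]
    x0 = np.zeros(n)
    x0[dofs] = values
    b = b - A @ x0
    keep = np.ones(n, dtype=bool)
    keep[dofs] = False
    mask = sp.diags(keep.astype(float))
    A = mask @ A @ mask + sp.diags((~keep).astype(float))
    b[dofs] = values
    return A.tocsr(), b


class LUSolver:
    """Cached sparse LU factorization."""

    def __init__(self, A: sp.csr_matrix):
        self.lu = spla.splu(A.tocsc())

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self.lu.solve(b)
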