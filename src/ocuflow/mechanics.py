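"""Quasi-static near-incompressible elasticity of the outflow tissues.

The TM, JCT and SC inner wall are isotropic linear-elastic regions
(E = 4, 4 and 7.48 kPa, nu = 0.495).  The stress splits into an elastic part
and an interstitial-pressure part:

    sigma_t = lambda e I + 2 mu_s eps(u_t),   sigma_i = -P_i I,
    sigma_total = sigma_t + sigma_i,          div(eps_t sigma_total) = 0,

with e = tr(eps) the volumetric strain and eps_t a per-region volume
fraction (default 1).  Near-incompressibility is handled by a two-field
mixed (Herrmann) formulation with the pressure-like unknown p_s = lambda e
and P1-P1 interpolation plus a weak pressure-gradient stabilization, which
is free of volumetric locking.  The 2D default is plane strain.

A ciliary-muscle pre-tension (~500 uN resultant) is applied as a statically
equivalent distributed tangential traction along the lateral TM boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import fem
from .geometry import BoundaryTag, Region, TaggedMesh

__all__ = [
    "SolidProperties", "MechanicalState", "lame_parameters", "strain_tensor",
    "stress_decomposition", "SolidSolver", "solve_quasistatic",
    "principal_values", "max_shear",
]

_SNAP = 1e-9


def lame_parameters(young: float, poisson: float) -> tuple[float, float]:
    """Lame parameters (lambda, mu) from (E, nu); rejects nu >= 0.5."""
    if young <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 <= poisson < 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5) (the "
                         "incompressible limit is not representable)")
    mu = young / (2 * (1 + poisson))
    lam = young * poisson / ((1 + poisson) * (1 - 2 * poisson))
    return lam, mu


@dataclass(frozen=True)
class SolidProperties:
    """Per-region elastic constants of the outflow tissues (SI)."""

    young_modulus: dict = field(default_factory=lambda: {
        Region.TM: 4e3, Region.JCT: 4e3, Region.SC_WALL: 7.48e3})
    poisson_ratio: float = 0.495
    volume_fraction: dict = field(default_factory=dict)  # eps_t, default 1
    pretension: float = 500e-6       # N, resultant ciliary pre-tension
    #: out-of-plane depth converting forces to line loads.  Default: the
    #: ~36 mm circumference of the TM ring, i.e. the pre-tension resultant
    #: is shared by the whole 360 deg band and a plane slice carries its
    #: per-length share (~14 uN/mm).
    out_of_plane_depth: float = 36e-3
    plane: str = "strain"
    stab_beta: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.plane not in ("strain", "stress"):
            raise ValueError("plane must be 'strain' or 'stress'")
        for r, vf in self.volume_fraction.items():
            if not 0 < vf <= 1:
                raise ValueError("volume fractions must lie in (0, 1]")

    def lame_arrays(self, region: np.ndarray):
        lam = np.empty(len(region))
        mu = np.empty(len(region))
        for r, E in self.young_modulus.items():
            m = region == int(r)
            l_, m_ = lame_parameters(E, self.poisson_ratio)
            lam[m], mu[m] = l_, m_
        return lam, mu

    def vf_array(self, region: np.ndarray) -> np.ndarray:
        vf = np.ones(len(region))
        for r, v in self.volume_fraction.items():
            vf[region == int(r)] = v
        return vf


def strain_tensor(mesh: TaggedMesh, displacement: np.ndarray):
    """Infinitesimal strain  eps = (grad u + grad u^T)/2  per cell.

    Returns (eps_voigt, e): eps_voigt = (eps_xx, eps_yy, eps_xy) of shape
    (m, 3) and the volumetric strain e = tr(eps).
    """
    basis = fem.P1Basis(mesh)
    gx = fem.cell_gradients(basis, displacement[:, 0])
    gy = fem.cell_gradients(basis, displacement[:, 1])
    eps = np.column_stack([gx[:, 0], gy[:, 1], 0.5 * (gx[:, 1] + gy[:, 0])])
    return eps, eps[:, 0] + eps[:, 1]


def stress_decomposition(strain: np.ndarray, e: np.ndarray, p_i: np.ndarray,
                         lam: np.ndarray, mu: np.ndarray):
    """Stress split sigma_t = lam e I + 2 mu eps, sigma_i = -P_i I (voigt).

    All inputs are per-cell; scalars broadcast.  Returns
    (sigma_t, sigma_i, sigma_total), each (m, 3) = (s_xx, s_yy, s_xy).
    """
    strain = np.atleast_2d(strain)
    e = np.broadcast_to(np.asarray(e, dtype=float), (len(strain),))
    p_i = np.broadcast_to(np.asarray(p_i, dtype=float), (len(strain),))
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (len(strain),))
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (len(strain),))
    st = np.column_stack([lam * e + 2 * mu * strain[:, 0],
                          lam * e + 2 * mu * strain[:, 1],
                          2 * mu * strain[:, 2]])
    si = np.column_stack([-p_i, -p_i, np.zeros(len(strain))])
    return st, si, st + si


def _as_voigt(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.ndim >= 2 and t.shape[-2:] == (2, 2):
        t = t.reshape(-1, 2, 2)
        if not np.allclose(t[:, 0, 1], t[:, 1, 0], rtol=1e-10, atol=1e-14):
            raise ValueError("tensor field is not symmetric")
        return np.column_stack([t[:, 0, 0], t[:, 1, 1], t[:, 0, 1]])
    return np.atleast_2d(t)


def principal_values(tensor_field: np.ndarray,
                     zz: np.ndarray | float = 0.0) -> np.ndarray:
    """Ordered principal values (s1 >= s2 >= s3) of symmetric 2D tensors.

    ``tensor_field`` is (m, 3) voigt or (m, 2, 2); ``zz`` supplies the
    out-of-plane component (e.g. nu*(s_xx+s_yy) for plane-strain stress,
    0 for plane-strain strain).  Returns (m, 3).
    """
    v = _as_voigt(tensor_field)
    zz = np.broadcast_to(np.asarray(zz, dtype=float), (len(v),))
    c = 0.5 * (v[:, 0] + v[:, 1])
    r = np.hypot(0.5 * (v[:, 0] - v[:, 1]), v[:, 2])
    vals = np.column_stack([c + r, c - r, zz])
    return -np.sort(-vals, axis=1)


def max_shear(tensor_field: np.ndarray,
              zz: np.ndarray | float = 0.0) -> np.ndarray:
    """Maximum shear (s1 - s3)/2 per point."""
    pv = principal_values(tensor_field, zz)
    return 0.5 * (pv[:, 0] - pv[:, 2])


@dataclass
class MechanicalState:
    """Tissue kinematics and stress at one time level (cellwise tensors)."""

    mesh: TaggedMesh
    displacement: np.ndarray       # (n, 2) m
    tissue_velocity: np.ndarray    # (n, 2) m/s
    strain: np.ndarray             # (m, 3) voigt
    e: np.ndarray                  # (m,), recovered volumetric strain
    sigma_t: np.ndarray            # (m, 3) Pa
    sigma_i: np.ndarray
    sigma_total: np.ndarray
    sigma_zz: np.ndarray           # (m,) out-of-plane total stress (plane strain)
    p_interstitial: np.ndarray     # (n,) Pa


class SolidSolver:
    """Mixed u-p solver on an all-tissue tagged mesh.

    Dof layout ``[u_x (n), u_y (n), p_s (n)]`` with p_s = lambda e.  Anchored
    facets are fixed, symmetry facets are rollers, interface loads arrive as
    consistent nodal forces, and the interstitial pressure enters through the
    isotropic stress term.  The operator is constant, so the factorization is
    reused across load steps.
    """

    def __init__(self, mesh: TaggedMesh, props: SolidProperties):
        if mesh.is_fluid_cell().any():
            raise ValueError("SolidSolver requires a tissue-only mesh")
        self.mesh = mesh
        self.props = props
        self.basis = fem.P1Basis(mesh)
        n = self.n = self.basis.n_nodes
        self.lam, self.mu = props.lame_arrays(mesh.region)
        vf = props.vf_array(mesh.region)
        A = fem.elasticity_mu(self.basis, 2 * self.mu * vf)
        self.D = fem.divergence(self.basis)
        self.Dvf = fem.divergence_weighted(self.basis, vf)
        Ml = fem.consistent_mass(self.basis, 1.0 / self.lam)
        hk2 = 2.0 * self.basis.area  # effective element size squared
        S = fem.stiffness(self.basis, props.stab_beta * hk2 / (2 * self.mu))
        self.A_sys = sp.bmat([[A, self.Dvf.T], [self.D, -(Ml + S)]],
                             format="csr")
        self._dirichlet()
        self._pretension_loads()
        if len(self.anchor_nodes) == 0:
            raise ValueError("no anchor facets: the tissue problem is singular")
        self._lu = None

    def _dirichlet(self) -> None:
        mesh, n = self.mesh, self.n
        anchor = mesh.nodes_by_tag(BoundaryTag.ANCHOR)
        self.anchor_nodes = anchor
        sym_idx = mesh.facet_index(BoundaryTag.SYMMETRY)
        f = mesh.facets[sym_idx]
        dy = np.abs(mesh.vertices[f[:, 0], 1] - mesh.vertices[f[:, 1], 1])
        horiz = dy < _SNAP
        sym_y = np.setdiff1d(np.unique(f[horiz]), anchor)
        sym_x = np.setdiff1d(np.unique(f[~horiz]), anchor)
        self.dir_dofs = np.concatenate([anchor, anchor + n, sym_x, sym_y + n])

    def _pretension_loads(self) -> None:
        """Unit pre-tension load vector: tangential (-x) traction on the
        lateral TM boundary, resultant 1 N (scaled at solve time)."""
        mesh = self.mesh
        idx = mesh.facet_index(BoundaryTag.SYMMETRY)
        adj = mesh.facet_cells[idx, 0]
        tm = mesh.region[adj] == int(Region.TM)
        idx = idx[tm]
        self.pretension_facets = idx
        b = np.zeros(2 * self.n)
        if len(idx):
            w = fem.boundary_lumped_loads(mesh, idx)  # int N_i ds, SI
            total_len = w.sum()
            b[:self.n] = -w / total_len  # traction -x, resultant 1 N/m
        self.unit_pretension = b

    def solve(self, interface_forces: np.ndarray | None = None,
              p_interstitial: np.ndarray | None = None,
              pretension: float | None = None,
              return_reactions: bool = False,
              return_system: bool = False):
        """Solve equilibrium; returns (displacement (n,2), p_s nodal[, reactions])."""
        n = self.n
        b = np.zeros(3 * n)
        if interface_forces is not None:
            f = np.asarray(interface_forces)
            b[:n] += f[:, 0]
            b[n:2 * n] += f[:, 1]
        if p_interstitial is not None:
            b[:2 * n] += self.Dvf.T @ p_interstitial
        if pretension is None:
            pretension = self.props.pretension
        line_force = pretension / self.props.out_of_plane_depth  # N/m
        b[:2 * n] += line_force * self.unit_pretension
        b0 = b.copy()
        A, b = fem.apply_dirichlet(self.A_sys, b, self.dir_dofs,
                                   np.zeros(len(self.dir_dofs)))
        if self._lu is None:
            self._lu = fem.LUSolver(A)
        x = self._lu.solve(b)
        u = np.column_stack([x[:n], x[n:2 * n]])
        ps = x[2 * n:]
        if return_system:
            return u, ps, x, b0
        if return_reactions:
            r = self.A_sys @ x - b0
            rx = r[self.anchor_nodes]
            ry = r[self.anchor_nodes + n]
            return u, ps, np.column_stack([rx, ry])
        return u, ps

    def state(self, u: np.ndarray, ps: np.ndarray,
              p_interstitial: np.ndarray | None = None,
              u_prev: np.ndarray | None = None,
              dt: float | None = None) -> MechanicalState:
        """Assemble the full kinematic/stress state from a mixed solution.

        The volumetric strain fed into the constitutive split is recovered
        from the mixed pressure (e = p_s/lambda), which is the locking-free
        quantity at nu near 0.5.
        """
        mesh = self.mesh
        eps, _ = strain_tensor(mesh, u)
        ps_cell = ps[mesh.cells].mean(axis=1)
        e = ps_cell / self.lam
        if p_interstitial is None:
            p_interstitial = np.zeros(self.n)
        pi_cell = p_interstitial[mesh.cells].mean(axis=1)
        st, si, stot = stress_decomposition(eps, e, pi_cell, self.lam, self.mu)
        # plane strain out-of-plane stress: sigma_zz = lam e - P_i
        szz = self.lam * e - pi_cell
        vt = np.zeros_like(u)
        if u_prev is not None and dt:
            vt = (u - u_prev) / dt
        return MechanicalState(mesh, u, vt, eps, e, st, si, stot, szz,
                               p_interstitial)

    def energy_balance(self, x_full: np.ndarray, b_full: np.ndarray):
        """(external work, stored energy) = (x.b/2, x.A x/2) for a solve."""
        w = 0.5 * float(x_full @ b_full)
        u_energy = 0.5 * float(x_full @ (self.A_sys @ x_full))
        return w, u_energy


def solve_quasistatic(mesh: TaggedMesh, props: SolidProperties,
                      interface_forces: np.ndarray | None = None,
                      p_interstitial: np.ndarray | None = None,
                      pretension: float | None = None) -> MechanicalState:
    """One-shot quasi-static solve returning the full mechanical state."""
    solver = SolidSolver(mesh, props)
    u, ps = solver.solve(interface_forces, p_interstitial, pretension)
    return solver.state(u, ps, p_interstitial)
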