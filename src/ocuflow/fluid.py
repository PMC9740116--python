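"""Incompressible laminar aqueous-humor flow with an electric body force.

Momentum balance (the electroosmotic Navier-Stokes system)

    rho (du/dt + u . grad u) = -grad p + mu lap u + rho_f E,

discretized with equal-order P1 velocity/pressure and Brezzi-Pitkaranta
pressure stabilization, implicit Euler in time, and Picard linearization of
the convective term.  Boundary conditions follow the outflow-pathway setup:
a normal-traction inlet carrying the IOP ramp, an open outlet with zero
normal stress (f0 = 0), no-slip (optionally moving-wall) glycocalyx
boundaries, and free-slip symmetry planes.

The elementwise body force is the product rho_f E; its sign is chosen by the
caller (the scenario layer defaults to the momentum equation as printed,
with the electric term entering as -rho_f E, while the analytic
electroosmotic oracles use the conventional +rho_f E).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import fem
from .geometry import BoundaryTag, TaggedMesh
from .units import UM, mmhg_to_pa, pa_to_mmhg  # noqa: F401  (re-exported)

__all__ = [
    "FluidProperties", "LoadSchedule", "FlowState", "FluxReport",
    "iop_schedule", "body_force_field", "FluidSolver", "solve_flow_step",
    "flux_balance", "analytic_plane_poiseuille", "reynolds_number",
]

_SNAP = 1e-9


@dataclass(frozen=True)
class FluidProperties:
    """Aqueous humor treated as a homogeneous Newtonian liquid."""

    density: float = 1000.0        # kg/m^3
    viscosity: float = 7.185e-4    # Pa s
    include_convection: bool = True

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class LoadSchedule:
    """Linear IOP ramp 0 -> peak over ``duration`` with fixed time step."""

    peak_iop: float = 15.0   # mmHg
    duration: float = 1.0    # s
    dt: float = 0.01         # s

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer number of steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def times(self) -> np.ndarray:
        return self.dt * np.arange(1, self.n_steps + 1)


def iop_schedule(t: float, schedule: LoadSchedule) -> float:
    """IOP (mmHg) at time ``t`` under the linear ramp."""
    if t < -1e-12 or t > schedule.duration + 1e-12:
        raise ValueError(f"t={t} outside [0, {schedule.duration}]")
    return schedule.peak_iop * t / schedule.duration


@dataclass
class FlowState:
    """Velocity (nodal, m/s) and pressure (nodal, Pa) at one time level."""

    mesh: TaggedMesh
    u: np.ndarray       # (n, 2)
    p: np.ndarray       # (n,)
    time: float = 0.0

    def speed(self) -> np.ndarray:
        return np.hypot(self.u[:, 0], self.u[:, 1])


@dataclass
class FluxReport:
    """Per-boundary volumetric fluxes (m^2/s per unit depth) and their net."""

    per_tag: dict
    net: float
    gross: float


def body_force_field(charge: np.ndarray, efield: np.ndarray,
                     mesh: TaggedMesh, sign: float = 1.0) -> np.ndarray:
    """Cellwise electric body force f = rho_f E (N/m^3).

    ``charge`` is nodal (C/m^3), ``efield`` cellwise (V/m).
    """
    if len(charge) != len(mesh.vertices) or len(efield) != len(mesh.cells):
        raise ValueError("charge/efield sizes do not match the mesh")
    rho_cell = charge[mesh.cells].mean(axis=1)
    return sign * rho_cell[:, None] * efield


class FluidSolver:
    """Stabilized P1-P1 flow solver on an all-fluid tagged mesh.

    Dof layout: ``[u_x (n), u_y (n), p (n)]``.
    """

    def __init__(self, mesh: TaggedMesh, props: FluidProperties,
                 stab_alpha: float = 0.05, force_sign: float = 1.0):
        if not mesh.is_fluid_cell().all():
            raise ValueError("FluidSolver requires an all-fluid mesh; extract "
                             "the fluid submesh first")
        self.mesh = mesh
        self.props = props
        self.force_sign = force_sign
        self.basis = fem.P1Basis(mesh)
        n = self.basis.n_nodes
        self.n = n
        mu = props.viscosity
        K = fem.stiffness(self.basis)
        self.visc = sp.block_diag([mu * K, mu * K]).tocsr()
        self.mass_l = fem.lumped_mass(self.basis)          # scalar lumped mass
        self.D = fem.divergence(self.basis)                # (n, 2n)
        hk2 = 2.0 * self.basis.area  # effective element size squared
        self.S = fem.stiffness(self.basis, stab_alpha * hk2 / mu)
        self._dirichlet()
        self._inlet_weights()

    # -- boundary bookkeeping -------------------------------------------
    def _dirichlet(self) -> None:
        mesh = self.mesh
        n = self.n
        wall = mesh.nodes_by_tag(BoundaryTag.GLYCOCALYX_WALL)
        self.wall_nodes = wall
        sym_idx = mesh.facet_index(BoundaryTag.SYMMETRY)
        f = mesh.facets[sym_idx]
        dy = np.abs(mesh.vertices[f[:, 0], 1] - mesh.vertices[f[:, 1], 1])
        horiz = dy < _SNAP
        sym_y = np.unique(f[horiz])
        sym_x = np.unique(f[~horiz])
        sym_y = np.setdiff1d(sym_y, wall)
        sym_x = np.setdiff1d(sym_x, wall)
        self.dir_dofs = np.concatenate([wall, wall + n, sym_x, sym_y + n])
        self._wall_slice = slice(0, 2 * len(wall))

    def _normal_weights(self, tag: BoundaryTag) -> np.ndarray:
        """Nodal weights int N_i n ds over the facets of one tag."""
        idx = self.mesh.facet_index(tag)
        w = np.zeros((self.n, 2))
        if len(idx):
            normals = self.mesh.facet_outward_normals(idx)
            lens = self.mesh.facet_lengths(idx) * UM
            f = self.mesh.facets[idx]
            for k in range(len(idx)):
                for node in f[k]:
                    w[node] += 0.5 * lens[k] * normals[k]
        return w

    def _inlet_weights(self) -> None:
        self.inlet_facets = self.mesh.facet_index(BoundaryTag.INLET)
        self.inlet_normal_weights = self._normal_weights(BoundaryTag.INLET)
        self.open_normal_weights = (self.inlet_normal_weights
                                    + self._normal_weights(BoundaryTag.OUTLET_OPEN))

    # -- assembly --------------------------------------------------------
    def _matrix(self, w: np.ndarray | None, dt: float | None) -> sp.csr_matrix:
        rho = self.props.density
        Av = self.visc.copy()
        if dt is not None:
            Md = sp.diags(np.tile(rho / dt * self.mass_l, 2))
            Av = Av + Md
        if w is not None and self.props.include_convection:
            C = fem.convection(self.basis, w)
            Av = Av + sp.block_diag([rho * C, rho * C])
        return sp.bmat([[Av, -self.D.T], [self.D, -self.S]], format="csr")

    def _rhs(self, inlet_pressure: float, body_force: np.ndarray | None,
             prev_u: np.ndarray | None, dt: float | None,
             osmotic_pressure: np.ndarray | None = None) -> np.ndarray:
        n = self.n
        b = np.zeros(3 * n)
        # traction inlet: t = -p_in n  =>  int t . v = -p_in int n N_i ds
        b[:n] += -inlet_pressure * self.inlet_normal_weights[:, 0]
        b[n:2 * n] += -inlet_pressure * self.inlet_normal_weights[:, 1]
        if osmotic_pressure is not None:
            # open boundaries cut through the double layer: the f0 = 0
            # condition applies to the electrochemical normal stress, so the
            # EDL osmotic pressure chi enters as an extra normal traction
            b[:n] += -osmotic_pressure * self.open_normal_weights[:, 0]
            b[n:2 * n] += -osmotic_pressure * self.open_normal_weights[:, 1]
        if body_force is not None:
            f = self.force_sign * np.asarray(body_force)
            w = self.basis.area / 3.0
            for c in range(3):
                np.add.at(b[:n], self.mesh.cells[:, c], w * f[:, 0])
                np.add.at(b[n:2 * n], self.mesh.cells[:, c], w * f[:, 1])
        if dt is not None and prev_u is not None:
            rho = self.props.density
            b[:n] += rho / dt * self.mass_l * prev_u[:, 0]
            b[n:2 * n] += rho / dt * self.mass_l * prev_u[:, 1]
        return b

    # -- solve -----------------------------------------------------------
    def solve(self, inlet_pressure: float = 0.0,
              body_force: np.ndarray | None = None,
              wall_velocity: np.ndarray | None = None,
              osmotic_pressure: np.ndarray | None = None,
              prev: FlowState | None = None, dt: float | None = None,
              picard_tol: float = 1e-8, max_picard: int = 30,
              w_init: np.ndarray | None = None, picard: bool = True,
              return_reactions: bool = False):
        """One implicit step (or the steady problem when ``dt`` is None).

        ``w_init`` seeds the Picard linearization (defaults to the previous
        step's velocity).  With ``picard=False`` a single Oseen solve
        linearized at ``w_init`` is performed — the operator is then affine
        in the boundary data, which the partitioned coupling relies on.
        """
        n = self.n
        prev_u = prev.u if prev is not None else None
        b0 = self._rhs(inlet_pressure, body_force, prev_u, dt,
                       osmotic_pressure)
        nw = len(self.wall_nodes)
        gw = np.zeros((nw, 2)) if wall_velocity is None else np.asarray(wall_velocity)
        dvals = np.concatenate([gw[:, 0], gw[:, 1],
                                np.zeros(len(self.dir_dofs) - 2 * nw)])
        if picard is False:
            A0 = self._matrix(w_init, dt)
            A, b = fem.apply_dirichlet(A0, b0.copy(), self.dir_dofs, dvals)
            x = fem.LUSolver(A).solve(b)
            return self._pack(x, A0, b0, prev, dt, return_reactions)
        x = None
        history = []
        # two attempts: seeded linearization, then a fresh Stokes start if a
        # bad seed made the iteration diverge
        for w_seed in (w_init if w_init is not None else prev_u, None):
            w = w_seed
            x = None
            history = []
            converged = not self.props.include_convection
            for it in range(max_picard if self.props.include_convection else 1):
                A0 = self._matrix(w, dt)
                A, b = fem.apply_dirichlet(A0, b0.copy(), self.dir_dofs, dvals)
                x_new = fem.LUSolver(A).solve(b)
                if x is not None:
                    du = np.linalg.norm(x_new[:2 * n] - x[:2 * n])
                    ref = max(np.linalg.norm(x_new[:2 * n]), 1e-300)
                    history.append(du / ref)
                    x = x_new
                    if du / ref < picard_tol:
                        converged = True
                        break
                    if du / ref > 10 and it > 2:
                        break  # diverging: try the fresh start
                else:
                    x = x_new
                w = np.column_stack([x[:n], x[n:2 * n]])
            if converged:
                break
        else:
            if self.props.include_convection:
                raise RuntimeError(
                    f"Picard iteration did not converge: residuals {history}")
        return self._pack(x, A0, b0, prev, dt, return_reactions)

    def _pack(self, x, A0, b0, prev, dt, return_reactions):
        n = self.n
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite flow solution")
        state = FlowState(self.mesh, np.column_stack([x[:n], x[n:2 * n]]),
                          x[2 * n:], time=(prev.time + dt) if (prev and dt) else 0.0)
        if return_reactions:
            r = A0 @ x - b0
            rx = r[self.wall_nodes]
            ry = r[self.wall_nodes + n]
            return state, np.column_stack([rx, ry])
        return state


def solve_flow_step(mesh: TaggedMesh, props: FluidProperties,
                    body_force: np.ndarray | None, inlet_pressure: float,
                    prev: FlowState | None, dt: float | None,
                    **kw) -> FlowState:
    """Convenience one-shot wrapper around :class:`FluidSolver`."""
    return FluidSolver(mesh, props).solve(
        inlet_pressure=inlet_pressure, body_force=body_force,
        prev=prev, dt=dt, **kw)


def flux_balance(state: FlowState, mesh: TaggedMesh) -> FluxReport:
    """Boundary volumetric fluxes int u.n ds per tag (outward from the fluid)."""
    per = {}
    for tag in BoundaryTag:
        idx = mesh.facet_index(tag)
        if len(idx) == 0:
            continue
        normals = mesh.facet_outward_normals(idx)
        lens = mesh.facet_lengths(idx) * UM
        f = mesh.facets[idx]
        un = 0.5 * (np.einsum("ij,ij->i", state.u[f[:, 0]], normals)
                    + np.einsum("ij,ij->i", state.u[f[:, 1]], normals))
        per[tag.name] = float((un * lens).sum())
    net = float(sum(per.values()))
    gross = float(sum(abs(v) for v in per.values()))
    return FluxReport(per, net, gross)


def analytic_plane_poiseuille(half_width: float, dpdx: float, viscosity: float,
                              n_points: int = 101):
    """Closed-form plane Poiseuille profile u(y) = (-dpdx/2mu)(h^2 - y^2) (SI)."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    y = np.linspace(-half_width, half_width, n_points)
    u = (-dpdx / (2 * viscosity)) * (half_width**2 - y**2)
    return y, u


def reynolds_number(state: FlowState, props: FluidProperties,
                    length_scale: float) -> float:
    """Re = rho U L / mu with U the peak speed and L a supplied scale (m)."""
    return props.density * float(state.speed().max()) * length_scale / props.viscosity
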