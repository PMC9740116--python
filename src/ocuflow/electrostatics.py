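"""Electric double layer of the charged glycocalyx-coated boundaries.

The glycocalyx is represented as a charged boundary condition: the zeta
potential is imposed on every tissue-fluid (glycocalyx) facet and the bulk
potential obeys the linearized (Debye-Hueckel) Poisson-Boltzmann closure

    lap(Phi) = kappa^2 Phi ,    rho_f = -eps kappa^2 Phi ,   E = -grad Phi,

with zero normal gradient on all other boundaries.  Linearization is
justified here because |zeta| = 19.5 mV is below the 25.7 mV thermal scale.
The Debye length kappa^-1 is a configuration parameter (the source constants
include no ionic strength); its default is the physiological-saline order of
10 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import fem
from .geometry import BoundaryTag, TaggedMesh, wall_normal_sizes
from .units import EPS0, NM

__all__ = [
    "ElectroProperties", "PotentialField", "ElectricState",
    "solve_quiescent_potential", "charge_density", "electric_field",
    "analytic_plane_edl", "helmholtz_smoluchowski_slip", "poisson_residual",
    "edl_osmotic_pressure",
]


@dataclass(frozen=True)
class ElectroProperties:
    """Electrical constants of the aqueous humor / outflow-tissue interface.

    ``conductivity`` is stored in the printed unit ohm^-1 cm^-1.
    ``reference_impedance`` and ``membrane_potential`` are recorded material
    metadata; only ``zeta_potential`` enters the fluid-side field problem.
    """

    zeta_potential: float = -19.5e-3     # V
    relative_permittivity: float = 99.0
    conductivity: float = 179e-4         # ohm^-1 cm^-1
    membrane_potential: float = -70e-3   # V
    reference_impedance: float = 50.0    # ohm (metadata only)
    debye_length_nm: float = 10.0

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 0:
            raise ValueError("relative_permittivity must be positive")
        if self.debye_length_nm <= 0:
            raise ValueError("debye_length_nm must be positive")

    @property
    def permittivity(self) -> float:
        """Absolute permittivity eps_r * eps0, F/m."""
        return self.relative_permittivity * EPS0

    @property
    def debye_length(self) -> float:
        """kappa^-1 in metres."""
        return self.debye_length_nm * NM

    @property
    def kappa(self) -> float:
        """Inverse Debye length, 1/m."""
        return 1.0 / self.debye_length


@dataclass
class PotentialField:
    """Nodal electric potential (V) on a tagged mesh."""

    mesh: TaggedMesh
    phi: np.ndarray
    mode: str
    zeta: float

    def __post_init__(self) -> None:
        if len(self.phi) != len(self.mesh.vertices):
            raise ValueError("potential length does not match mesh")


@dataclass
class ElectricState:
    """Free charge density (nodal, C/m^3) and field E = -grad Phi (per cell, V/m)."""

    mesh: TaggedMesh
    rho_f: np.ndarray
    E: np.ndarray


def _fluid_basis(mesh: TaggedMesh):
    """Basis over fluid cells; returns (basis, node scatter map or None)."""
    fluid = mesh.is_fluid_cell()
    if fluid.all():
        return fem.P1Basis(mesh), None
    sub, parent = mesh.submesh(fluid)
    return fem.P1Basis(sub), parent


def solve_quiescent_potential(mesh: TaggedMesh, props: ElectroProperties,
                              mode: str = "thin-edl") -> PotentialField:
    """Solve the no-flow (quiescent) potential on the fluid region.

    ``resolved`` meshes the double layer (requires wall-adjacent elements no
    larger than kappa^-1/3 in the wall-normal direction); ``thin-edl`` treats
    the layer as unresolved: the bulk potential is identically zero and zeta
    is recorded for slip-velocity generation at the walls.
    """
    if mode not in ("resolved", "thin-edl"):
        raise ValueError("mode must be 'resolved' or 'thin-edl'")
    wall_nodes = mesh.nodes_by_tag(BoundaryTag.GLYCOCALYX_WALL)
    if len(wall_nodes) == 0:
        raise ValueError("mesh has no glycocalyx_wall facets")
    zeta = props.zeta_potential
    if mode == "thin-edl" or zeta == 0.0:
        return PotentialField(mesh, np.zeros(len(mesh.vertices)), mode, zeta)

    sizes_um = wall_normal_sizes(mesh)
    limit_um = props.debye_length / 3.0 / 1e-6
    if sizes_um.max() > limit_um * (1 + 1e-9):
        raise ValueError(
            f"under-resolved double layer: wall-normal element size "
            f"{sizes_um.max():.3g} um exceeds kappa^-1/3 = {limit_um:.3g} um; "
            "refine near the glycocalyx walls")

    basis, parent = _fluid_basis(mesh)
    sub_mesh = basis.mesh
    K = fem.stiffness(basis)
    # lumped Helmholtz term keeps the discrete maximum principle on
    # right-triangle meshes
    M = sp.diags(fem.lumped_mass(basis))
    A = (K + props.kappa**2 * M).tocsr()
    b = np.zeros(basis.n_nodes)
    dn = sub_mesh.nodes_by_tag(BoundaryTag.GLYCOCALYX_WALL)
    A, b = fem.apply_dirichlet(A, b, dn, np.full(len(dn), zeta))
    phi_sub = fem.LUSolver(A).solve(b)
    if parent is None:
        phi = phi_sub
    else:
        phi = np.zeros(len(mesh.vertices))
        phi[parent] = phi_sub
    return PotentialField(mesh, phi, mode, zeta)


def charge_density(potential: PotentialField,
                   props: ElectroProperties) -> np.ndarray:
    """Nodal free charge density rho_f = -eps kappa^2 Phi (C/m^3)."""
    return -props.permittivity * props.kappa**2 * potential.phi


def electric_field(potential: PotentialField) -> np.ndarray:
    """Cellwise field E = -grad Phi (V/m); piecewise constant for P1."""
    basis = fem.P1Basis(potential.mesh)
    return -fem.cell_gradients(basis, potential.phi)


def electric_state(potential: PotentialField,
                   props: ElectroProperties) -> ElectricState:
    return ElectricState(potential.mesh, charge_density(potential, props),
                         electric_field(potential))


def analytic_plane_edl(half_width: float, zeta: float, debye_length: float,
                       n_points: int = 101):
    """Closed-form Debye-Hueckel potential in a plane channel (SI lengths).

    Phi(y) = zeta cosh(y/lambda_D) / cosh(h/lambda_D) on y in [-h, h],
    evaluated in an overflow-safe exponential-difference form.

    Returns (y, phi).
    """
    if half_width <= 0 or debye_length <= 0:
        raise ValueError("half_width and debye_length must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    y = np.linspace(-half_width, half_width, n_points)
    phi = zeta * edl_profile(y, half_width, debye_length)
    return y, phi


def edl_profile(y: np.ndarray, half_width: float,
                debye_length: float) -> np.ndarray:
    """cosh(kappa y)/cosh(kappa h) computed without overflow for kappa*h >> 1."""
    k = 1.0 / debye_length
    ay = np.abs(np.asarray(y, dtype=float))
    return (np.exp(k * (ay - half_width)) * (1 + np.exp(-2 * k * ay))
            / (1 + np.exp(-2 * k * half_width)))


def edl_osmotic_pressure(potential: PotentialField,
                         props: ElectroProperties) -> np.ndarray:
    """Nodal double-layer osmotic pressure chi = eps kappa^2 Phi^2 / 2 (Pa).

    Under the Debye-Hueckel closure the quiescent electric body force is the
    exact gradient rho_f E = grad(chi); chi is the excess osmotic pressure of
    the mobile counter-charge.  Open boundaries that cut through the double
    layer need chi in their normal-stress condition, otherwise the truncated
    layer acts as an artificial boundary pump.
    """
    return 0.5 * props.permittivity * props.kappa**2 * potential.phi**2


def helmholtz_smoluchowski_slip(zeta: float, props: ElectroProperties,
                                tangential_field: float,
                                viscosity: float) -> float:
    """Thin-double-layer electroosmotic slip  u = -eps zeta E_t / mu (m/s)."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    return -props.permittivity * zeta * tangential_field / viscosity


def poisson_residual(potential: PotentialField, rho_f: np.ndarray,
                     props: ElectroProperties) -> float:
    """Discrete dual-norm residual of lap(Phi) = -rho_f/eps on free fluid nodes.

    Zero (to solver precision) when rho_f comes from the Debye-Hueckel
    closure of the solved potential.
    """
    basis, parent = _fluid_basis(potential.mesh)
    if parent is None:
        phi, rho = potential.phi, rho_f
    else:
        phi, rho = potential.phi[parent], rho_f[parent]
    K = fem.stiffness(basis)
    M = sp.diags(fem.lumped_mass(basis))
    r = K @ phi - M @ (rho / props.permittivity)
    free = np.ones(basis.n_nodes, dtype=bool)
    free[basis.mesh.nodes_by_tag(BoundaryTag.GLYCOCALYX_WALL)] = False
    scale = max(np.abs(K @ phi)[free].max(), 1e-300)
    return float(np.abs(r[free]).max() / scale)
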