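"""Near-incompressible tissue elasticity: constitutive law and solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocuflow import fem
from ocuflow.geometry import (BoundaryTag, GeometryParams, Region,
                              build_outflow_domain, tissue_slab_mesh)
from ocuflow.mechanics import (SolidProperties, SolidSolver, lame_parameters,
                               max_shear, principal_values, solve_quasistatic,
                               strain_tensor, stress_decomposition)


# ---------------------------------------------------------------------------
# constitutive pieces
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("young,nu,lam,mu", [
    (1000.0, 0.0, 0.0, 500.0),
    (4e3, 0.495, 132.44e3, 1.3378e3),
    (7.48e3, 0.495, 247.67e3, 2.5017e3),
])
def test_lame_parameters(young, nu, lam, mu):
    l, m = lame_parameters(young, nu)
    assert l == pytest.approx(lam, rel=1e-4)
    assert m == pytest.approx(mu, rel=1e-4)


def test_lame_parameters_reject_incompressible_limit():
    for nu in (0.5, 0.6, -0.1):
        with pytest.raises(ValueError):
            lame_parameters(1e3, nu)
    with pytest.raises(ValueError):
        lame_parameters(-1.0, 0.3)


@given(young=st.floats(10.0, 1e6), nu=st.floats(0.0, 0.49))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_lame_roundtrip_through_compliance(young, nu):
    # invert the isotropic relations back to (E, nu)
    lam, mu = lame_parameters(young, nu)
    e_back = mu * (3 * lam + 2 * mu) / (lam + mu)
    nu_back = lam / (2 * (lam + mu))
    assert e_back == pytest.approx(young, rel=1e-10)
    assert nu_back == pytest.approx(nu, rel=1e-8, abs=1e-12)


def test_strain_tensor_elementary_fields():
    mesh = tissue_slab_mesh(2.0, 2.0, 4, 4)
    xy = mesh.vertices * 1e-6  # SI
    # rigid translation
    eps, e = strain_tensor(mesh, np.tile([1e-6, -2e-6], (len(xy), 1)))
    np.testing.assert_allclose(eps, 0.0, atol=1e-18)
    np.testing.assert_allclose(e, 0.0, atol=1e-18)
    # uniaxial stretch u = (a x, 0)
    a = 0.01
    eps, e = strain_tensor(mesh, np.column_stack([a * xy[:, 0],
                                                  np.zeros(len(xy))]))
    np.testing.assert_allclose(eps[:, 0], a, rtol=1e-12)
    np.testing.assert_allclose(eps[:, 1:], 0.0, atol=1e-14)
    np.testing.assert_allclose(e, a, rtol=1e-12)
    # infinitesimal rotation is strain-free
    th = 1e-3
    eps, e = strain_tensor(mesh, np.column_stack([-th * xy[:, 1],
                                                  th * xy[:, 0]]))
    np.testing.assert_allclose(eps, 0.0, atol=1e-15)


def test_stress_decomposition_cases():
    lam, mu = lame_parameters(4e3, 0.495)
    # zero strain, only interstitial pressure
    st_, si, tot = stress_decomposition(np.zeros((1, 3)), 0.0, 100.0, lam, mu)
    np.testing.assert_allclose(tot, [[-100.0, -100.0, 0.0]])
    # pure shear: sigma_xy = 2 mu eps_xy = mu gamma
    gamma = 0.02
    st_, si, tot = stress_decomposition(np.array([[0, 0, gamma / 2]]), 0.0,
                                        0.0, lam, mu)
    assert tot[0, 2] == pytest.approx(mu * gamma)
    # uniaxial strain: sigma_xx = (lam + 2 mu) e
    st_, si, tot = stress_decomposition(np.array([[0.01, 0, 0]]), 0.01, 0.0,
                                        lam, mu)
    assert st_[0, 0] == pytest.approx((lam + 2 * mu) * 0.01, rel=1e-12)
    assert st_[0, 0] == pytest.approx(1351.0, rel=1e-3)


def test_stress_decomposition_additive_and_isotropic():
    rng = np.random.default_rng(0)
    eps = rng.normal(size=(50, 3))
    e = eps[:, 0] + eps[:, 1]
    p = rng.normal(size=50)
    st_, si, tot = stress_decomposition(eps, e, p, 1e5, 1e3)
    np.testing.assert_array_equal(tot, st_ + si)
    np.testing.assert_array_equal(si[:, 0], si[:, 1])
    np.testing.assert_array_equal(si[:, 2], 0.0)


# ---------------------------------------------------------------------------
# principal values and max shear
# ---------------------------------------------------------------------------

def test_principal_values_examples():
    np.testing.assert_allclose(
        principal_values(np.array([[3.0, 2.0, 0.0]]), zz=1.0), [[3, 2, 1]])
    # antidiagonal [[0, 1], [1, 0]] has the eigenpair (1, -1)
    pv = principal_values(np.array([[[0.0, 1.0], [1.0, 0.0]]]))
    np.testing.assert_allclose(pv, [[1.0, 0.0, -1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        principal_values(np.array([[[0.0, 1.0], [0.5, 0.0]]]))


@given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=4))
@settings(max_examples=80, deadline=None, derandomize=True)
def test_principal_values_match_eigensolver(vals):
    sxx, syy, sxy, szz = vals
    pv = principal_values(np.array([[sxx, syy, sxy]]), zz=szz)[0]
    full = np.diag([0.0, 0.0, szz])
    full[0, 0], full[1, 1] = sxx, syy
    full[0, 1] = full[1, 0] = sxy
    expected = np.sort(np.linalg.eigvalsh(full))[::-1]
    scale = max(1.0, np.abs(vals).max())
    np.testing.assert_allclose(pv, expected, atol=1e-12 * scale)


def test_max_shear_examples():
    # hydrostatic state has no shear on any plane
    assert max_shear(np.array([[-5.0, -5.0, 0.0]]), zz=-5.0)[0] == 0.0
    assert max_shear(np.array([[3.0, 2.0, 0.0]]), zz=1.0)[0] == 1.0
    tau = 7.0
    assert max_shear(np.array([[0.0, 0.0, tau]]), zz=0.0)[0] == \
        pytest.approx(tau)


# ---------------------------------------------------------------------------
# quasi-static solver
# ---------------------------------------------------------------------------

def _slab_under_pressure(nu, n=8, p=100.0, height=10.0):
    mesh = tissue_slab_mesh(10.0, height, n, n)
    props = SolidProperties(poisson_ratio=nu, pretension=0.0)
    idx = mesh.facet_index(BoundaryTag.GLYCOCALYX_WALL)
    w = fem.boundary_lumped_loads(mesh, idx)
    forces = np.zeros((len(mesh.vertices), 2))
    forces[:, 1] = -p * w
    state = solve_quasistatic(mesh, props, interface_forces=forces,
                              pretension=0.0)
    lam, mu = lame_parameters(4e3, nu)
    exact = -p * height * 1e-6 / (lam + 2 * mu)
    top = mesh.vertices[:, 1] > height - 1e-9
    return state, float(state.displacement[top, 1].mean()), exact


def test_zero_load_zero_displacement():
    mesh = tissue_slab_mesh(4.0, 4.0, 4, 4)
    state = solve_quasistatic(mesh, SolidProperties(), pretension=0.0)
    assert np.abs(state.displacement).max() == 0.0


@pytest.mark.parametrize("nu", [0.3, 0.495])
def test_confined_slab_matches_plane_strain_closed_form(nu):
    state, uy, exact = _slab_under_pressure(nu)
    assert uy == pytest.approx(exact, rel=1e-2)
    # the uniform stress state is reproduced through the whole slab
    np.testing.assert_allclose(state.sigma_t[:, 1], -100.0, rtol=1e-9)


def test_mixed_formulation_is_locking_free():
    # the error at nu = 0.495 must not blow up relative to nu = 0.3
    _, uy3, ex3 = _slab_under_pressure(0.3)
    _, uy495, ex495 = _slab_under_pressure(0.495)
    err3 = abs(uy3 - ex3) / abs(ex3)
    err495 = abs(uy495 - ex495) / abs(ex495)
    assert err495 <= 2 * err3 + 1e-10


def test_pretension_reactions_balance(default_mesh):
    tissue, _ = default_mesh.submesh(~default_mesh.is_fluid_cell())
    props = SolidProperties()
    solver = SolidSolver(tissue, props)
    u, ps, reactions = solver.solve(return_reactions=True)
    total = props.pretension / props.out_of_plane_depth
    assert reactions[:, 0].sum() == pytest.approx(total, rel=1e-8)
    assert len(solver.pretension_facets) > 0


def test_energy_consistency(default_mesh):
    tissue, _ = default_mesh.submesh(~default_mesh.is_fluid_cell())
    solver = SolidSolver(tissue, SolidProperties())
    u, ps, x, b0 = solver.solve(return_system=True)
    work, stored = solver.energy_balance(x, b0)
    assert stored == pytest.approx(work, rel=1e-6)


def test_solver_requires_anchors_and_tissue_cells():
    mesh = tissue_slab_mesh(4.0, 4.0, 2, 2)
    mesh.facet_tags[mesh.facet_tags == int(BoundaryTag.ANCHOR)] = \
        int(BoundaryTag.SYMMETRY)
    with pytest.raises(ValueError, match="singular|anchor"):
        SolidSolver(mesh, SolidProperties())
    fluid_mesh = build_outflow_domain(
        GeometryParams(tm_depth=30.0, channel_length=8.0, channel_height=4.0,
                       tissue_band=4.0), 1.0)
    fluid_sub, _ = fluid_mesh.submesh(fluid_mesh.is_fluid_cell())
    with pytest.raises(ValueError, match="tissue"):
        SolidSolver(fluid_sub, SolidProperties())


def test_region_moduli_enter_stress(small_mesh):
    tissue, _ = small_mesh.submesh(~small_mesh.is_fluid_cell())
    props = SolidProperties()
    lam, mu = props.lame_arrays(tissue.region)
    l_tm, m_tm = lame_parameters(4e3, 0.495)
    l_sc, m_sc = lame_parameters(7.48e3, 0.495)
    assert np.all(mu[tissue.region == int(Region.TM)] == m_tm)
    assert np.all(mu[tissue.region == int(Region.SC_WALL)] == m_sc)
    assert np.all(lam[tissue.region == int(Region.JCT)] == l_tm)
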