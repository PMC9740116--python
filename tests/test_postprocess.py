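"""Summaries, streamlines, and field export round trips."""

import numpy as np
import pytest

from ocuflow.fluid import FlowState, LoadSchedule
from ocuflow.geometry import Region, plane_channel_mesh, tissue_slab_mesh
from ocuflow.io import export_fields, load_bundle, read_vtk, save_bundle, write_vtk
from ocuflow.mechanics import MechanicalState
from ocuflow.pipeline import ResultsBundle
from ocuflow.postprocess import (inlet_seed_line, streamlines, summarize,
                                 summary_table)


def _synthetic_bundle(u_const=(2e-6, 0.0), n_steps=4):
    """Hand-built bundle with constant fields (synthetic, not a solver run)."""
    fmesh = plane_channel_mesh(10.0, 2.0, nx=5, ny=4)
    n_f = len(fmesh.vertices)
    flow = FlowState(fmesh, np.tile([1e-3, 0.0], (n_f, 1)),
                     np.full(n_f, 50.0), 1.0)
    tmesh = tissue_slab_mesh(10.0, 4.0, 5, 4, region=Region.TM)
    n_t, m_t = len(tmesh.vertices), len(tmesh.cells)
    disp = np.tile(u_const, (n_t, 1))
    mech = MechanicalState(
        mesh=tmesh, displacement=disp, tissue_velocity=np.zeros((n_t, 2)),
        strain=np.zeros((m_t, 3)), e=np.zeros(m_t),
        sigma_t=np.zeros((m_t, 3)), sigma_i=np.zeros((m_t, 3)),
        sigma_total=np.tile([200.0, 100.0, 0.0], (m_t, 1)),
        sigma_zz=np.zeros(m_t), p_interstitial=np.zeros(n_t))
    series = {k: np.linspace(0.1, 1.0, n_steps) for k in (
        "max_velocity_mm_s", "max_pressure_mmhg", "max_principal_stress_kpa",
        "max_principal_strain_pct", "max_shear_stress_kpa",
        "max_shear_strain_pct", "tm_displacement_um", "net_flux",
        "gross_flux")}
    return ResultsBundle(
        name="synthetic", series=series,
        schedule=LoadSchedule(15.0, 1.0, 1.0 / n_steps),
        mesh_digest="e" * 16, config_digest="c" * 16,
        final_flow=flow, final_mech=mech, provenance={"synthetic": True})


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_summarize_constant_displacement_gives_its_magnitude():
    bundle = _synthetic_bundle(u_const=(3e-6, 4e-6))
    row = summarize(bundle, region=Region.TM)
    assert row["tm_displacement_um"] == pytest.approx(5.0)  # |(3,4)| um
    assert row["max_velocity_mm_s"] == pytest.approx(1.0)
    assert row["max_pressure_mmhg"] == pytest.approx(50.0 / 133.322)
    assert row["max_principal_stress_kpa"] == pytest.approx(0.2)
    # plane-strain shear from the (200, 100, 0; zz=0) state: (200-0)/2 Pa
    assert row["max_shear_stress_kpa"] == pytest.approx(0.1)


def test_summarize_zero_bundle_is_zero():
    bundle = _synthetic_bundle(u_const=(0.0, 0.0))
    bundle.final_flow.u[:] = 0.0
    bundle.final_flow.p[:] = 0.0
    bundle.final_mech.sigma_total[:] = 0.0
    row = summarize(bundle)
    for key in ("max_velocity_mm_s", "max_pressure_mmhg",
                "max_principal_stress_kpa", "tm_displacement_um"):
        assert row[key] == 0.0


def test_summarize_rejects_empty_region():
    bundle = _synthetic_bundle()
    with pytest.raises(ValueError, match="empty"):
        summarize(bundle, region=Region.JCT)  # slab is all TM


def test_summarize_invariant_under_cell_storage_order():
    bundle = _synthetic_bundle(u_const=(1e-6, 1e-6))
    row0 = summarize(bundle)
    perm = np.random.default_rng(1).permutation(len(bundle.final_mech.mesh.cells))
    m = bundle.final_mech
    m.mesh.cells = m.mesh.cells[perm]
    m.mesh.region = m.mesh.region[perm]
    for name in ("strain", "sigma_t", "sigma_i", "sigma_total"):
        setattr(m, name, getattr(m, name)[perm])
    m.sigma_zz = m.sigma_zz[perm]
    m.e = m.e[perm]
    row1 = summarize(bundle)
    for k, v in row0.items():
        if isinstance(v, float):
            assert row1[k] == pytest.approx(v, rel=1e-12)


def test_summary_table_has_one_row_per_scenario():
    bundles = [_synthetic_bundle(), _synthetic_bundle()]
    bundles[1].name = "other"
    table = summary_table(bundles)
    assert list(table.index) == ["synthetic", "other"]
    assert "max_velocity_mm_s" in table.columns


def test_volume_weighted_average_equals_unweighted_for_constant_field():
    bundle = _synthetic_bundle(u_const=(2e-6, 0.0))
    a = summarize(bundle, volume_weighted=False)["tm_displacement_um"]
    b = summarize(bundle, volume_weighted=True)["tm_displacement_um"]
    assert a == pytest.approx(b, rel=1e-12)


# ---------------------------------------------------------------------------
# streamlines
# ---------------------------------------------------------------------------

def test_streamlines_uniform_flow_are_straight():
    mesh = plane_channel_mesh(20.0, 2.0, nx=20, ny=8)
    n = len(mesh.vertices)
    flow = FlowState(mesh, np.tile([1e-3, 0.0], (n, 1)), np.zeros(n))
    lines = streamlines(flow, np.array([[1.0, 0.5]]), step=0.5)
    pts = lines.points[0]
    np.testing.assert_allclose(pts[:, 1], 0.5, atol=1e-12)
    assert pts[-1, 0] > 18.0
    np.testing.assert_allclose(lines.speeds[0], 1.0)  # mm/s


def test_streamlines_zero_flow_degenerates_to_seed():
    mesh = plane_channel_mesh(10.0, 2.0, nx=5, ny=4)
    n = len(mesh.vertices)
    flow = FlowState(mesh, np.zeros((n, 2)), np.zeros(n))
    lines = streamlines(flow, np.array([[2.0, 0.0]]), step=0.5)
    assert len(lines.points[0]) == 1
    np.testing.assert_allclose(lines.points[0][0], [2.0, 0.0])


def test_streamlines_skip_seeds_outside_fluid():
    mesh = plane_channel_mesh(10.0, 2.0, nx=5, ny=4)
    n = len(mesh.vertices)
    flow = FlowState(mesh, np.ones((n, 2)), np.zeros(n))
    lines = streamlines(flow, np.array([[50.0, 50.0]]), step=0.5)
    assert len(lines.points[0]) == 0


def test_streamlines_follow_poiseuille_without_transverse_drift():
    # analytic parabolic field: streamlines must stay parallel to the walls
    mesh = plane_channel_mesh(20.0, 2.0, nx=40, ny=16)
    y = mesh.vertices[:, 1]
    u = np.column_stack([1e-3 * (4.0 - y**2), np.zeros(len(y))])
    state = FlowState(mesh, u, np.zeros(len(y)))
    lines = streamlines(state, np.array([[0.5, 0.7], [0.5, -1.1]]), step=0.2)
    for pts in lines.points:
        drift = np.abs(pts[:, 1] - pts[0, 1]).max()
        assert drift < 1e-9  # um, integration tolerance


def test_streamline_step_refinement_first_order():
    mesh = plane_channel_mesh(20.0, 2.0, nx=20, ny=8)
    n = len(mesh.vertices)
    u = np.column_stack([np.full(n, 1e-3),
                         1e-4 * np.sin(mesh.vertices[:, 0] / 3.0)])
    flow = FlowState(mesh, u, np.zeros(n))

    def endpoint(step):
        line = streamlines(flow, np.array([[0.5, 0.0]]), step=step,
                           max_steps=int(40 / step))
        return line.points[0][-1]

    e1 = np.linalg.norm(endpoint(0.4) - endpoint(0.1))
    e2 = np.linalg.norm(endpoint(0.2) - endpoint(0.1))
    assert e2 <= e1 + 1e-12


def test_inlet_seed_line_spans_inlet():
    mesh = plane_channel_mesh(10.0, 2.0, nx=5, ny=8)
    seeds = inlet_seed_line(mesh, n=6)
    assert seeds.shape == (6, 2)
    assert np.all(np.abs(seeds[:, 1]) < 2.0)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def test_bundle_h5_roundtrip_is_lossless(tmp_path):
    bundle = _synthetic_bundle()
    path = tmp_path / "b.h5"
    save_bundle(bundle, path)
    back = load_bundle(path)
    assert back.name == bundle.name
    assert back.schedule == bundle.schedule
    for k in bundle.series:
        np.testing.assert_array_equal(back.series[k], bundle.series[k])
    np.testing.assert_array_equal(back.final_flow.u, bundle.final_flow.u)
    np.testing.assert_array_equal(back.final_mech.sigma_total,
                                  bundle.final_mech.sigma_total)
    assert back.digest() == bundle.digest()


def test_vtk_roundtrip_and_field_names(tmp_path):
    mesh = plane_channel_mesh(10.0, 2.0, nx=4, ny=3)
    n, m = len(mesh.vertices), len(mesh.cells)
    rng = np.random.default_rng(0)
    pdata = {"pressure": rng.normal(size=n), "velocity": rng.normal(size=(n, 2))}
    cdata = {"region": mesh.region.astype(float)}
    path = tmp_path / "f.vtk"
    write_vtk(path, mesh, pdata, cdata)
    pts, cells, pd, cd = read_vtk(path)
    np.testing.assert_array_equal(cells, mesh.cells)
    np.testing.assert_allclose(pts[:, :2], mesh.vertices)
    assert set(pd) == {"pressure", "velocity"}
    assert set(cd) == {"region"}
    np.testing.assert_array_equal(pd["pressure"], pdata["pressure"])
    np.testing.assert_array_equal(pd["velocity"][:, :2], pdata["velocity"])


def test_export_fields_formats(tmp_path):
    bundle = _synthetic_bundle()
    vtk_files = export_fields(bundle, tmp_path / "out", fmt="vtk")
    assert len(vtk_files) == 2  # fluid + tissue grids
    for f in vtk_files:
        pts, cells, pd, cd = read_vtk(f)
        assert len(pts) > 0 and len(pd) > 0
    xdmf_files = export_fields(bundle, tmp_path / "out", fmt="xdmf")
    assert any(str(f).endswith(".xdmf") for f in xdmf_files)
    csv_files = export_fields(bundle, tmp_path / "out", fmt="csv")
    import pandas as pd_mod

    df = pd_mod.read_csv(csv_files[0])
    assert len(df) == bundle.n_steps
    assert "max_velocity_mm_s" in df.columns
    with pytest.raises(ValueError, match="unsupported"):
        export_fields(bundle, tmp_path / "out", fmt="npz")
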