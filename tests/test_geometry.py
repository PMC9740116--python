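"""Synthetic outflow geometry: pore layouts, tagged meshes, refinement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocuflow.geometry import (BoundaryTag, GeometryParams, Region,
                              build_outflow_domain, graded_breaks,
                              mesh_quality, place_inner_wall_pores,
                              plane_channel_mesh, pore_count,
                              refine_near_wall, tissue_slab_mesh,
                              wall_normal_sizes)


# ---------------------------------------------------------------------------
# pore layouts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("density,patch,expected", [
    (835.0, (1.0, 1.0), 835),      # printed inner-wall density on 1 mm^2
    (835.0, (0.1, 0.1), 8),        # round(835 * 0.01)
    (500.0, (0.0, 0.0), 0),        # zero patch area
])
def test_grid_pore_count(density, patch, expected):
    layout = place_inner_wall_pores(density, 1.3, patch, mode="grid")
    assert layout.count == expected


@given(density=st.floats(1.0, 5000.0), w=st.floats(0.01, 2.0),
       h=st.floats(0.01, 2.0))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_grid_pore_count_matches_closed_form(density, w, h):
    try:
        layout = place_inner_wall_pores(density, 1e-3, (w, h), mode="grid")
    except ValueError:
        return  # overlap-infeasible combinations are rejected, not mis-counted
    assert layout.count == pore_count(density, (w, h))
    assert layout.count == int(round(density * w * h))


def test_pores_inside_patch_and_non_overlapping():
    layout = place_inner_wall_pores(835.0, 1.3, (0.3, 0.3), mode="jittered",
                                    seed=7)
    w_um, h_um = 300.0, 300.0
    r = layout.diameter / 2
    assert np.all(layout.centers[:, 0] >= r - 1e-9)
    assert np.all(layout.centers[:, 0] <= w_um - r + 1e-9)
    assert np.all(layout.centers[:, 1] >= r - 1e-9)
    assert np.all(layout.centers[:, 1] <= h_um - r + 1e-9)
    from scipy.spatial.distance import pdist

    assert pdist(layout.centers).min() >= layout.diameter


def test_jitter_is_seed_reproducible():
    a = place_inner_wall_pores(835.0, 1.3, (0.2, 0.2), "jittered", seed=3)
    b = place_inner_wall_pores(835.0, 1.3, (0.2, 0.2), "jittered", seed=3)
    c = place_inner_wall_pores(835.0, 1.3, (0.2, 0.2), "jittered", seed=4)
    np.testing.assert_array_equal(a.centers, b.centers)
    assert not np.array_equal(a.centers, c.centers)


def test_jitter_requires_seed_and_overlap_rejected():
    with pytest.raises(ValueError, match="seed"):
        place_inner_wall_pores(835.0, 1.3, (1.0, 1.0), "jittered")
    with pytest.raises(ValueError, match="overlap"):
        # pitch at this density is ~34.6 um < requested 50 um diameter
        place_inner_wall_pores(835.0, 50.0, (1.0, 1.0), "grid")


# ---------------------------------------------------------------------------
# outflow domain
# ---------------------------------------------------------------------------

def test_outflow_regions_partition_domain(small_mesh, small_geometry):
    areas = np.abs(small_mesh.cell_areas())
    total = small_geometry.total_length * small_geometry.total_height
    by_region = {r: areas[small_mesh.region == int(r)].sum() for r in Region}
    assert sum(by_region.values()) == pytest.approx(total, rel=1e-12)
    assert all(by_region[r] > 0 for r in Region)


def test_outflow_boundary_fully_tagged(small_mesh):
    # every edge used by exactly one cell must appear among tagged facets
    edges = {}
    for tri in small_mesh.cells:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
    boundary = {k for k, cnt in edges.items() if cnt == 1}
    tagged = {(min(a, b), max(a, b)) for a, b in small_mesh.facets}
    assert boundary <= tagged


def test_outflow_interface_separates_fluid_and_tissue(small_mesh):
    idx = small_mesh.facet_index(BoundaryTag.GLYCOCALYX_WALL)
    interior = small_mesh.facet_cells[idx]
    interior = interior[interior[:, 1] >= 0]
    r0 = small_mesh.region[interior[:, 0]]
    r1 = small_mesh.region[interior[:, 1]]
    assert np.all((r0 == int(Region.FLUID)) != (r1 == int(Region.FLUID)))
    # orientation contract: the first adjacent cell is the fluid one
    assert np.all(r0 == int(Region.FLUID))


def test_zero_pore_density_closes_the_outlet():
    params = GeometryParams(pore_density=0.0, tm_depth=30.0,
                            channel_length=8.0, channel_height=4.0,
                            tissue_band=4.0)
    mesh = build_outflow_domain(params, resolution=1.0)
    assert len(mesh.facet_index(BoundaryTag.OUTLET_OPEN)) == 0


def test_pore_gap_spacing_follows_inverse_root_density():
    # tall channel so that several gaps fit: spacing = 1/sqrt(835) mm
    params = GeometryParams(channel_height=120.0, tissue_band=10.0,
                            tm_depth=30.0, channel_length=8.0)
    mesh = build_outflow_domain(params, resolution=1.0)
    out_nodes = mesh.nodes_by_tag(BoundaryTag.OUTLET_OPEN)
    ys = np.sort(mesh.vertices[out_nodes, 1])
    gaps = np.split(ys, np.nonzero(np.diff(ys) > 2.0)[0] + 1)
    centers = np.array([g.mean() for g in gaps])
    expected = 1e3 / math.sqrt(835.0)
    assert len(centers) == 3
    np.testing.assert_allclose(np.diff(centers), expected, rtol=1e-9)
    # every gap is one pore diameter wide
    for g in gaps:
        assert g.max() - g.min() == pytest.approx(1.3, rel=1e-9)


@pytest.mark.parametrize("kwargs,match", [
    (dict(resolution=3.0), "too coarse"),
    (dict(resolution=0.49, params=dict(sc_wall_thickness=0.2)), "SC inner wall"),
])
def test_domain_resolution_rejections(kwargs, match):
    params = GeometryParams(tm_depth=30.0, channel_length=8.0,
                            channel_height=4.0, tissue_band=4.0,
                            **kwargs.get("params", {}))
    with pytest.raises(ValueError, match=match):
        build_outflow_domain(params, kwargs.get("resolution", 1.0))


def test_gap_wider_than_channel_rejected():
    params = GeometryParams(channel_height=1.2, tissue_band=4.0,
                            tm_depth=30.0, channel_length=8.0,
                            glycocalyx_thickness=109.0)
    with pytest.raises(ValueError, match="wider"):
        build_outflow_domain(params, resolution=0.3)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        GeometryParams(jct_thickness=-1.0)
    with pytest.raises(ValueError):
        GeometryParams(pore_diameter=40.0)  # exceeds mean pore spacing
    with pytest.raises(ValueError):
        GeometryParams(dimensionality="4d")


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def test_refine_near_wall_reaches_target_and_keeps_tags():
    mesh = plane_channel_mesh(8.0, 2.0, nx=4, ny=8)
    refined = refine_near_wall(mesh, layer_scale=109.0, growth=1.3)
    sizes = wall_normal_sizes(refined)
    assert sizes.max() <= 109e-3 / 3 + 1e-9   # 36.4 nm in um
    assert set(refined.facet_tags) == set(mesh.facet_tags)


def test_refine_near_wall_noop_when_already_fine():
    mesh = plane_channel_mesh(8.0, 2.0, nx=4, ny=8)  # wall cells 0.5 um
    refined = refine_near_wall(mesh, layer_scale=3 * 0.5e3, growth=1.0)
    assert len(refined.vertices) == len(mesh.vertices)
    np.testing.assert_array_equal(refined.cells, mesh.cells)


def test_refine_near_wall_budget():
    mesh = plane_channel_mesh(8.0, 2.0, nx=4, ny=8)
    with pytest.raises(ValueError, match="budget"):
        refine_near_wall(mesh, layer_scale=0.5, growth=1.0, max_cells=5000)


def test_refine_outflow_mesh_preserves_region_areas(small_mesh):
    refined = refine_near_wall(small_mesh, layer_scale=2000.0, growth=1.5)
    for r in Region:
        a0 = np.abs(small_mesh.cell_areas())[small_mesh.region == int(r)].sum()
        a1 = np.abs(refined.cell_areas())[refined.region == int(r)].sum()
        assert a1 == pytest.approx(a0, rel=1e-9)


# ---------------------------------------------------------------------------
# quality
# ---------------------------------------------------------------------------

def test_quality_unit_square():
    mesh = tissue_slab_mesh(1.0, 1.0, 1, 1)
    q = mesh_quality(mesh)
    assert q.n_cells == 2
    assert q.n_inverted == 0
    assert q.total_area == pytest.approx(1.0)
    assert q.max_aspect == pytest.approx(1.0)


def test_quality_uniform_grid_aspect_one():
    mesh = plane_channel_mesh(4.0, 2.0, nx=8, ny=8)
    q = mesh_quality(mesh)
    assert q.max_aspect == pytest.approx(1.0)


def test_quality_min_size_matches_bruteforce(small_mesh):
    q = mesh_quality(small_mesh)
    # independent exhaustive scan of the shortest edge of every cell
    best = np.inf
    for tri in small_mesh.cells:
        p = small_mesh.vertices[tri]
        for i, j in ((0, 1), (1, 2), (2, 0)):
            best = min(best, float(np.hypot(*(p[i] - p[j]))))
    assert q.min_size == pytest.approx(best, rel=1e-14)


def test_quality_flags_inverted_cell():
    mesh = tissue_slab_mesh(2.0, 2.0, 2, 2)
    mesh.cells[0] = mesh.cells[0][[1, 0, 2]]  # flip orientation
    q = mesh_quality(mesh)
    assert q.n_inverted == 1
    assert 0 in q.inverted_cells
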