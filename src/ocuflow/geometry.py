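"""Synthetic geometry for the conventional aqueous outflow pathway.

The eye-specific imaged TM/JCT/SC mesh used in the source study is not
available, so this module generates an idealized, layered stand-in: a 2D
slice in which aqueous humor enters an anterior-chamber vestibule, passes
along a narrow channel bounded by elastic trabecular-meshwork (TM) and
juxtacanalicular (JCT) tissue, and exits through micron-scale pore gaps in
the Schlemm's-canal (SC) inner wall.  The trabecular region is represented
as a homogeneous permeable channel bounded by elastic tissue rather than as
resolved beams.

Layout (plane-2D, lengths in micrometres, flow axis = +x)::

      y=Ly +--------------------------------------------+
           |          tissue band (TM | JCT)        |SC |
           |  inlet  +--------------------------+   |   |
           | chamber |      fluid channel       |gap-> out
           |         +--------------------------+   |   |
           |          tissue band (TM | JCT)        |SC |
       y=0 +--------------------------------------------+
           x=0      x=channel_length            x=Lx-sc  x=Lx

All meshes are conforming structured triangulations whose grid lines are
snapped to every material interface; region labels and boundary tags are
derived from cell/facet positions so that refinement preserves them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable

import numpy as np

__all__ = [
    "Region",
    "BoundaryTag",
    "GeometryParams",
    "PoreLayout",
    "TaggedMesh",
    "QualityReport",
    "build_outflow_domain",
    "place_inner_wall_pores",
    "refine_near_wall",
    "mesh_quality",
    "plane_channel_mesh",
    "graded_breaks",
]

_SNAP = 1e-9  # coordinate comparison tolerance, um


class Region(IntEnum):
    """Material label carried per cell."""

    FLUID = 0
    TM = 1
    JCT = 2
    SC_WALL = 3


TISSUE_REGIONS = (Region.TM, Region.JCT, Region.SC_WALL)


class BoundaryTag(IntEnum):
    """Facet label. GLYCOCALYX_WALL marks every tissue-fluid interface."""

    INLET = 0
    OUTLET_OPEN = 1
    GLYCOCALYX_WALL = 2
    SYMMETRY = 3
    ANCHOR = 4


@dataclass(frozen=True)
class GeometryParams:
    """Idealized outflow-domain dimensions.

    Lengths in micrometres except ``glycocalyx_thickness`` (nanometres) and
    ``pore_density`` (pores per mm^2 of inner wall, mapped in 2D to a wall-gap
    spacing of ``1/sqrt(density)``).
    """

    tm_depth: float = 120.0
    jct_thickness: float = 14.0
    sc_wall_thickness: float = 2.2
    pore_density: float = 835.0
    pore_diameter: float = 1.3
    glycocalyx_thickness: float = 109.0  # nm
    channel_height: float = 2.0
    channel_length: float = 20.0
    tissue_band: float = 8.0
    dimensionality: str = "plane-2d"

    def __post_init__(self) -> None:
        for name in ("tm_depth", "jct_thickness", "sc_wall_thickness",
                     "pore_diameter", "glycocalyx_thickness",
                     "channel_height", "channel_length", "tissue_band"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pore_density < 0:
            raise ValueError("pore_density must be non-negative")
        if self.dimensionality not in ("plane-2d", "slab-3d"):
            raise ValueError("dimensionality must be 'plane-2d' or 'slab-3d'")
        if self.pore_density > 0:
            spacing = self.pore_spacing
            if self.pore_diameter >= spacing:
                raise ValueError(
                    f"pore_diameter {self.pore_diameter} um exceeds the mean "
                    f"spacing 1/sqrt(density) = {spacing:.3g} um")
        if self.glycocalyx_thickness * 1e-3 >= self.channel_height / 4:
            raise ValueError("glycocalyx layer must be thin relative to the channel")

    @property
    def pore_spacing(self) -> float:
        """Mean inner-wall pore spacing 1/sqrt(density), in um."""
        return 1e3 / math.sqrt(self.pore_density)

    @property
    def total_length(self) -> float:
        return (self.channel_length + self.tm_depth + self.jct_thickness
                + self.sc_wall_thickness)

    @property
    def total_height(self) -> float:
        return self.channel_height + 2 * self.tissue_band


@dataclass(frozen=True)
class PoreLayout:
    """Planar layout of SC inner-wall pores on a rectangular patch.

    ``centers`` are in micrometres; ``patch_dims`` in millimetres.
    """

    centers: np.ndarray  # (n, 2) um
    diameter: float  # um
    patch_dims: tuple[float, float]  # mm
    mode: str
    seed: int | None = None

    @property
    def count(self) -> int:
        return len(self.centers)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "x_um": self.centers[:, 0],
            "y_um": self.centers[:, 1],
            "diameter_um": np.full(self.count, self.diameter),
        }).to_csv(path, index=False)


@dataclass
class TaggedMesh:
    """Conforming triangle mesh with per-cell regions and tagged facets.

    ``facets`` holds every domain-boundary facet plus every internal
    fluid-tissue interface facet; ``facet_cells`` stores the adjacent cell
    indices (second entry -1 on the boundary).  ``grid`` carries the
    structured-generator metadata needed for tag-preserving refinement.
    """

    vertices: np.ndarray          # (n, 2) um
    cells: np.ndarray             # (m, 3) int
    region: np.ndarray            # (m,) int (Region)
    facets: np.ndarray            # (f, 2) int
    facet_tags: np.ndarray        # (f,) int (BoundaryTag)
    facet_cells: np.ndarray       # (f, 2) int, -1 = outside
    grid: dict | None = field(default=None, repr=False)

    # -- queries ---------------------------------------------------------
    def facet_index(self, tag: BoundaryTag) -> np.ndarray:
        return np.nonzero(self.facet_tags == int(tag))[0]

    def facets_by_tag(self, tag: BoundaryTag) -> np.ndarray:
        return self.facets[self.facet_tags == int(tag)]

    def nodes_by_tag(self, *tags: BoundaryTag) -> np.ndarray:
        sel = np.isin(self.facet_tags, [int(t) for t in tags])
        return np.unique(self.facets[sel])

    def cell_centroids(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    def cell_areas(self) -> np.ndarray:
        p = self.vertices[self.cells]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def facet_lengths(self, idx=None) -> np.ndarray:
        f = self.facets if idx is None else self.facets[idx]
        d = self.vertices[f[:, 1]] - self.vertices[f[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    def facet_outward_normals(self, idx) -> np.ndarray:
        """Unit normals pointing away from the first adjacent cell."""
        f = self.facets[idx]
        d = self.vertices[f[:, 1]] - self.vertices[f[:, 0]]
        n = np.column_stack([d[:, 1], -d[:, 0]])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        cent = self.cell_centroids()[self.facet_cells[idx, 0]]
        mid = 0.5 * (self.vertices[f[:, 0]] + self.vertices[f[:, 1]])
        flip = np.einsum("ij,ij->i", n, mid - cent) < 0
        n[flip] *= -1.0
        return n

    def is_fluid_cell(self) -> np.ndarray:
        return self.region == int(Region.FLUID)

    # -- submesh extraction ---------------------------------------------
    def submesh(self, cell_mask: np.ndarray) -> tuple["TaggedMesh", np.ndarray]:
        """Extract the cells where ``cell_mask`` is True.

        Returns the submesh and the parent index of each submesh vertex.
        Facet tags are inherited; interface facets become boundary facets of
        the submesh and keep their GLYCOCALYX_WALL tag.
        """
        cells = self.cells[cell_mask]
        used = np.unique(cells)
        new_id = -np.ones(len(self.vertices), dtype=np.int64)
        new_id[used] = np.arange(len(used))
        sub_cells = new_id[cells]
        tag_of = {}
        for (a, b), t in zip(self.facets, self.facet_tags):
            tag_of[(min(a, b), max(a, b))] = int(t)
        facets, tags, fcells = _extract_facets(
            sub_cells, lambda pair, cells_pair: tag_of.get(pair, -1),
            parent_nodes=used)
        keep = tags >= 0
        sub = TaggedMesh(self.vertices[used].copy(), sub_cells,
                         self.region[cell_mask].copy(),
                         facets[keep], tags[keep], fcells[keep], grid=None)
        return sub, used


@dataclass(frozen=True)
class QualityReport:
    """Summary statistics of a mesh (sizes in um)."""

    n_vertices: int
    n_cells: int
    n_tagged_facets: int
    min_size: float        # smallest shortest-edge over cells
    max_size: float        # largest longest-edge over cells
    max_aspect: float      # bounding-box aspect ratio, 1 = square cell
    total_area: float
    n_inverted: int
    inverted_cells: np.ndarray


# ---------------------------------------------------------------------------
# structured grid machinery
# ---------------------------------------------------------------------------

def _subdivide(breaks: np.ndarray, resolution: float) -> np.ndarray:
    """Insert uniform points so every interval is at most ``resolution`` wide."""
    out = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(math.ceil((b - a) / resolution - 1e-9)))
        out.extend(a + (b - a) * (np.arange(1, n + 1) / n))
    return np.asarray(out)


def _dedupe(vals) -> np.ndarray:
    v = np.sort(np.asarray(vals, dtype=float))
    keep = np.concatenate([[True], np.diff(v) > _SNAP])
    return v[keep]


def _extract_facets(cells: np.ndarray, tagger, parent_nodes=None):
    """Collect facets adjacent to exactly one cell or tagged internal ones.

    ``tagger(pair, (c0, c1))`` returns the tag int or -1 for untagged; for
    submesh extraction ``parent_nodes`` maps local nodes to parent ids so the
    parent's tag table can be consulted.
    """
    edges = {}
    for ci, tri in enumerate(cells):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edges.setdefault(key, []).append(ci)
    facets, tags, fcells = [], [], []
    for (a, b), adj in edges.items():
        if parent_nodes is not None:
            pa, pb = parent_nodes[a], parent_nodes[b]
            key = (min(pa, pb), max(pa, pb))
        else:
            key = (a, b)
        c1 = adj[1] if len(adj) > 1 else -1
        t = tagger(key, (adj[0], c1))
        if len(adj) == 1 and t < 0:
            raise ValueError("untagged boundary facet encountered")
        if t >= 0:
            facets.append((a, b))
            tags.append(t)
            fcells.append((adj[0], c1))
    return (np.asarray(facets, dtype=np.int64).reshape(-1, 2),
            np.asarray(tags, dtype=np.int64),
            np.asarray(fcells, dtype=np.int64).reshape(-1, 2))


def _structured_mesh(x_lines: np.ndarray, y_lines: np.ndarray,
                     region_at: Callable[[float, float], int],
                     boundary_tag_at: Callable[[float, float, int], int],
                     grid_meta: dict | None) -> TaggedMesh:
    nx, ny = len(x_lines), len(y_lines)
    X, Y = np.meshgrid(x_lines, y_lines, indexing="xy")
    vertices = np.column_stack([X.ravel(), Y.ravel()])

    def nid(ix, iy):
        return iy * nx + ix

    cells, region = [], []
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            n00, n10 = nid(ix, iy), nid(ix + 1, iy)
            n01, n11 = nid(ix, iy + 1), nid(ix + 1, iy + 1)
            cx = 0.5 * (x_lines[ix] + x_lines[ix + 1])
            cy = 0.5 * (y_lines[iy] + y_lines[iy + 1])
            r = region_at(cx, cy)
            cells.append((n00, n10, n11))
            cells.append((n00, n11, n01))
            region.extend((r, r))
    cells = np.asarray(cells, dtype=np.int64)
    region = np.asarray(region, dtype=np.int64)

    def tagger(pair, adj):
        a, b = pair
        c0, c1 = adj
        if c1 >= 0:
            r0, r1 = region[c0], region[c1]
            fl0 = r0 == int(Region.FLUID)
            fl1 = r1 == int(Region.FLUID)
            if fl0 != fl1:
                return int(BoundaryTag.GLYCOCALYX_WALL)
            return -1
        mid = 0.5 * (vertices[a] + vertices[b])
        return boundary_tag_at(mid[0], mid[1], region[c0])

    facets, tags, fcells = _extract_facets(cells, tagger)
    # orient interface facets fluid-side-first so outward normals point into tissue
    iface = tags == int(BoundaryTag.GLYCOCALYX_WALL)
    for i in np.nonzero(iface)[0]:
        c0, c1 = fcells[i]
        if c1 >= 0 and region[c0] != int(Region.FLUID):
            fcells[i] = (c1, c0)
    return TaggedMesh(vertices, cells, region, facets, tags, fcells,
                      grid=grid_meta)


# ---------------------------------------------------------------------------
# pore layouts
# ---------------------------------------------------------------------------

def pore_count(density: float, patch_dims: tuple[float, float]) -> int:
    """Expected pore count: round(density x patch area in mm^2)."""
    return int(round(density * patch_dims[0] * patch_dims[1]))


def place_inner_wall_pores(density: float, diameter: float,
                           patch_dims: tuple[float, float], mode: str = "grid",
                           seed: int | None = None) -> PoreLayout:
    """Place SC inner-wall pores on a rectangular patch.

    ``density`` in pores/mm^2, ``diameter`` in um, ``patch_dims`` in mm.
    Grid mode yields exactly ``round(density*area)`` pores on a centered
    rectangular lattice; jittered mode perturbs that lattice with a seeded RNG
    under a hard non-overlap guarantee.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    if patch_dims[0] < 0 or patch_dims[1] < 0:
        raise ValueError("patch_dims must be non-negative")
    if mode not in ("grid", "jittered"):
        raise ValueError("mode must be 'grid' or 'jittered'")
    if mode == "jittered" and seed is None:
        raise ValueError("jittered mode requires a seed")
    count = pore_count(density, patch_dims)
    w_um, h_um = patch_dims[0] * 1e3, patch_dims[1] * 1e3
    if count == 0:
        return PoreLayout(np.empty((0, 2)), diameter, tuple(patch_dims), mode, seed)

    aspect = w_um / h_um if h_um > 0 else 1.0
    nx = max(1, int(math.ceil(math.sqrt(count * aspect))))
    ny = int(math.ceil(count / nx))
    sx, sy = w_um / nx, h_um / ny
    if min(sx, sy) <= diameter:
        raise ValueError(
            f"{count} pores of diameter {diameter} um cannot be placed without "
            f"overlap on a {patch_dims[0]}x{patch_dims[1]} mm patch")
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    pts = np.column_stack([(ix.ravel() + 0.5) * sx, (iy.ravel() + 0.5) * sy])
    # keep the `count` lattice sites closest to the patch center (deterministic)
    d2 = ((pts - [w_um / 2, h_um / 2]) ** 2).sum(axis=1)
    order = np.lexsort((pts[:, 0], pts[:, 1], np.round(d2, 9)))
    pts = pts[order[:count]]
    if mode == "jittered":
        rng = np.random.default_rng(seed)
        amp = 0.99 * (min(sx, sy) - diameter) / (2 * math.sqrt(2))
        pts = pts + rng.uniform(-amp, amp, size=pts.shape)
        pts[:, 0] = np.clip(pts[:, 0], diameter / 2, w_um - diameter / 2)
        pts[:, 1] = np.clip(pts[:, 1], diameter / 2, h_um - diameter / 2)
    return PoreLayout(pts, diameter, tuple(patch_dims), mode, seed)


def _gap_intervals(params: GeometryParams) -> list[tuple[float, float]]:
    """Pore-gap y-intervals in the SC wall across the fluid channel."""
    if params.pore_density == 0:
        return []
    s = params.pore_spacing
    d = params.pore_diameter
    ch = params.channel_height
    if d > ch:
        raise ValueError("pore gap wider than the channel it perforates")
    n = max(1, int(round(ch / s)))
    while n > 1 and (n - 1) * s + d > ch:
        n -= 1
    y_mid = params.tissue_band + ch / 2
    centers = y_mid + (np.arange(n) - (n - 1) / 2) * s
    return [(c - d / 2, c + d / 2) for c in centers]


# ---------------------------------------------------------------------------
# domain builders
# ---------------------------------------------------------------------------

def build_outflow_domain(params: GeometryParams,
                         resolution: float) -> TaggedMesh:
    """Build the layered TM/JCT/SC flow domain at the given element size (um)."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if resolution > params.channel_height / 4:
        raise ValueError(
            f"resolution {resolution} um too coarse: must be <= "
            f"channel_height/4 = {params.channel_height / 4} um")
    if resolution > params.sc_wall_thickness:
        raise ValueError(
            f"resolution {resolution} um cannot resolve the {params.sc_wall_thickness} "
            "um SC inner wall")
    gaps = _gap_intervals(params)
    if gaps and resolution > params.pore_diameter:
        raise ValueError(
            f"resolution {resolution} um cannot resolve {params.pore_diameter} um pores")
    x_breaks = _dedupe([0.0, params.channel_length,
                        params.channel_length + params.tm_depth,
                        params.total_length - params.sc_wall_thickness,
                        params.total_length])
    yb = [0.0, params.tissue_band, params.tissue_band + params.channel_height,
          params.total_height]
    for lo, hi in gaps:
        yb.extend((lo, hi))
    y_breaks = _dedupe(yb)
    x_lines = _subdivide(x_breaks, resolution)
    y_lines = _subdivide(y_breaks, resolution)
    return _outflow_from_lines(params, x_lines, y_lines)


def _outflow_from_lines(params: GeometryParams, x_lines, y_lines) -> TaggedMesh:
    gaps = _gap_intervals(params)
    lx, ly = params.total_length, params.total_height
    x_sc = lx - params.sc_wall_thickness
    y_lo = params.tissue_band
    y_hi = params.tissue_band + params.channel_height

    def region_at(x, y):
        if x > x_sc:
            for lo, hi in gaps:
                if lo < y < hi:
                    return int(Region.FLUID)
            return int(Region.SC_WALL)
        if y_lo < y < y_hi:
            return int(Region.FLUID)
        if x < params.channel_length:
            return int(Region.FLUID)
        if x < params.channel_length + params.tm_depth:
            return int(Region.TM)
        return int(Region.JCT)

    def boundary_tag_at(x, y, reg):
        fluid = reg == int(Region.FLUID)
        if x < _SNAP:
            return int(BoundaryTag.INLET if fluid else BoundaryTag.ANCHOR)
        if x > lx - _SNAP:
            return int(BoundaryTag.OUTLET_OPEN if fluid else BoundaryTag.ANCHOR)
        # lateral cut planes: free-slip for fluid, rollers for tissue
        return int(BoundaryTag.SYMMETRY)

    meta = {"kind": "outflow", "params": params,
            "x_lines": np.asarray(x_lines), "y_lines": np.asarray(y_lines)}
    return _structured_mesh(np.asarray(x_lines), np.asarray(y_lines),
                            region_at, boundary_tag_at, meta)


def plane_channel_mesh(length: float, half_width: float,
                       nx: int = 4, ny: int | None = None,
                       y_lines: np.ndarray | None = None) -> TaggedMesh:
    """Straight fluid channel on [0,L] x [-h,h] (um) for analytic oracles.

    Walls at y = +-h are tagged GLYCOCALYX_WALL; x = 0 / L are inlet/outlet.
    Either a uniform wall-to-wall subdivision ``ny`` or explicit ``y_lines``
    (e.g. from :func:`graded_breaks`) may be given.
    """
    if y_lines is None:
        if ny is None:
            raise ValueError("give ny or y_lines")
        y_lines = np.linspace(-half_width, half_width, ny + 1)
    x_lines = np.linspace(0.0, length, nx + 1)

    def region_at(x, y):
        return int(Region.FLUID)

    def boundary_tag_at(x, y, reg):
        if abs(y) > half_width - _SNAP:
            return int(BoundaryTag.GLYCOCALYX_WALL)
        if x < _SNAP:
            return int(BoundaryTag.INLET)
        return int(BoundaryTag.OUTLET_OPEN)

    meta = {"kind": "channel", "params": (length, half_width),
            "x_lines": np.asarray(x_lines), "y_lines": np.asarray(y_lines, dtype=float)}
    return _structured_mesh(meta["x_lines"], meta["y_lines"],
                            region_at, boundary_tag_at, meta)


def tissue_slab_mesh(width: float, height: float, nx: int, ny: int,
                     region: Region = Region.TM) -> TaggedMesh:
    """Rectangular tissue slab for elasticity oracles (um).

    The bottom face is anchored, the sides are rollers (symmetry), and the
    top face is a loaded fluid-facing (glycocalyx) boundary.
    """
    x_lines = np.linspace(0.0, width, nx + 1)
    y_lines = np.linspace(0.0, height, ny + 1)

    def region_at(x, y):
        return int(region)

    def boundary_tag_at(x, y, reg):
        if y < _SNAP:
            return int(BoundaryTag.ANCHOR)
        if y > height - _SNAP:
            return int(BoundaryTag.GLYCOCALYX_WALL)
        return int(BoundaryTag.SYMMETRY)

    meta = {"kind": "slab", "params": (width, height)}
    return _structured_mesh(x_lines, y_lines, region_at, boundary_tag_at, meta)


def graded_breaks(half_width: float, first: float, growth: float = 1.3,
                  interior: float | None = None) -> np.ndarray:
    """Symmetric wall-refined y-lines for [-h, h] with first spacing ``first``.

    Spacings grow geometrically from each wall until they reach ``interior``
    (default h/4), which fills the core.
    """
    if interior is None:
        interior = half_width / 4
    pts = [0.0]
    d = first
    while pts[-1] < half_width:
        pts.append(min(pts[-1] + d, half_width))
        d = min(d * growth, interior)
    y = np.asarray(pts)
    y = half_width - y[::-1]  # distances from the wall -> coordinates
    lower = -half_width + (half_width - y)[::-1]
    return _dedupe(np.concatenate([lower, y]))


# ---------------------------------------------------------------------------
# refinement and quality
# ---------------------------------------------------------------------------

def refine_near_wall(mesh: TaggedMesh, layer_scale: float, growth: float = 1.3,
                     max_cells: int = 2_000_000) -> TaggedMesh:
    """Refine the structured grid so wall-normal element sizes near every
    glycocalyx facet are at most ``layer_scale``/3 (``layer_scale`` in nm).

    Works by inserting geometrically graded grid lines next to each wall line
    and regenerating the mesh from its stored generator metadata, which
    preserves region labels and boundary tags exactly.
    """
    if layer_scale <= 0:
        raise ValueError("layer_scale must be positive")
    if growth < 1:
        raise ValueError("growth must be >= 1")
    if mesh.grid is None:
        raise ValueError("refine_near_wall requires a structured mesh with "
                         "generator metadata")
    target = layer_scale * 1e-3 / 3.0  # nm -> um, first-layer size
    idx = mesh.facet_index(BoundaryTag.GLYCOCALYX_WALL)
    f = mesh.facets[idx]
    p0, p1 = mesh.vertices[f[:, 0]], mesh.vertices[f[:, 1]]
    horiz = np.abs(p0[:, 1] - p1[:, 1]) < _SNAP
    wall_y = _dedupe(p0[horiz, 1]) if horiz.any() else np.empty(0)
    wall_x = _dedupe(p0[~horiz, 0]) if (~horiz).any() else np.empty(0)

    def enrich(lines, walls):
        lines = list(np.asarray(lines, dtype=float))
        new = set(np.round(lines, 9))
        for w in walls:
            for sgn in (+1.0, -1.0):
                # nearest existing line on this side of the wall
                side = [v for v in lines if sgn * (v - w) > _SNAP]
                if not side:
                    continue
                gap = min(sgn * (v - w) for v in side)
                d, pos = target, 0.0
                while pos + d < gap - _SNAP:
                    pos += d
                    new.add(round(w + sgn * pos, 9))
                    d *= growth
                    if growth == 1.0 and d >= gap:
                        break
        return _dedupe(sorted(new))

    x_lines = enrich(mesh.grid["x_lines"], wall_x)
    y_lines = enrich(mesh.grid["y_lines"], wall_y)
    n_pred = 2 * (len(x_lines) - 1) * (len(y_lines) - 1)
    if n_pred > max_cells:
        raise ValueError(
            f"refinement would create {n_pred} cells, exceeding the budget of "
            f"{max_cells}; coarsen layer_scale or raise max_cells")
    kind = mesh.grid["kind"]
    if kind == "outflow":
        return _outflow_from_lines(mesh.grid["params"], x_lines, y_lines)
    if kind == "channel":
        length, half_width = mesh.grid["params"]
        return plane_channel_mesh(length, half_width,
                                  nx=len(x_lines) - 1, y_lines=y_lines)
    raise ValueError(f"unknown structured-grid kind {kind!r}")


def wall_normal_sizes(mesh: TaggedMesh,
                      tag: BoundaryTag = BoundaryTag.GLYCOCALYX_WALL) -> np.ndarray:
    """Wall-normal extent (2*area/edge) of the cell adjacent to each tagged facet."""
    idx = mesh.facet_index(tag)
    areas = np.abs(mesh.cell_areas())
    lens = mesh.facet_lengths(idx)
    return 2.0 * areas[mesh.facet_cells[idx, 0]] / lens


def mesh_quality(mesh: TaggedMesh) -> QualityReport:
    """Element-quality summary: sizes, bounding-box aspect ratios, inversions."""
    p = mesh.vertices[mesh.cells]
    e = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]])
    elen = np.hypot(e[..., 0], e[..., 1])  # (3, m)
    areas = mesh.cell_areas()
    bbox = p.max(axis=1) - p.min(axis=1)
    aspect = bbox.max(axis=1) / bbox.min(axis=1)
    inverted = np.nonzero(areas <= 0)[0]
    return QualityReport(
        n_vertices=len(mesh.vertices),
        n_cells=len(mesh.cells),
        n_tagged_facets=len(mesh.facets),
        min_size=float(elen.min(axis=0).min()),
        max_size=float(elen.max(axis=0).max()),
        max_aspect=float(aspect.max()),
        total_area=float(np.abs(areas).sum()),
        n_inverted=int(len(inverted)),
        inverted_cells=inverted,
    )
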