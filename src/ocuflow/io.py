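"""Persistence and field export.

HDF5 is the native, lossless format for :class:`~ocuflow.pipeline.ResultsBundle`
round trips.  Legacy ASCII VTK and XDMF+HDF5 exports serve visualization;
CSV exports carry the scalar time series and summary tables.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np

from .fluid import FlowState, LoadSchedule
from .geometry import TaggedMesh
from .mechanics import MechanicalState
from .pipeline import ResultsBundle

__all__ = ["save_bundle", "load_bundle", "write_vtk", "read_vtk",
           "export_fields"]


# ---------------------------------------------------------------------------
# native HDF5 bundle round trip
# ---------------------------------------------------------------------------

def _save_mesh(g: h5py.Group, mesh: TaggedMesh) -> None:
    for name in ("vertices", "cells", "region", "facets", "facet_tags",
                 "facet_cells"):
        g.create_dataset(name, data=getattr(mesh, name))


def _load_mesh(g: h5py.Group) -> TaggedMesh:
    return TaggedMesh(*[g[name][()] for name in
                        ("vertices", "cells", "region", "facets",
                         "facet_tags", "facet_cells")])


def save_bundle(bundle: ResultsBundle, path) -> None:
    """Write a results bundle to HDF5 (lossless for all arrays)."""
    with h5py.File(path, "w") as f:
        f.attrs["name"] = bundle.name
        f.attrs["mesh_digest"] = bundle.mesh_digest
        f.attrs["config_digest"] = bundle.config_digest
        f.attrs["provenance"] = json.dumps(bundle.provenance)
        f.attrs["schedule"] = json.dumps([bundle.schedule.peak_iop,
                                          bundle.schedule.duration,
                                          bundle.schedule.dt])
        gs = f.create_group("series")
        for k, v in bundle.series.items():
            gs.create_dataset(k, data=v)
        if bundle.final_flow is not None:
            g = f.create_group("flow")
            _save_mesh(g.create_group("mesh"), bundle.final_flow.mesh)
            g.create_dataset("u", data=bundle.final_flow.u)
            g.create_dataset("p", data=bundle.final_flow.p)
            g.attrs["time"] = bundle.final_flow.time
        if bundle.final_mech is not None:
            m = bundle.final_mech
            g = f.create_group("mech")
            _save_mesh(g.create_group("mesh"), m.mesh)
            for name in ("displacement", "tissue_velocity", "strain", "e",
                         "sigma_t", "sigma_i", "sigma_total", "sigma_zz",
                         "p_interstitial"):
                g.create_dataset(name, data=getattr(m, name))
        if bundle.potential is not None:
            g = f.create_group("potential")
            g.create_dataset("phi", data=bundle.potential.phi)
            g.attrs["mode"] = bundle.potential.mode
            g.attrs["zeta"] = bundle.potential.zeta


def load_bundle(path) -> ResultsBundle:
    with h5py.File(path, "r") as f:
        peak, dur, dt = json.loads(f.attrs["schedule"])
        series = {k: f["series"][k][()] for k in f["series"]}
        flow = mech = pot = None
        if "flow" in f:
            g = f["flow"]
            flow = FlowState(_load_mesh(g["mesh"]), g["u"][()], g["p"][()],
                             float(g.attrs["time"]))
        if "mech" in f:
            g = f["mech"]
            mech = MechanicalState(
                _load_mesh(g["mesh"]),
                *[g[name][()] for name in
                  ("displacement", "tissue_velocity", "strain", "e",
                   "sigma_t", "sigma_i", "sigma_total", "sigma_zz",
                   "p_interstitial")])
        if "potential" in f:
            from .electrostatics import PotentialField
            g = f["potential"]
            pot = PotentialField(flow.mesh if flow else mech.mesh,
                                 g["phi"][()], str(g.attrs["mode"]),
                                 float(g.attrs["zeta"]))
        return ResultsBundle(
            name=str(f.attrs["name"]), series=series,
            schedule=LoadSchedule(peak, dur, dt),
            mesh_digest=str(f.attrs["mesh_digest"]),
            config_digest=str(f.attrs["config_digest"]),
            final_flow=flow, final_mech=mech, potential=pot,
            provenance=json.loads(f.attrs["provenance"]))


# ---------------------------------------------------------------------------
# legacy ASCII VTK
# ---------------------------------------------------------------------------

def write_vtk(path, mesh: TaggedMesh, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "ocuflow") -> None:
    """Write a triangle mesh and fields as legacy ASCII VTK."""
    pts = mesh.vertices
    tri = mesh.cells
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for x, y in pts:
            f.write(f"{x:.17g} {y:.17g} 0\n")
        f.write(f"CELLS {len(tri)} {4 * len(tri)}\n")
        for a, b, c in tri:
            f.write(f"3 {a} {b} {c}\n")
        f.write(f"CELL_TYPES {len(tri)}\n")
        f.write("5\n" * len(tri))

        def dump(data, n, header):
            f.write(f"{header} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        f.write(f"{v:.17g}\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for row in arr:
                        z = row[2] if len(row) > 2 else 0.0
                        f.write(f"{row[0]:.17g} {row[1]:.17g} {z:.17g}\n")

        if point_data:
            dump(point_data, len(pts), "POINT_DATA")
        if cell_data:
            dump(cell_data, len(tri), "CELL_DATA")


def read_vtk(path):
    """Minimal legacy-VTK reader (triangles, scalars/vectors) for round trips.

    Returns (points (n,3), cells (m,3), point_data, cell_data).
    """
    with open(path) as f:
        tokens = f.read().split("\n")
    i = 0

    def next_line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        line = tokens[i]
        i += 1
        return line

    points = cells = None
    point_data, cell_data = {}, {}
    target = None
    while i < len(tokens):
        line = next_line().split()
        if not line:
            continue
        kw = line[0].upper()
        if kw == "POINTS":
            n = int(line[1])
            points = np.array([next_line().split() for _ in range(n)],
                              dtype=float)
        elif kw == "CELLS":
            m = int(line[1])
            rows = [next_line().split() for _ in range(m)]
            cells = np.array([r[1:4] for r in rows], dtype=np.int64)
        elif kw == "CELL_TYPES":
            for _ in range(int(line[1])):
                next_line()
        elif kw == "POINT_DATA":
            target = point_data
        elif kw == "CELL_DATA":
            target = cell_data
        elif kw == "SCALARS":
            name = line[1]
            next_line()  # LOOKUP_TABLE
            n = len(points) if target is point_data else len(cells)
            target[name] = np.array([next_line() for _ in range(n)],
                                    dtype=float)
        elif kw == "VECTORS":
            name = line[1]
            n = len(points) if target is point_data else len(cells)
            target[name] = np.array([next_line().split() for _ in range(n)],
                                    dtype=float)
        if i >= len(tokens) - 1:
            break
    return points, cells, point_data, cell_data


# ---------------------------------------------------------------------------
# XDMF (XML + HDF5 heavy data)
# ---------------------------------------------------------------------------

def _write_xdmf(path: Path, mesh: TaggedMesh, point_data: dict,
                cell_data: dict) -> None:
    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as f:
        pts3 = np.column_stack([mesh.vertices, np.zeros(len(mesh.vertices))])
        f.create_dataset("geometry", data=pts3)
        f.create_dataset("topology", data=mesh.cells)
        for name, arr in {**point_data, **cell_data}.items():
            f.create_dataset(f"fields/{name}", data=np.asarray(arr))
    attrs = []
    for center, data in (("Node", point_data), ("Cell", cell_data)):
        for name, arr in data.items():
            arr = np.asarray(arr)
            atype = "Scalar" if arr.ndim == 1 else "Vector"
            dims = " ".join(str(d) for d in arr.shape)
            attrs.append(
                f'      <Attribute Name="{name}" Center="{center}" '
                f'AttributeType="{atype}">\n'
                f'        <DataItem Format="HDF" Dimensions="{dims}">'
                f'{h5path.name}:/fields/{name}</DataItem>\n'
                f'      </Attribute>')
    xml = f"""<?xml version="1.0"?>
<Xdmf Version="3.0">
  <Domain>
    <Grid Name="ocuflow" GridType="Uniform">
      <Topology TopologyType="Triangle" NumberOfElements="{len(mesh.cells)}">
        <DataItem Format="HDF" Dimensions="{len(mesh.cells)} 3">{h5path.name}:/topology</DataItem>
      </Topology>
      <Geometry GeometryType="XYZ">
        <DataItem Format="HDF" Dimensions="{len(mesh.vertices)} 3">{h5path.name}:/geometry</DataItem>
      </Geometry>
{chr(10).join(attrs)}
    </Grid>
  </Domain>
</Xdmf>
"""
    path.with_suffix(".xdmf").write_text(xml)


# ---------------------------------------------------------------------------
# unified export entry point
# ---------------------------------------------------------------------------

def _bundle_fields(bundle: ResultsBundle):
    out = []
    if bundle.final_flow is not None:
        fl = bundle.final_flow
        pdata = {"velocity": fl.u, "pressure": fl.p}
        if bundle.potential is not None:
            pdata["potential"] = bundle.potential.phi
        out.append(("fluid", fl.mesh, pdata, {"region": fl.mesh.region}))
    if bundle.final_mech is not None:
        m = bundle.final_mech
        out.append(("tissue", m.mesh,
                    {"displacement": m.displacement,
                     "tissue_velocity": m.tissue_velocity,
                     "p_interstitial": m.p_interstitial},
                    {"region": m.mesh.region,
                     "sigma_xx": m.sigma_total[:, 0],
                     "sigma_yy": m.sigma_total[:, 1],
                     "sigma_xy": m.sigma_total[:, 2],
                     "sigma_zz": m.sigma_zz,
                     "eps_xx": m.strain[:, 0],
                     "eps_yy": m.strain[:, 1],
                     "eps_xy": m.strain[:, 2]}))
    return out


def export_fields(bundle: ResultsBundle, path, fmt: str = "vtk") -> list:
    """Export final-step fields (and the scalar series for csv).

    Returns the list of files written.  On a failed partial write the
    already-written files are removed before the error propagates.
    """
    if fmt not in ("vtk", "xdmf", "csv"):
        raise ValueError(f"unsupported export format {fmt!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        if fmt == "csv":
            import pandas as pd

            df = pd.DataFrame({"time_s": bundle.schedule.times(),
                               **bundle.series})
            out = path.with_suffix(".csv")
            df.to_csv(out, index=False)
            written.append(out)
        else:
            for label, mesh, pdata, cdata in _bundle_fields(bundle):
                stem = path.parent / f"{path.stem}_{label}"
                if fmt == "vtk":
                    out = stem.with_suffix(".vtk")
                    write_vtk(out, mesh, pdata, cdata)
                    written.append(out)
                else:
                    _write_xdmf(stem, mesh, pdata, cdata)
                    written.extend([stem.with_suffix(".xdmf"),
                                    stem.with_suffix(".h5")])
    except Exception:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise
    return written
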