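"""Summary statistics and streamline extraction for scenario results."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluid import FlowState
from .geometry import Region, TaggedMesh
from .mechanics import max_shear, principal_values
from .pipeline import ResultsBundle
from .units import pa_to_mmhg

__all__ = ["Polylines", "summarize", "summary_table", "streamlines"]

#: columns of the per-scenario summary row, with units
SUMMARY_COLUMNS = [
    "max_velocity_mm_s", "max_pressure_mmhg",
    "max_principal_stress_kpa", "max_principal_strain_pct",
    "max_shear_stress_kpa", "max_shear_strain_pct",
    "tm_displacement_um",
]


@dataclass
class Polylines:
    """Streamline polylines: per-line point arrays (um) and speeds (mm/s)."""

    points: list          # list of (k, 2) arrays
    speeds: list          # list of (k,) arrays
    seeds: np.ndarray


def summarize(bundle: ResultsBundle, region: str | Region = Region.TM,
              volume_weighted: bool = False) -> dict:
    """One summary row for a scenario, maxima taken at the final time step.

    The nodal-averaged displacement is the unweighted arithmetic mean of the
    nodal displacement magnitudes over the named region's nodes (the
    ``volume_weighted`` variant weights nodes by their lumped cell area).
    Also reports the time at which the spatial velocity maximum peaked, since
    the spatial max at final time and the spatiotemporal max can differ.
    """
    if isinstance(region, str):
        region = Region[region.upper()] if region.upper() != "ALL" else None
    mech = bundle.final_mech
    flow = bundle.final_flow
    if mech is None or flow is None:
        raise ValueError("bundle lacks final fields")
    mesh = mech.mesh
    if region is None:
        cell_mask = np.ones(len(mesh.cells), dtype=bool)
    else:
        cell_mask = mesh.region == int(region)
    nodes = np.unique(mesh.cells[cell_mask])
    if len(nodes) == 0:
        raise ValueError(f"region {region} is empty")
    mag = np.hypot(mech.displacement[nodes, 0], mech.displacement[nodes, 1])
    if volume_weighted:
        w = np.zeros(len(mesh.vertices))
        areas = np.abs(mesh.cell_areas())[cell_mask]
        np.add.at(w, mesh.cells[cell_mask].ravel(),
                  np.repeat(areas / 3.0, 3))
        disp = float((mag * w[nodes]).sum() / w[nodes].sum()) * 1e6
    else:
        disp = float(mag.mean()) * 1e6
    s1 = principal_values(mech.sigma_total, zz=mech.sigma_zz)
    e1 = principal_values(mech.strain, zz=0.0)
    vseries = bundle.series["max_velocity_mm_s"]
    return {
        "scenario": bundle.name,
        "max_velocity_mm_s": float(flow.speed().max() * 1e3),
        "max_pressure_mmhg": float(pa_to_mmhg(flow.p.max())),
        "max_principal_stress_kpa": float(s1[:, 0].max() / 1e3),
        "max_principal_strain_pct": float(e1[:, 0].max() * 1e2),
        "max_shear_stress_kpa": float(max_shear(mech.sigma_total,
                                                zz=mech.sigma_zz).max() / 1e3),
        "max_shear_strain_pct": float(max_shear(mech.strain).max() * 1e2),
        "tm_displacement_um": disp,
        "time_of_max_velocity_s": float(bundle.schedule.times()[int(np.argmax(vseries))]),
        "spatiotemporal_max_velocity_mm_s": float(vseries.max()),
    }


def summary_table(bundles: dict | list, region: str | Region = Region.TM) -> pd.DataFrame:
    """Per-scenario summary rows as a DataFrame."""
    if isinstance(bundles, dict):
        bundles = list(bundles.values())
    rows = [summarize(b, region=region) for b in bundles]
    return pd.DataFrame(rows).set_index("scenario")


def streamlines(flow: FlowState, seeds: np.ndarray, step: float = 0.5,
                max_steps: int = 4000) -> Polylines:
    """Fixed-step integration of the velocity direction field.

    ``seeds`` are (k, 2) points in um; ``step`` is the arc-length step in um.
    Each polyline follows the unit velocity direction until it leaves the
    fluid region, stalls, or reaches ``max_steps``.  Speeds are recorded in
    mm/s.  Seeds outside the fluid region are skipped with a warning entry
    (an empty polyline).
    """
    import matplotlib.tri as mtri

    mesh = flow.mesh
    tri = mtri.Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1],
                             mesh.cells)
    iux = mtri.LinearTriInterpolator(tri, flow.u[:, 0])
    iuy = mtri.LinearTriInterpolator(tri, flow.u[:, 1])
    lines, speeds = [], []
    for seed in np.atleast_2d(seeds):
        p = np.asarray(seed, dtype=float)
        pts, spd = [], []
        for _ in range(max_steps + 1):
            vx, vy = iux(p[0], p[1]), iuy(p[0], p[1])
            if np.ma.is_masked(vx) or np.ma.is_masked(vy):
                break  # left the fluid region (or seed outside it)
            v = np.array([float(vx), float(vy)])
            s = float(np.hypot(v[0], v[1]))
            pts.append(p.copy())
            spd.append(s * 1e3)
            if s < 1e-300:
                break  # stagnation: polyline degenerates to its seed
            p = p + step * v / s
        lines.append(np.asarray(pts).reshape(-1, 2))
        speeds.append(np.asarray(spd))
    return Polylines(lines, speeds, np.atleast_2d(seeds))


def inlet_seed_line(mesh: TaggedMesh, n: int = 10, offset: float = 0.5) -> np.ndarray:
    """Uniform line of seed points just inside the inlet face."""
    from .geometry import BoundaryTag

    nodes = mesh.nodes_by_tag(BoundaryTag.INLET)
    if len(nodes) == 0:
        raise ValueError("mesh has no inlet facets")
    y0 = mesh.vertices[nodes, 1].min()
    y1 = mesh.vertices[nodes, 1].max()
    x = mesh.vertices[nodes, 0].mean() + offset
    ys = y0 + (y1 - y0) * (np.arange(n) + 0.5) / n
    return np.column_stack([np.full(n, x), ys])
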