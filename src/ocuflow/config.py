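"""TOML configuration: sections [geometry], [electro], [fluid], [solid],
[scenario] mapped onto the parameter dataclasses."""

from __future__ import annotations

import tomllib
from dataclasses import fields as dc_fields
from pathlib import Path

from .electrostatics import ElectroProperties
from .fluid import FluidProperties, LoadSchedule
from .geometry import GeometryParams, Region
from .mechanics import SolidProperties
from .pipeline import GlycocalyxLayer, PhysicalParams, ScenarioConfig

__all__ = ["load_config", "scenario_from_config", "EXAMPLE_CONFIG"]

EXAMPLE_CONFIG = """\
# ocuflow scenario configuration (all values shown are the defaults)

[geometry]
tm_depth = 120.0            # um, TM extent along the flow axis
jct_thickness = 14.0        # um
sc_wall_thickness = 2.2     # um
pore_density = 835.0        # pores/mm^2 of SC inner wall
pore_diameter = 1.3         # um
glycocalyx_thickness = 109.0  # nm
channel_height = 2.0        # um, fluid channel height
channel_length = 20.0       # um, anterior-chamber vestibule
tissue_band = 8.0           # um, elastic tissue on each side of the channel

[electro]
zeta_potential = -19.5e-3   # V
relative_permittivity = 99.0
conductivity = 179e-4       # ohm^-1 cm^-1
membrane_potential = -70e-3 # V (metadata)
reference_impedance = 50.0  # ohm (metadata)
debye_length_nm = 2000.0    # scale-model Debye length (see docs/methods.md)

[fluid]
density = 1000.0            # kg/m^3
viscosity = 7.185e-4        # Pa s
include_convection = true

[solid]
young_tm = 4e3              # Pa
young_jct = 4e3
young_sc_wall = 7.48e3
poisson_ratio = 0.495
pretension = 500e-6         # N
out_of_plane_depth = 36e-3  # m, TM ring circumference

[scenario]
name = "EFSI_15"
electric_enabled = true
peak_iop = 15.0             # mmHg
duration = 1.0              # s
dt = 0.01                   # s
resolution = 0.5            # um
edl_mode = "resolved"
inlet_tangential_field = 0.0  # V/m
coupling_tol = 1e-6
max_coupling_iters = 50
relaxation = "aitken"
seed = 0
"""


def _take(cls, section: dict) -> dict:
    names = {f.name for f in dc_fields(cls)}
    return {k: v for k, v in section.items() if k in names}


def load_config(path) -> dict:
    """Parse a TOML config file into its raw section dictionaries."""
    with open(Path(path), "rb") as f:
        return tomllib.load(f)


def scenario_from_config(path_or_dict) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a TOML file or parsed dict."""
    raw = (path_or_dict if isinstance(path_or_dict, dict)
           else load_config(path_or_dict))
    geometry = GeometryParams(**_take(GeometryParams, raw.get("geometry", {})))
    electro = ElectroProperties(**_take(ElectroProperties, raw.get("electro", {})))
    fluid = FluidProperties(**_take(FluidProperties, raw.get("fluid", {})))
    sol = raw.get("solid", {})
    young = {Region.TM: sol.get("young_tm", 4e3),
             Region.JCT: sol.get("young_jct", 4e3),
             Region.SC_WALL: sol.get("young_sc_wall", 7.48e3)}
    solid = SolidProperties(young_modulus=young,
                            **_take(SolidProperties,
                                    {k: v for k, v in sol.items()
                                     if k != "young_modulus"}))
    glyco = GlycocalyxLayer(thickness_nm=geometry.glycocalyx_thickness)
    params = PhysicalParams(fluid=fluid, electro=electro, solid=solid,
                            glycocalyx=glyco)
    sc = raw.get("scenario", {})
    schedule = LoadSchedule(peak_iop=sc.get("peak_iop", 15.0),
                            duration=sc.get("duration", 1.0),
                            dt=sc.get("dt", 0.01))
    kw = _take(ScenarioConfig, sc)
    kw.pop("schedule", None)
    kw.setdefault("name", "scenario")
    kw.setdefault("electric_enabled", True)
    kw.setdefault("peak_iop", schedule.peak_iop)
    return ScenarioConfig(schedule=schedule, geometry=geometry,
                          params=params, **kw)
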