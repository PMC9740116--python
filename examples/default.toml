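# ocuflow scenario configuration (all values shown are the defaults)

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
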