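"""Physical constants and the package-wide unit conventions.

Unit conventions (used everywhere unless a docstring says otherwise):

==============  =========================================
quantity        unit
==============  =========================================
length          nm (trajectories, boxes, radii)
                m (droplet radii, diffusion lengths)
time            ps / ns (trajectories), s (droplets)
energy          k_B*T (dimensionless, per temperature)
diffusivity     m^2 s^-1 externally; nm^2 ps^-1 inside
                trajectory integrators
viscosity       Pa s
density         kg m^-3
==============  =========================================

1 nm^2/ps = 1e-6 m^2/s.
"""

KB = 1.380649e-23
"""Boltzmann constant, J K^-1 (exact, SI 2019)."""

H_PLANCK = 6.62607015e-34
"""Planck constant, J s (exact, SI 2019)."""

NM2_PER_PS_TO_M2_PER_S = 1e-6
M2_PER_S_TO_NM2_PER_PS = 1e6

WATER_RADIUS_M = 0.1e-9
"""Default hydrodynamic radius of water (0.2 nm diameter)."""

DENSITY_WATER = 1000.0
"""kg m^-3, liquid water at ambient conditions (rounded)."""

#: Pure-component densities of the amorphous solutes, kg m^-3.
SOLUTE_DENSITY = {
    "glucose": 1562.0,
    "sucrose": 1587.0,
    "trehalose": 1580.0,
    "maltose": 1540.0,
    "raffinose": 1465.0,
    "levoglucosan": 1690.0,
    "generic": 1550.0,
}

#: Bondi van der Waals radii, nm.
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
}


def kt_over_h_per_ns(temperature: float) -> float:
    """Thermal attempt frequency k_B*T/h expressed in ns^-1.

    At 300 K this is ~6.25e3 ns^-1, the default transition-state-theory
    prefactor.
    """
    return KB * temperature / H_PLANCK * 1e-9
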