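"""Physical constants and unit helpers.

Energies are kcal/mol throughout; temperatures are Kelvin internally
(Celsius accepted at I/O boundaries); concentrations are μM in subunit
units unless stated otherwise.
"""

# Gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987e-3

# SI constants for Eyring / Stokes-Einstein expressions
BOLTZMANN_SI = 1.380649e-23  # J K^-1
PLANCK_SI = 6.62607015e-34   # J s

# Standard-state reference concentration for K_D -> free energy, in μM
C_STANDARD_UM = 1.0e6  # 1 M

#: Dynamic viscosity of water, Pa s, at common experiment temperatures (°C).
WATER_VISCOSITY_PA_S = {
    20.0: 1.002e-3,
    25.0: 0.890e-3,
    37.0: 0.6913e-3,
}

ZERO_CELSIUS = 273.15


def celsius_to_kelvin(t_c):
    return t_c + ZERO_CELSIUS


def kelvin_to_celsius(t_k):
    return t_k - ZERO_CELSIUS
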