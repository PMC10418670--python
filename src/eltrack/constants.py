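"""Physical constants and unit conversions.

Cross-sections are carried in units of 1e-20 m^2 (identical to A^2)
throughout the package; energies in eV unless noted.
"""

HARTREE_EV = 27.211386245988      # 1 Hartree in eV
BOHR_RADIUS_M = 0.529177210903e-10
A0_SQ_1E20_M2 = (BOHR_RADIUS_M * 1e10) ** 2  # a0^2 in 1e-20 m^2 (= A^2)
DEBYE_AU = 0.3934303              # 1 Debye in e*a0

ELECTRON_MASS_KG = 9.1093837015e-31
EV_J = 1.602176634e-19

MOLECULE_NAME = "1M5NI"
MOLECULAR_MASS_U = 127.0          # parent mass, u
DIPOLE_MOMENT_D = 4.4             # permanent dipole moment, Debye
MEAN_ROTATIONAL_TRANSFER_EV = 0.617e-3  # mean rotational excitation at 300 K


def wavenumber_au(energy_ev: float) -> float:
    """Electron wavenumber in atomic units, k = sqrt(2 E) with E in Hartree."""
    return (2.0 * energy_ev / HARTREE_EV) ** 0.5


def electron_speed_ms(energy_ev: float) -> float:
    """Non-relativistic electron speed in m/s."""
    return (2.0 * energy_ev * EV_J / ELECTRON_MASS_KG) ** 0.5
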