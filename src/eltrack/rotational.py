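"""First-Born rigid-rotor dipole rotational-excitation cross-sections.

1M5NI carries a strong permanent dipole (4.4 D), so long-range dipole
rotational excitation is an ever-open side channel.  The model here is the
standard point-dipole first Born approximation with a single effective
transition at the thermally averaged rotational energy transfer
(0.617 meV at 300 K): in atomic units

    dsigma/dOmega = (4/3) D^2 (k_f / k_i) / K^2,

with K^2 = k_i^2 + k_f^2 - 2 k_i k_f cos(theta) the squared momentum
transfer.  The forward divergence of the Born dipole amplitude is
regularized by a minimum-transferred-energy cutoff translated to a minimum
angle via binary-encounter kinematics, theta_cut = arcsin(sqrt(eps_cut/E)).

These cross-sections are a qualitative side channel: they are excluded
from the self-consistency closure of the integral set, and only their
energy dependence (monotone decrease) and scalings are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .errors import ConfigError, DomainError

__all__ = ["RotorSpec", "born_dipole_dcs", "born_dipole_ics", "cutoff_angle_deg"]


@dataclass(frozen=True)
class RotorSpec:
    """Rigid-rotor dipole parameters for the effective single transition."""

    dipole_debye: float = constants.DIPOLE_MOMENT_D
    delta_e_rot_ev: float = constants.MEAN_ROTATIONAL_TRANSFER_EV
    temperature_k: float = 300.0
    min_transfer_ev: float = constants.MEAN_ROTATIONAL_TRANSFER_EV

    def __post_init__(self) -> None:
        if self.dipole_debye < 0:
            raise ConfigError("dipole moment must be >= 0")
        if self.delta_e_rot_ev <= 0:
            raise ConfigError("rotational transfer must be > 0")
        if self.min_transfer_ev <= 0:
            raise ConfigError("minimum transferred-energy cutoff must be > 0")


def cutoff_angle_deg(spec: RotorSpec, energy: float) -> float:
    """Minimum angle (degrees) from the minimum-transfer regularization.

    Binary-encounter kinematics relate an energy transfer eps to a
    deflection via eps = E sin^2(theta); the cutoff angle is the deflection
    that would carry the minimum allowed transfer.
    """
    frac = min(spec.min_transfer_ev / energy, 1.0)
    return float(np.degrees(np.arcsin(np.sqrt(frac))))


def _wavenumbers(spec: RotorSpec, energy: float) -> tuple[float, float]:
    if energy <= spec.delta_e_rot_ev:
        raise DomainError(
            f"impact energy {energy} eV must exceed the rotational transfer "
            f"{spec.delta_e_rot_ev} eV")
    ki = constants.wavenumber_au(energy)
    kf = constants.wavenumber_au(energy - spec.delta_e_rot_ev)
    return ki, kf


def born_dipole_dcs(spec: RotorSpec, energy: float, theta_deg: float) -> float:
    """Point-dipole FBA differential cross-section, 1e-20 m^2/sr.

    Raises :class:`DomainError` below the cutoff angle, where the Born
    amplitude is not trusted (forward divergence).
    """
    theta_cut = cutoff_angle_deg(spec, energy)
    if theta_deg < theta_cut:
        raise DomainError(
            f"theta = {theta_deg:.4g} deg below the minimum-transfer cutoff "
            f"angle {theta_cut:.4g} deg at E = {energy} eV")
    if theta_deg > 180:
        raise DomainError("theta must be <= 180 degrees")
    ki, kf = _wavenumbers(spec, energy)
    d_au = spec.dipole_debye * constants.DEBYE_AU
    mu = np.cos(np.radians(theta_deg))
    k2 = ki * ki + kf * kf - 2.0 * ki * kf * mu
    dcs_au = (4.0 / 3.0) * d_au**2 * (kf / ki) / k2
    return float(dcs_au * constants.A0_SQ_1E20_M2)


def born_dipole_ics(spec: RotorSpec, energy: float) -> float:
    """Integral of the FBA dipole DCS over [theta_cut, 180 deg], 1e-20 m^2.

    Closed form: with a = k_i^2 + k_f^2 and b = 2 k_i k_f,
    int dOmega / K^2 = (2 pi / b) ln[(a + b) / (a - b cos(theta_cut))].
    """
    ki, kf = _wavenumbers(spec, energy)
    d_au = spec.dipole_debye * constants.DEBYE_AU
    mu_cut = np.cos(np.radians(cutoff_angle_deg(spec, energy)))
    a = ki * ki + kf * kf
    b = 2.0 * ki * kf
    solid = (2.0 * np.pi / b) * np.log((a + b) / (a - b * mu_cut))
    ics_au = (4.0 / 3.0) * d_au**2 * (kf / ki) * solid
    return float(ics_au * constants.A0_SQ_1E20_M2)
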