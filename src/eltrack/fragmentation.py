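"""Discrete fragment samplers for dissociative electron attachment (anions)
and electron-impact ionization (cations).

Anion branching ratios are anchored at the measured incident energies
(3.1-4.7 eV, the resonant window where anion yields peak); between anchors
the categorical distribution is linearly interpolated and renormalized,
outside the window the nearest anchor is used (no measured branching exists
elsewhere).  Cation relative intensities were measured at a single energy
(67 eV) and are treated as energy-independent.

Fragment kinetic energies all peak near 0 eV and the emission is highly
isotropic; the sampler draws an exponential KE with a species-specific mean
(CN- broader than NO2-) and a uniform direction on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ConfigError, SchemaError

__all__ = [
    "FragmentSpecies",
    "BranchingTable",
    "CationIntensityTable",
    "AnionKineticEnergyModel",
    "sample_anion",
    "sample_anion_ke",
    "sample_cation",
    "read_branching_csv",
    "read_cation_csv",
]

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class FragmentSpecies:
    """A charged fragment: label, mass in u, and charge sign (+1 or -1)."""

    label: str
    mass_u: float
    charge: int

    def __post_init__(self) -> None:
        if self.mass_u <= 0:
            raise ConfigError(f"species {self.label}: mass must be > 0")
        if self.charge not in (-1, +1):
            raise ConfigError(f"species {self.label}: charge must be +-1")


@dataclass
class BranchingTable:
    """Energy-indexed categorical distributions over anion fragment species.

    ``energies`` are the anchored incident energies (eV); ``probabilities``
    has shape (n_energies, n_species), each row summing to 1.
    """

    species: tuple[FragmentSpecies, ...]
    energies: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.species) == 0:
            raise ConfigError("branching table has no species")
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate species labels in branching table")
        if self.probabilities.shape != (self.energies.size, len(self.species)):
            raise ConfigError(
                f"probability array shape {self.probabilities.shape} does not "
                f"match {self.energies.size} energies x {len(self.species)} species"
            )
        if not np.all(np.diff(self.energies) > 0):
            raise ConfigError("branching anchor energies must be increasing")
        if np.any(self.probabilities < 0):
            raise ConfigError("negative branching probability")
        rowsums = self.probabilities.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > _PROB_TOL):
            bad = float(self.energies[np.argmax(np.abs(rowsums - 1.0))])
            raise ConfigError(f"branching row at {bad} eV does not sum to 1")

    @property
    def emin(self) -> float:
        return float(self.energies[0])

    @property
    def emax(self) -> float:
        return float(self.energies[-1])

    def distribution(self, energy: float) -> np.ndarray:
        """Interpolated, renormalized species probabilities at ``energy``.

        Energies outside the anchored window map to the nearest anchor.
        """
        e = float(energy)
        if e <= self.emin:
            p = self.probabilities[0].copy()
        elif e >= self.emax:
            p = self.probabilities[-1].copy()
        else:
            i = int(np.searchsorted(self.energies, e))
            e0, e1 = self.energies[i - 1], self.energies[i]
            t = (e - e0) / (e1 - e0)
            p = (1 - t) * self.probabilities[i - 1] + t * self.probabilities[i]
        return p / p.sum()


def sample_anion(table: BranchingTable, energy: float,
                 rng: np.random.Generator) -> FragmentSpecies:
    """Draw one anion species from the branching distribution at ``energy``."""
    p = table.distribution(energy)
    idx = rng.choice(len(table.species), p=p)
    return table.species[idx]


@dataclass
class AnionKineticEnergyModel:
    """Zero-mode (exponential) kinetic-energy draw plus isotropic direction.

    Mean KEs are explicit configuration, not measured values: the experiments
    give distribution shapes (all peaking near 0 eV, CN- markedly broader
    than NO2-), not tabulated parameters.
    """

    mean_ev: Mapping[str, float] = field(
        default_factory=lambda: {"NO2-": 0.05, "CN-": 0.2}
    )
    default_mean_ev: float = 0.05

    def mean_for(self, species: FragmentSpecies) -> float:
        return float(self.mean_ev.get(species.label, self.default_mean_ev))

    def sample(self, species: FragmentSpecies,
               rng: np.random.Generator) -> tuple[float, np.ndarray]:
        """Return (kinetic energy eV, isotropic unit direction)."""
        ke = rng.exponential(self.mean_for(species))
        mu = rng.uniform(-1.0, 1.0)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        s = np.sqrt(1.0 - mu * mu)
        direction = np.array([s * np.cos(phi), s * np.sin(phi), mu])
        return float(ke), direction


def sample_anion_ke(species: FragmentSpecies, rng: np.random.Generator,
                    model: AnionKineticEnergyModel | None = None) -> float:
    """Draw a fragment kinetic energy (eV) for ``species``."""
    model = model or AnionKineticEnergyModel()
    ke, _ = model.sample(species, rng)
    return ke


@dataclass
class CationIntensityTable:
    """Relative intensities of cation species (parent ion = 1), one energy."""

    species: tuple[FragmentSpecies, ...]
    intensities: np.ndarray
    energy_ev: float = 67.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.species) == 0:
            raise ConfigError("cation table has no species")
        if self.intensities.shape != (len(self.species),):
            raise ConfigError("intensity array does not match species list")
        if np.any(self.intensities <= 0):
            raise ConfigError("cation intensities must be > 0")
        parent = int(np.argmax([s.mass_u for s in self.species]))
        if abs(self.intensities[parent] - 1.0) > _PROB_TOL:
            raise ConfigError("parent-ion relative intensity must be 1")

    @property
    def parent(self) -> FragmentSpecies:
        return self.species[int(np.argmax([s.mass_u for s in self.species]))]

    def distribution(self) -> np.ndarray:
        return self.intensities / self.intensities.sum()


def sample_cation(table: CationIntensityTable,
                  rng: np.random.Generator) -> FragmentSpecies:
    """Draw one cation species with probability intensity / sum(intensities)."""
    idx = rng.choice(len(table.species), p=table.distribution())
    return table.species[idx]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _data_rows(path: Path) -> list[list[str]]:
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([c.strip() for c in line.split(",")])
    return rows


def read_branching_csv(path: Path | str) -> BranchingTable:
    """Read ``energy_eV,species,mass_u,probability`` rows into a table."""
    path = Path(path)
    rows = _data_rows(path)
    if not rows or rows[0] != ["energy_eV", "species", "mass_u", "probability"]:
        raise SchemaError(f"{path}: malformed branching CSV header")
    by_species: dict[str, float] = {}
    records: dict[float, dict[str, float]] = {}
    for r in rows[1:]:
        if len(r) != 4:
            raise SchemaError(f"{path}: expected 4 columns, got {r}")
        e, label, mass, prob = float(r[0]), r[1], float(r[2]), float(r[3])
        by_species.setdefault(label, mass)
        if by_species[label] != mass:
            raise SchemaError(f"{path}: inconsistent mass for {label}")
        records.setdefault(e, {})[label] = prob
    labels = list(by_species)
    energies = sorted(records)
    species = tuple(FragmentSpecies(l, by_species[l], -1) for l in labels)
    probs = np.array([[records[e].get(l, 0.0) for l in labels] for e in energies])
    return BranchingTable(species=species, energies=np.array(energies),
                          probabilities=probs)


def read_cation_csv(path: Path | str, energy_ev: float = 67.0) -> CationIntensityTable:
    """Read ``species,mass_u,relative_intensity`` rows into a table."""
    path = Path(path)
    rows = _data_rows(path)
    if not rows or rows[0] != ["species", "mass_u", "relative_intensity"]:
        raise SchemaError(f"{path}: malformed cation CSV header")
    species, intens = [], []
    for r in rows[1:]:
        if len(r) != 3:
            raise SchemaError(f"{path}: expected 3 columns, got {r}")
        species.append(FragmentSpecies(r[0], float(r[1]), +1))
        intens.append(float(r[2]))
    return CationIntensityTable(species=tuple(species),
                                intensities=np.array(intens),
                                energy_ev=energy_ev)
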