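"""Packaged reference tables and synthetic-input generators.

The printed integral cross-section tables of the 1M5NI data set ship with
the package (they are short, published data), so everything downstream is
testable without downloads.  Synthetic generators provide a parametric toy
elastic DCS (screened-Coulomb shape, clearly labelled non-measured physics)
and resonance test curves with their true decomposition retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import constants
from .errors import ConfigError, SchemaError
from .fragmentation import (BranchingTable, CationIntensityTable,
                            read_branching_csv, read_cation_csv)
from .xs import Channel, ChannelTable, CrossSectionSet, read_channel_csv

__all__ = [
    "FIXTURE_IDS",
    "packaged_tables",
    "load_fixture_set",
    "load_anion_branching",
    "load_cation_intensities",
    "ScreenedCoulombDCS",
    "make_toy_dcs",
    "make_resonance_curve",
    "ResonanceTruth",
]

#: fixture id -> channel CSV file names
_SET_FILES = {
    "1m5ni_recommended": [
        "recommended_elastic.csv",
        "recommended_attachment.csv",
        "recommended_vibrational.csv",
        "recommended_electronic.csv",
        "recommended_ionization.csv",
        "recommended_sum.csv",
    ],
    "1m5ni_tcs_reference": [
        "tcs_experimental.csv",
        "tcs_reference.csv",
    ],
}

FIXTURE_IDS = (
    "1m5ni_recommended",
    "1m5ni_tcs_reference",
    "1m5ni_anion_br",
    "1m5ni_cation_67eV",
)


def _data_path(name: str) -> Path:
    return Path(resources.files("eltrack").joinpath("data", name))


def load_fixture_set(fixture_id: str) -> CrossSectionSet:
    """Load one of the packaged cross-section sets by id."""
    if fixture_id not in _SET_FILES:
        raise SchemaError(f"unknown cross-section fixture id: {fixture_id!r}")
    out = CrossSectionSet(
        molecule=constants.MOLECULE_NAME,
        mass_u=constants.MOLECULAR_MASS_U,
        dipole_debye=constants.DIPOLE_MOMENT_D,
    )
    for name in _SET_FILES[fixture_id]:
        table = read_channel_csv(_data_path(name))
        out.add(table, note=table.note)
    return out


def load_anion_branching() -> BranchingTable:
    """DEA anion branching ratios anchored at 3.1 and 4.7 eV."""
    return read_branching_csv(_data_path("anion_branching.csv"))


def load_cation_intensities() -> CationIntensityTable:
    """Cation relative intensities at 67 eV impact (parent ion = 1)."""
    return read_cation_csv(_data_path("cation_intensities_67eV.csv"))


def packaged_tables() -> tuple[CrossSectionSet, BranchingTable, CationIntensityTable]:
    """The recommended cross-section set plus both fragment tables."""
    return (load_fixture_set("1m5ni_recommended"),
            load_anion_branching(),
            load_cation_intensities())


# ---------------------------------------------------------------------------
# Toy elastic DCS
# ---------------------------------------------------------------------------

@dataclass
class ScreenedCoulombDCS:
    """Forward-peaked screened-Coulomb elastic DCS provider.

    dsigma/dOmega = N(E) / (1 + 2 eta(E) - cos theta)^2, normalized so the
    full solid-angle integral equals ``ics(E)`` (analytic: the integral of
    the shape is pi / (eta (1 + eta))).  This is a documented synthetic
    stand-in for measured or computed differential elastic tables, used when
    no user-supplied DCS table is available; it carries no molecule-specific
    angular physics beyond forward peaking.
    """

    ics: Callable[[float], float]
    screening: Callable[[float], float] | float = 2.0

    def eta(self, energy: float) -> float:
        if callable(self.screening):
            val = float(self.screening(energy))
        else:
            # fixed screening strength divided by energy: stronger forward
            # peaking at higher impact energy
            val = float(self.screening) / max(float(energy), 0.1)
        if val <= 0:
            raise ConfigError("screening parameter must be > 0")
        return val

    def __call__(self, energy: float, theta_deg):
        """DCS in 1e-20 m^2/sr at impact energy (eV) and angle (degrees).

        Accepts a scalar or array of angles.
        """
        eta = self.eta(energy)
        mu = np.cos(np.radians(np.asarray(theta_deg, dtype=float)))
        norm = float(self.ics(energy)) * eta * (1.0 + eta) / np.pi
        out = norm / (1.0 + 2.0 * eta - mu) ** 2
        return float(out) if np.isscalar(theta_deg) else out

    def sample_mu(self, energy: float, rng: np.random.Generator) -> float:
        """Analytic inverse-CDF draw of mu = cos(theta) from the shape.

        The CDF of 1/(c - mu)^2 on [-1, 1] (c = 1 + 2 eta) inverts in
        closed form, so transport can sample deflections without numeric
        CDF construction.
        """
        c = 1.0 + 2.0 * self.eta(energy)
        u = rng.random()
        inv_lo = 1.0 / (c + 1.0)   # mu = -1
        inv_hi = 1.0 / (c - 1.0)   # mu = +1
        inv = inv_lo + u * (inv_hi - inv_lo)
        return float(c - 1.0 / inv)


def make_toy_dcs(ics: Callable[[float], float] | float,
                 screening: Callable[[float], float] | float = 2.0) -> ScreenedCoulombDCS:
    """Build a toy elastic DCS provider normalized to ``ics`` (1e-20 m^2)."""
    if not callable(ics):
        level = float(ics)
        ics = lambda energy: level  # noqa: E731
    return ScreenedCoulombDCS(ics=ics, screening=screening)


# ---------------------------------------------------------------------------
# Synthetic resonance curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResonanceTruth:
    """True decomposition of a synthetic resonance curve, kept for oracles."""

    energies: np.ndarray
    background: np.ndarray
    peaks_total: np.ndarray
    peak_params: tuple[tuple[float, float, float], ...]  # (center, width, area)


def make_resonance_curve(
    grid: Sequence[float],
    background: Callable[[np.ndarray], np.ndarray] | tuple[float, float] = (40.0, 50.0),
    peaks: Sequence[tuple[float, float, float]] = (),
    shape: str = "lorentzian",
    noise_rel: float = 0.0,
    seed: int | None = None,
) -> tuple[ChannelTable, ResonanceTruth]:
    """Synthesize an "elastic plus attachment" curve with known decomposition.

    ``background`` is either a callable sigma_bg(E) or an (a, b) pair for the
    smooth form a + b/E; ``peaks`` are given as (center eV, width eV, area
    eV*1e-20 m^2) with ``shape`` selecting a Lorentzian (width = HWHM) or
    Gaussian (width = standard deviation) lineshape.  Returns the curve as a
    ChannelTable plus the retained truth for oracle comparisons.
    """
    e = np.asarray(grid, dtype=float)
    if callable(background):
        bg = np.asarray(background(e), dtype=float)
    else:
        a, b = background
        bg = a + b / e
    if shape not in ("lorentzian", "gaussian"):
        raise ConfigError(f"unknown peak shape {shape!r}")
    peak_sum = np.zeros_like(e)
    for center, width, area in peaks:
        if width <= 0 or area < 0:
            raise ConfigError("peak width must be > 0 and area >= 0")
        if shape == "lorentzian":
            peak_sum += (area / np.pi) * width / ((e - center) ** 2 + width**2)
        else:
            peak_sum += (area / (width * np.sqrt(2.0 * np.pi))
                         * np.exp(-((e - center) ** 2) / (2.0 * width**2)))
    values = bg + peak_sum
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + noise_rel * rng.standard_normal(e.size))
        values = np.clip(values, 1e-12, None)
    table = ChannelTable(channel=Channel.ELASTIC, energies=e, values=values,
                         note="synthetic elastic+attachment test curve")
    truth = ResonanceTruth(energies=e, background=bg, peaks_total=peak_sum,
                           peak_params=tuple(peaks))
    return table, truth
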