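"""Channel-resolved integral cross-section sets: data model, I/O, interpolation.

The central container is :class:`CrossSectionSet`, one energy-gridded
:class:`ChannelTable` per scattering channel, in units of 1e-20 m^2 (= A^2).
A set is *self-consistent* when, at every energy, the sum of the open-channel
cross-sections (elastic, attachment, vibrational, electronic, ionization —
rotational excitation is deliberately excluded) reproduces the reference
total cross-section; :func:`validate_consistency` reports on that closure.

Interpolation between grid points is log-log linear by default: integral
cross-sections are smooth positive functions spanning decades in both energy
and magnitude, and a power-law segment between nodes preserves positivity
and monotonicity.  Where a bracketing value is zero (a channel opening, or a
blank table cell read as zero) the segment falls back to linear-linear.
No extrapolation is performed beyond the tabulated span.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import EnergyRangeError, SchemaError

__all__ = [
    "Channel",
    "ChannelTable",
    "CrossSectionSet",
    "ConsistencyReport",
    "interpolate",
    "sum_channels",
    "validate_consistency",
    "load_set",
    "read_channel_csv",
    "write_channel_csv",
]


class Channel(str, Enum):
    """Scattering channel labels."""

    ELASTIC = "elastic"
    ATTACHMENT = "attachment"
    VIBRATIONAL = "vibrational"
    ELECTRONIC = "electronic"
    IONIZATION = "ionization"
    TCS_EXPERIMENTAL = "tcs_experimental"
    TCS_REFERENCE = "tcs_reference"
    ROTATIONAL = "rotational"
    # derived intermediate, never part of a closure sum
    TOTAL_INELASTIC = "total_inelastic"


#: channels that enter the self-consistency (closure) sum
CLOSURE_CHANNELS = (
    Channel.ELASTIC,
    Channel.ATTACHMENT,
    Channel.VIBRATIONAL,
    Channel.ELECTRONIC,
    Channel.IONIZATION,
)


@dataclass(frozen=True)
class ChannelTable:
    """One channel's integral cross-section on a strictly increasing energy grid.

    Parameters
    ----------
    channel
        Channel label.
    energies
        Impact energies in eV; strictly increasing, all > 0.
    values
        Cross-sections in 1e-20 m^2; all >= 0.  Zeros mark a closed or
        negligible channel at that grid point.
    threshold
        Channel opening energy in eV (0 for elastic and total channels).
        Below threshold the channel contributes exactly 0.
    loglog
        Interpolate log-log between nodes (default); set False for
        linear-linear, e.g. for sub-eV resonant structure on a coarse grid.
    """

    channel: Channel
    energies: np.ndarray
    values: np.ndarray
    threshold: float = 0.0
    loglog: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channel", Channel(self.channel))
        if e.ndim != 1 or v.ndim != 1 or e.size != v.size:
            raise SchemaError(
                f"channel {self.channel.value}: energies and values must be "
                f"1-d arrays of equal length (got {e.shape} vs {v.shape})"
            )
        if e.size == 0:
            raise SchemaError(f"channel {self.channel.value}: empty table")
        if not np.all(e > 0):
            raise SchemaError(f"channel {self.channel.value}: energies must be > 0")
        if not np.all(np.diff(e) > 0):
            bad = int(np.flatnonzero(np.diff(e) <= 0)[0]) + 1
            raise SchemaError(
                f"channel {self.channel.value}: energies not strictly "
                f"increasing at row {bad}"
            )
        if not np.all(v >= 0):
            bad = int(np.flatnonzero(v < 0)[0])
            raise SchemaError(
                f"channel {self.channel.value}: negative cross-section at row {bad}"
            )
        if self.threshold < 0:
            raise SchemaError(f"channel {self.channel.value}: negative threshold")
        below = e < self.threshold
        if np.any(v[below] > 0):
            bad = int(np.flatnonzero(below & (v > 0))[0])
            raise SchemaError(
                f"channel {self.channel.value}: nonzero value below threshold "
                f"at row {bad}"
            )

    @property
    def emin(self) -> float:
        return float(self.energies[0])

    @property
    def emax(self) -> float:
        return float(self.energies[-1])

    def __call__(self, energy: float) -> float:
        return interpolate(self, energy)


def interpolate(table: ChannelTable, energy: float) -> float:
    """Evaluate a channel table at ``energy`` (eV).

    Grid points return the stored value exactly; between nodes the value is
    log-log (or linear, per the table flag) interpolated; below the channel
    threshold the result is 0; energies outside the tabulated span and above
    threshold raise :class:`EnergyRangeError`.
    """
    e = float(energy)
    if e < table.threshold:
        return 0.0
    if e < table.emin or e > table.emax:
        raise EnergyRangeError(
            f"E = {e} eV outside tabulated span "
            f"[{table.emin}, {table.emax}] eV for channel {table.channel.value}"
        )
    grid = table.energies
    i = int(np.searchsorted(grid, e))
    if i < grid.size and grid[i] == e:
        return float(table.values[i])
    lo, hi = i - 1, i
    e0, e1 = grid[lo], grid[hi]
    v0, v1 = table.values[lo], table.values[hi]
    if table.loglog and v0 > 0 and v1 > 0:
        t = (np.log(e) - np.log(e0)) / (np.log(e1) - np.log(e0))
        return float(np.exp((1 - t) * np.log(v0) + t * np.log(v1)))
    t = (e - e0) / (e1 - e0)
    return float((1 - t) * v0 + t * v1)


@dataclass
class CrossSectionSet:
    """A molecule's channel-keyed collection of integral cross-section tables."""

    molecule: str
    mass_u: float
    dipole_debye: float
    tables: dict[Channel, ChannelTable] = field(default_factory=dict)
    provenance: dict[Channel, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tables = {Channel(k): t for k, t in self.tables.items()}
        for ch, t in self.tables.items():
            if t.channel != ch:
                raise SchemaError(
                    f"table keyed {ch.value} labels itself {t.channel.value}"
                )

    def __contains__(self, channel: Channel | str) -> bool:
        return Channel(channel) in self.tables

    def __getitem__(self, channel: Channel | str) -> ChannelTable:
        return self.tables[Channel(channel)]

    def add(self, table: ChannelTable, note: str = "") -> None:
        if table.channel in self.tables:
            raise SchemaError(f"duplicate channel {table.channel.value}")
        self.tables[table.channel] = table
        if note:
            self.provenance[table.channel] = note

    @property
    def emin(self) -> float:
        return max(t.emin for t in self.tables.values())

    @property
    def emax(self) -> float:
        return min(t.emax for t in self.tables.values())


def sum_channels(xs_set: CrossSectionSet, energy: float) -> float:
    """Sum of open scattering channels at ``energy``.

    Covers elastic, attachment, vibrational, electronic and ionization;
    rotational excitation is excluded by construction (it is not part of the
    reference total in the self-consistency procedure).  Closed channels
    contribute 0.
    """
    if Channel.ELASTIC not in xs_set.tables:
        raise SchemaError("set has no elastic channel")
    total = 0.0
    for ch in CLOSURE_CHANNELS:
        table = xs_set.tables.get(ch)
        if table is not None:
            total += interpolate(table, energy)
    return total


@dataclass(frozen=True)
class ConsistencyRow:
    energy: float
    channel_sum: float
    reference: float
    discrepancy: float
    ok: bool


@dataclass(frozen=True)
class ConsistencyReport:
    tol: float
    rows: tuple[ConsistencyRow, ...]

    @property
    def failing_energies(self) -> tuple[float, ...]:
        return tuple(r.energy for r in self.rows if not r.ok)

    @property
    def all_ok(self) -> bool:
        return all(r.ok for r in self.rows)

    def to_text(self) -> str:
        lines = [f"{'E (eV)':>10} {'sum':>10} {'reference':>10} {'|diff|':>10} flag"]
        for r in self.rows:
            flag = "ok" if r.ok else "FAIL"
            lines.append(
                f"{r.energy:>10g} {r.channel_sum:>10.4g} {r.reference:>10.4g} "
                f"{r.discrepancy:>10.3g} {flag}"
            )
        lines.append(
            f"closure at tol {self.tol}: "
            + ("all rows pass" if self.all_ok
               else f"failing energies: {list(self.failing_energies)}")
        )
        return "\n".join(lines)


def validate_consistency(xs_set: CrossSectionSet, tol: float = 0.15) -> ConsistencyReport:
    """Check closure of the set against its reference TCS table.

    At every energy of the reference grid, records |channel sum - reference|
    and flags rows exceeding ``tol`` (1e-20 m^2).  Purely reporting; the data
    are never repaired.
    """
    if Channel.TCS_REFERENCE not in xs_set.tables:
        raise SchemaError("set has no tcs_reference channel")
    ref = xs_set.tables[Channel.TCS_REFERENCE]
    rows = []
    for e, r in zip(ref.energies, ref.values):
        s = sum_channels(xs_set, float(e))
        d = abs(s - float(r))
        rows.append(ConsistencyRow(float(e), s, float(r), d, d <= tol))
    return ConsistencyReport(tol=tol, rows=tuple(rows))


# ---------------------------------------------------------------------------
# CSV I/O.  Schema: comment header lines  "# molecule:", "# channel:",
# "# threshold_eV:", "# units: 1e-20 m2", optional "# note:", then the
# column header "energy_eV,sigma_1e-20_m2" and two numeric columns.
# ---------------------------------------------------------------------------

def write_channel_csv(table: ChannelTable, path: Path | str, molecule: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        if molecule:
            fh.write(f"# molecule: {molecule}\n")
        fh.write(f"# channel: {table.channel.value}\n")
        fh.write(f"# threshold_eV: {table.threshold:g}\n")
        fh.write("# units: 1e-20 m2\n")
        if table.note:
            fh.write(f"# note: {table.note}\n")
        fh.write("energy_eV,sigma_1e-20_m2\n")
        for e, v in zip(table.energies, table.values):
            fh.write(f"{e:.10g},{v:.10g}\n")


def _parse_channel_stream(stream: io.TextIOBase, name: str) -> ChannelTable:
    meta: dict[str, str] = {}
    energies: list[float] = []
    values: list[float] = []
    saw_header = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        if not saw_header:
            cols = [c.strip() for c in line.split(",")]
            if cols != ["energy_eV", "sigma_1e-20_m2"]:
                raise SchemaError(
                    f"{name}, line {lineno}: malformed column header {line!r}"
                )
            saw_header = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise SchemaError(f"{name}, line {lineno}: expected 2 columns")
        try:
            energies.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise SchemaError(f"{name}, line {lineno}: non-numeric entry") from exc
    if "channel" not in meta:
        raise SchemaError(f"{name}: missing '# channel:' header")
    if not energies:
        raise SchemaError(f"{name}: no data rows")
    try:
        channel = Channel(meta["channel"])
    except ValueError as exc:
        raise SchemaError(f"{name}: unknown channel {meta['channel']!r}") from exc
    try:
        return ChannelTable(
            channel=channel,
            energies=np.array(energies),
            values=np.array(values),
            threshold=float(meta.get("threshold_eV", 0.0)),
            note=meta.get("note", ""),
        )
    except SchemaError as exc:
        raise SchemaError(f"{name}: {exc}") from exc


def read_channel_csv(path: Path | str) -> ChannelTable:
    """Read one channel CSV; invariant violations raise SchemaError (never repaired)."""
    path = Path(path)
    with path.open() as fh:
        return _parse_channel_stream(fh, name=str(path))


def load_set(source: str | Path | Iterable[Path],
             molecule: str = "",
             mass_u: float = 0.0,
             dipole_debye: float = 0.0) -> CrossSectionSet:
    """Load a validated :class:`CrossSectionSet`.

    ``source`` is either a packaged fixture id (e.g. ``"1m5ni_recommended"``),
    a directory of channel CSVs, or an iterable of CSV paths.  Any invariant
    violation is rejected with :class:`SchemaError` naming the file and row.
    """
    if isinstance(source, str) and not Path(source).exists():
        from . import fixtures

        if source in fixtures.FIXTURE_IDS:
            return fixtures.load_fixture_set(source)
        raise SchemaError(f"unknown fixture id or missing path: {source!r}")
    if isinstance(source, (str, Path)):
        p = Path(source)
        paths = sorted(p.glob("*.csv")) if p.is_dir() else [p]
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise SchemaError(f"no channel CSV files found in {source!r}")
    out = CrossSectionSet(molecule=molecule, mass_u=mass_u, dipole_debye=dipole_debye)
    for p in paths:
        out.add(read_channel_csv(p))
    return out
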