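"""Event-by-event Monte Carlo electron transport through 1M5NI vapor.

Each primary electron is followed collision by collision: free paths are
drawn from exponential attenuation with the set's total cross-section,
the colliding channel is chosen proportionally to the open-channel integral
cross-sections (the same weights whose sum closes to the reference TCS),
and each channel applies its own energy-loss and deflection rules.
Secondary electrons from ionization are pushed on a stack and transported
identically; a track is the full cascade of one primary.

The published data set prescribes no transport conventions (energy-loss
spectra, secondary-energy sharing, thermalization), so all such rules live
in :class:`TransportConfig` with explicit defaults flagged as assumptions:
ionization energy 9.0 eV (placeholder, not a measured value), ionization
energy loss drawn from a 1/dE^2 binary-encounter-like tail on
[IP, (E+IP)/2], a fixed 0.15 eV vibrational quantum, electronic losses at
the channel threshold, and local deposition ("thermalization") of any
electron dropping below the 0.1 eV data floor.

Energy is conserved exactly per cascade: the primary energy equals the sum
of all collisional deposits (including the ionization potential per
ionization and the captured electron's energy at attachment) plus
thermalized sub-cutoff residuals, with secondaries' kinetic energy flowing
through their own deposits.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .ddcs import DDCSModel, sample_deflection
from .errors import ConfigError, DomainError
from .fragmentation import (AnionKineticEnergyModel, BranchingTable,
                            CationIntensityTable, sample_anion, sample_cation)
from .xs import CLOSURE_CHANNELS, Channel, CrossSectionSet, interpolate, sum_channels

__all__ = [
    "TransportConfig",
    "TransportModels",
    "TrackEvent",
    "TrackSummary",
    "Track",
    "Simulator",
    "step_free_path",
    "choose_channel",
    "run",
    "events_to_jsonl",
]

log = logging.getLogger(__name__)

_BALANCE_RTOL = 1e-6


@dataclass
class TransportConfig:
    """Run-level knobs for the track simulator (see module docstring)."""

    density_m3: float = 1e25
    cutoff_ev: float = 0.1                 # data-set floor
    ionization_energy_ev: float = 9.0      # assumption, not a measured value
    vibrational_loss_ev: float = 0.15      # fixed quantum per collision
    electronic_loss_ev: float = 4.0        # channel threshold
    k: float = 1.3
    seed: int = 0
    max_events_per_track: int = 100_000
    disabled_channels: frozenset[Channel] = frozenset()
    # terminate an electron once no energy-loss channel remains open: below
    # the lowest inelastic threshold an electron can only random-walk
    # elastically forever, so it is deposited locally ("thermalized")
    terminate_elastic_only: bool = True

    def __post_init__(self) -> None:
        if self.density_m3 <= 0:
            raise ConfigError("number density must be > 0")
        if self.cutoff_ev <= 0:
            raise ConfigError("energy cutoff must be > 0")
        if self.ionization_energy_ev <= 0:
            raise ConfigError("ionization energy must be > 0")
        self.disabled_channels = frozenset(Channel(c) for c in self.disabled_channels)


@dataclass
class TransportModels:
    """Physics providers the transport loop draws from."""

    elastic_dcs: Callable[[float, float], float]
    ddcs: DDCSModel
    anion_branching: BranchingTable | None = None
    anion_ke: AnionKineticEnergyModel = field(default_factory=AnionKineticEnergyModel)
    cation_intensities: CationIntensityTable | None = None
    elastic_dcs_is_fallback: bool = False


@dataclass
class TrackEvent:
    """One collision record along a track."""

    index: int
    electron_id: int
    position_m: tuple[float, float, float]
    energy_before_ev: float
    energy_after_ev: float
    channel: str
    theta_deg: float
    phi_deg: float
    products: tuple[tuple[str, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "electron_id": self.electron_id,
            "position_m": list(self.position_m),
            "energy_before_ev": self.energy_before_ev,
            "energy_after_ev": self.energy_after_ev,
            "channel": self.channel,
            "theta_deg": self.theta_deg,
            "phi_deg": self.phi_deg,
            "products": [list(p) for p in self.products],
        }


@dataclass
class TrackSummary:
    """Aggregates of one full cascade (primary plus its secondaries)."""

    primary_energy_ev: float
    path_length_m: float
    deposited_ev: float
    thermalized_ev: float
    truncated_residual_ev: float
    channel_counts: Counter
    fragments: Counter
    n_secondaries: int
    secondary_initial_ke_ev: float
    truncated: bool

    @property
    def energy_balance_rel(self) -> float:
        """Relative closure error of the per-track energy audit."""
        total = self.deposited_ev + self.thermalized_ev + self.truncated_residual_ev
        return abs(total - self.primary_energy_ev) / self.primary_energy_ev


@dataclass
class Track:
    events: list[TrackEvent]
    summary: TrackSummary


def step_free_path(energy: float, xs_set: CrossSectionSet,
                   config: TransportConfig, rng: np.random.Generator) -> float:
    """Exponential free path s = -ln(u) / (n sigma_tot), in metres."""
    sigma = sum_channels(xs_set, energy) * 1e-20  # m^2
    if sigma <= 0:
        raise DomainError(f"total cross-section vanishes at {energy} eV")
    u = 1.0 - rng.random()  # uniform on (0, 1]
    return float(-np.log(u) / (config.density_m3 * sigma))


def choose_channel(energy: float, xs_set: CrossSectionSet,
                   rng: np.random.Generator,
                   disabled: frozenset[Channel] = frozenset()) -> Channel:
    """Draw the colliding channel with probability sigma_ch / sigma_tot."""
    channels, weights = [], []
    for ch in CLOSURE_CHANNELS:
        if ch in disabled:
            continue
        table = xs_set.tables.get(ch)
        if table is None:
            continue
        w = interpolate(table, energy)
        if w > 0:
            channels.append(ch)
            weights.append(w)
    if not channels:
        raise DomainError(f"no open channels at {energy} eV")
    w = np.asarray(weights)
    idx = rng.choice(len(channels), p=w / w.sum())
    return channels[idx]


def _rotate(direction: np.ndarray, theta_rad: float, phi_rad: float) -> np.ndarray:
    """Rotate a unit vector by polar theta about itself with azimuth phi."""
    d = direction
    if abs(d[2]) < 0.999999:
        ref = np.array([0.0, 0.0, 1.0])
    else:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    out = (np.cos(theta_rad) * d
           + np.sin(theta_rad) * (np.cos(phi_rad) * u + np.sin(phi_rad) * v))
    return out / np.linalg.norm(out)


def _sample_elastic_angle(dcs: Callable[[float, float], float], energy: float,
                          rng: np.random.Generator, n_mu: int = 1001) -> float:
    """Inverse-CDF draw of a polar angle (degrees) from an elastic DCS."""
    sampler = getattr(dcs, "sample_mu", None)
    if sampler is not None:
        mu_s = float(sampler(energy, rng))
        return float(np.degrees(np.arccos(np.clip(mu_s, -1.0, 1.0))))
    from .ddcs import _eval_dcs

    mu = np.linspace(-1.0, 1.0, n_mu)
    pdf = _eval_dcs(dcs, energy, np.degrees(np.arccos(mu)))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                           * np.diff(mu))])
    if cdf[-1] <= 0:
        return 0.0
    cdf /= cdf[-1]
    mu_s = float(np.interp(rng.random(), cdf, mu))
    return float(np.degrees(np.arccos(np.clip(mu_s, -1.0, 1.0))))


def _sample_ionization_loss(energy: float, ip: float,
                            rng: np.random.Generator) -> float:
    """Total ionization energy loss from a 1/dE^2 density on [IP, (E+IP)/2]."""
    lo = ip
    hi = (energy + ip) / 2.0
    if hi <= lo:
        return min(energy, ip)
    u = rng.random()
    # inverse CDF of p(x) ~ 1/x^2 on [lo, hi]
    return float(1.0 / (1.0 / lo - u * (1.0 / lo - 1.0 / hi)))


@dataclass
class _ElectronState:
    eid: int
    energy: float
    position: np.ndarray
    direction: np.ndarray


class Simulator:
    """Event-by-event cascade simulator bound to a cross-section set."""

    def __init__(self, xs_set: CrossSectionSet, config: TransportConfig,
                 models: TransportModels) -> None:
        self.xs_set = xs_set
        self.config = config
        self.models = models
        if models.elastic_dcs_is_fallback:
            log.info("elastic angular sampling uses the synthetic "
                     "screened-Coulomb fallback DCS")

    # -- single-collision physics ------------------------------------------

    def apply_collision(self, state: _ElectronState, channel: Channel,
                        rng: np.random.Generator, event_index: int,
                        ) -> tuple[TrackEvent, list[_ElectronState], float]:
        """Apply one collision; returns (event, spawned secondaries, deposit)."""
        cfg, models = self.config, self.models
        e_before = state.energy
        phi = float(np.degrees(rng.uniform(0.0, 2.0 * np.pi)))
        products: list[tuple[str, float]] = []
        secondaries: list[_ElectronState] = []
        deposit = 0.0
        terminated = False

        if channel is Channel.ELASTIC:
            theta = _sample_elastic_angle(models.elastic_dcs, e_before, rng)
            e_after = e_before  # recoil neglected (mass ratio ~ 1/230000)
        elif channel in (Channel.VIBRATIONAL, Channel.ELECTRONIC):
            loss = (cfg.vibrational_loss_ev if channel is Channel.VIBRATIONAL
                    else cfg.electronic_loss_ev)
            if loss > e_before:
                log.warning("%s loss %.3g eV exceeds electron energy %.3g eV; "
                            "truncating", channel.value, loss, e_before)
                loss = e_before
            theta = sample_deflection(models.ddcs, e_before, loss, rng)
            e_after = e_before - loss
            deposit = loss
        elif channel is Channel.IONIZATION:
            ip = cfg.ionization_energy_ev
            loss = _sample_ionization_loss(e_before, ip, rng)
            if loss > e_before:
                log.warning("ionization loss exceeds available energy; truncating")
                loss = e_before
            theta = sample_deflection(models.ddcs, e_before, loss, rng)
            e_after = e_before - loss
            secondary_ke = max(loss - ip, 0.0)
            deposit = loss - secondary_ke  # the ionization potential
            if models.cation_intensities is not None:
                cation = sample_cation(models.cation_intensities, rng)
                products.append((cation.label, 0.0))
            secondaries.append(_ElectronState(
                eid=-1,  # assigned by the caller
                energy=secondary_ke,
                position=state.position.copy(),
                direction=_isotropic_direction(rng),
            ))
        elif channel is Channel.ATTACHMENT:
            theta = 0.0
            e_after = 0.0
            deposit = e_before  # electron captured: its energy stays local
            terminated = True
            if models.anion_branching is not None:
                anion = sample_anion(models.anion_branching, e_before, rng)
                ke, _dir = models.anion_ke.sample(anion, rng)
                products.append((anion.label, ke))
        else:
            raise DomainError(f"channel {channel.value} is not collidable")

        if not terminated:
            state.direction = _rotate(state.direction, np.radians(theta),
                                      np.radians(phi))
        state.energy = e_after
        event = TrackEvent(
            index=event_index,
            electron_id=state.eid,
            position_m=tuple(state.position),
            energy_before_ev=e_before,
            energy_after_ev=e_after,
            channel=channel.value,
            theta_deg=theta,
            phi_deg=phi,
            products=tuple(products),
        )
        return event, secondaries, deposit

    def _loss_channel_open(self, energy: float) -> bool:
        """True if any channel that removes electron energy is open."""
        for ch in CLOSURE_CHANNELS:
            if ch is Channel.ELASTIC or ch in self.config.disabled_channels:
                continue
            table = self.xs_set.tables.get(ch)
            if table is not None and interpolate(table, energy) > 0:
                return True
        return False

    # -- cascade loop -------------------------------------------------------

    def simulate_track(self, primary_energy: float,
                       rng: np.random.Generator) -> Track:
        cfg = self.config
        events: list[TrackEvent] = []
        counts: Counter = Counter()
        fragments: Counter = Counter()
        deposited = 0.0
        thermalized = 0.0
        truncated_residual = 0.0
        path_length = 0.0
        n_secondaries = 0
        secondary_ke = 0.0
        truncated = False
        next_eid = 1

        stack = [_ElectronState(eid=0, energy=float(primary_energy),
                                position=np.zeros(3),
                                direction=np.array([0.0, 0.0, 1.0]))]
        event_index = 0
        while stack:
            electron = stack.pop()
            while True:
                if electron.energy < cfg.cutoff_ev:
                    thermalized += electron.energy
                    break
                if cfg.terminate_elastic_only and not self._loss_channel_open(
                        electron.energy):
                    thermalized += electron.energy
                    break
                if event_index >= cfg.max_events_per_track:
                    truncated = True
                    truncated_residual += electron.energy
                    break
                step = step_free_path(electron.energy, self.xs_set, cfg, rng)
                electron.position = electron.position + step * electron.direction
                path_length += step
                channel = choose_channel(electron.energy, self.xs_set, rng,
                                         cfg.disabled_channels)
                event, spawned, deposit = self.apply_collision(
                    electron, channel, rng, event_index)
                event_index += 1
                events.append(event)
                counts[channel.value] += 1
                deposited += deposit
                for label, _ke in event.products:
                    fragments[label] += 1
                for sec in spawned:
                    sec.eid = next_eid
                    next_eid += 1
                    n_secondaries += 1
                    secondary_ke += sec.energy
                    stack.append(sec)
                if channel is Channel.ATTACHMENT:
                    break
            if truncated and event_index >= cfg.max_events_per_track:
                # drain remaining stack into the residual audit
                for leftover in stack:
                    truncated_residual += leftover.energy
                stack.clear()

        summary = TrackSummary(
            primary_energy_ev=float(primary_energy),
            path_length_m=path_length,
            deposited_ev=deposited,
            thermalized_ev=thermalized,
            truncated_residual_ev=truncated_residual,
            channel_counts=counts,
            fragments=fragments,
            n_secondaries=n_secondaries,
            secondary_initial_ke_ev=secondary_ke,
            truncated=truncated,
        )
        if summary.energy_balance_rel > _BALANCE_RTOL:
            log.warning("energy audit failed: relative error %.3g",
                        summary.energy_balance_rel)
        return Track(events=events, summary=summary)

    def run(self, primary_energy: float, n_primaries: int) -> list[Track]:
        """Simulate ``n_primaries`` independent cascades (seed-reproducible)."""
        rng = np.random.default_rng(self.config.seed)
        return [self.simulate_track(primary_energy, rng)
                for _ in range(n_primaries)]


def _isotropic_direction(rng: np.random.Generator) -> np.ndarray:
    mu = rng.uniform(-1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - mu * mu)
    return np.array([s * np.cos(phi), s * np.sin(phi), mu])


def run(config: TransportConfig, xs_set: CrossSectionSet,
        models: TransportModels, primary_energy: float,
        n_primaries: int) -> list[Track]:
    """Functional front door over :class:`Simulator`."""
    return Simulator(xs_set, config, models).run(primary_energy, n_primaries)


def events_to_jsonl(tracks: Iterable[Track]) -> str:
    """Serialize every event of every track as JSON Lines."""
    lines = []
    for ti, track in enumerate(tracks):
        for ev in track.events:
            rec = {"track": ti, **ev.to_dict()}
            lines.append(json.dumps(rec))
    return "\n".join(lines) + ("\n" if lines else "")
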