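"""Self-consistency engine for building a recommended cross-section set.

The closure pipeline works in four steps:

1. Missing-angle correction: a transmission-measured total cross-section
   misses elastic flux scattered into the detector's forward acceptance
   cone; the correction integrates the differential elastic cross-section
   over that cone and is added to the measured TCS.
2. Total inelastic residual: pointwise subtraction of the pure integral
   elastic cross-section from the corrected reference TCS.
3. Resonance extraction: the low-energy "elastic plus attachment" curve is
   split into a smooth background (pure elastic) and a resonant excess
   (electron attachment) by an iterative-clipping smooth fit; peaks above a
   cutoff (default 10 eV) with no experimental confirmation are treated as
   pseudo-resonances - artifacts of omitting inelastic channels from the
   elastic calculation - and removed from the attachment.
4. Threshold-constrained partition: the remaining inelastic residual (after
   removing ionization and attachment) is split between vibrational and
   electronic excitation by per-energy weights anchored at calibration
   energies, with the electronic share forced to zero below its threshold;
   the two parts always re-sum to the residual exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, signal

from .errors import ConfigError, DomainError, InsufficientDataError
from .xs import Channel, ChannelTable, interpolate

__all__ = [
    "AcceptanceGeometry",
    "ResonanceDecomposition",
    "PartitionSpec",
    "missing_angle_correction",
    "derive_total_inelastic",
    "extract_resonances",
    "partition_inelastic",
    "calibrate_partition",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcceptanceGeometry:
    """Detector acceptance cone(s) for a transmission TCS measurement.

    ``theta_acc_deg`` is the forward cutoff; scattering below it is not
    resolved from the unscattered beam.  An optional backward cutoff models
    detectors also blind near 180 degrees.
    """

    theta_acc_deg: float
    theta_back_deg: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.theta_acc_deg < 90:
            raise ConfigError("forward acceptance angle must be in [0, 90)")
        if self.theta_back_deg is not None and not 90 < self.theta_back_deg <= 180:
            raise ConfigError("backward cutoff must be in (90, 180]")


def missing_angle_correction(
    dcs: Callable[[float], float],
    geometry: AcceptanceGeometry,
) -> float:
    """Elastic flux missed inside the acceptance cone(s), 1e-20 m^2.

    ``dcs(theta_deg)`` is the differential elastic cross-section at the
    measurement energy (1e-20 m^2/sr).  Returns
    2 pi * int_0^theta_acc dcs(theta) sin(theta) dtheta, plus the analogous
    backward integral if configured.  The caller adds the result to the
    measured TCS to obtain the corrected reference value.
    """

    def integrand(theta_rad: float) -> float:
        value = dcs(np.degrees(theta_rad))
        if value < 0:
            raise DomainError(f"negative DCS at {np.degrees(theta_rad):.2f} deg")
        return value * np.sin(theta_rad)

    total = 0.0
    if geometry.theta_acc_deg > 0:
        val, _ = integrate.quad(integrand, 0.0,
                                np.radians(geometry.theta_acc_deg), limit=200)
        total += 2.0 * np.pi * val
    if geometry.theta_back_deg is not None:
        val, _ = integrate.quad(integrand, np.radians(geometry.theta_back_deg),
                                np.pi, limit=200)
        total += 2.0 * np.pi * val
    return total


def derive_total_inelastic(reference: ChannelTable,
                           elastic: ChannelTable,
                           grid: Sequence[float] | None = None) -> ChannelTable:
    """Total inelastic cross-section: reference (TCS+MA) minus pure elastic.

    Evaluated pointwise on ``grid`` (default: the reference grid restricted
    to the elastic table's span).  Small negative differences - expected
    from measurement noise - are clamped to 0 and logged.
    """
    if grid is None:
        lo = max(reference.emin, elastic.emin)
        hi = min(reference.emax, elastic.emax)
        grid = reference.energies[(reference.energies >= lo)
                                  & (reference.energies <= hi)]
        if len(grid) == 0:
            raise DomainError("reference and elastic tables have disjoint spans")
    e = np.asarray(grid, dtype=float)
    diff = np.array([interpolate(reference, x) - interpolate(elastic, x)
                     for x in e])
    negative = diff < 0
    if np.any(negative):
        log.warning("elastic exceeds reference at E = %s eV; clamping to 0",
                    list(np.round(e[negative], 4)))
        diff = np.where(negative, 0.0, diff)
    return ChannelTable(channel=Channel.TOTAL_INELASTIC, energies=e, values=diff,
                        note="total inelastic (reference minus pure elastic)")


@dataclass(frozen=True)
class ResonanceDecomposition:
    """Smooth-background + resonant-excess split of a low-energy curve.

    ``background`` is the pure elastic part, ``attachment`` the resonant
    excess (zeroed wherever a peak is flagged as a pseudo-resonance).
    ``peaks`` lists (center eV, height 1e-20 m^2, flagged_pseudo).
    """

    input_curve: ChannelTable
    background: ChannelTable
    attachment: ChannelTable
    peaks: tuple[tuple[float, float, bool], ...]

    def attachment_area(self, emax: float | None = None) -> float:
        """Trapezoidal integral of the attachment excess (eV * 1e-20 m^2)."""
        e = self.attachment.energies
        v = self.attachment.values
        if emax is not None:
            keep = e <= emax
            e, v = e[keep], v[keep]
        return float(np.trapezoid(v, e))


def extract_resonances(curve: ChannelTable,
                       pseudo_cutoff: float = 10.0,
                       clip_band: float = 2.5,
                       rel_floor: float = 0.01,
                       max_iter: int = 20,
                       degree: int = 4) -> ResonanceDecomposition:
    """Split an elastic+attachment curve into smooth background and resonances.

    The pure elastic cross-section follows a smooth energy dependence, so a
    low-order polynomial (rigid enough to bridge the clipped-out resonance
    regions) is fitted in log-log coordinates with iterative clipping:
    residual maxima that clear both ``clip_band`` robust noise scales
    (estimated from the *negative* residuals, which resonances cannot
    contaminate) and a relative floor of ``rel_floor`` times the local
    background are significant peaks; the contiguous positive-residual
    support of each is removed and the fit repeated until the retained
    point set stabilizes (removal only, at most ``max_iter`` rounds).
    The attachment is the non-negative excess over the converged
    background; a curve with no significant peak decomposes to exactly
    zero attachment.  Peaks centred above ``pseudo_cutoff`` (eV) are
    flagged as pseudo-resonances and their excess is removed from the
    attachment.

    Resonances much broader than the background's own curvature scale
    (widths well above ~0.5 eV near a few eV) are partially absorbed into
    the background; see the package methods notes.
    """
    e = curve.energies
    y = curve.values
    if e.size < 6:
        raise InsufficientDataError(
            f"resonance extraction needs >= 6 grid points, got {e.size}")
    if np.any(y <= 0):
        raise DomainError("curve values must be > 0 for log-log fitting")
    x = np.log(e)
    ly = np.log(y)
    deg = min(degree, e.size - 2)
    keep = np.ones(e.size, dtype=bool)
    fit_vals = ly.copy()
    idx: np.ndarray = np.array([], dtype=int)
    for _ in range(max_iter):
        poly = np.polynomial.Polynomial.fit(x[keep], ly[keep],
                                            min(deg, int(keep.sum()) - 2))
        fit_vals = poly(x)
        resid = ly - fit_vals
        neg = resid[keep & (resid <= 0)]
        sigma = 1.4826 * float(np.median(np.abs(neg))) if neg.size else 0.0
        thresh = max(clip_band * max(sigma, 1e-9), np.log1p(rel_floor))
        idx, _props = signal.find_peaks(resid, height=thresh)
        mask = np.zeros(e.size, dtype=bool)
        for i in idx:
            j = i
            while j >= 0 and resid[j] > 0:
                mask[j] = True
                j -= 1
            j = i + 1
            while j < e.size and resid[j] > 0:
                mask[j] = True
                j += 1
        new_keep = keep & ~mask
        if np.array_equal(new_keep, keep) or new_keep.sum() < deg + 2:
            break
        keep = new_keep
    background_vals = np.exp(fit_vals)
    if idx.size:
        excess = np.clip(y - background_vals, 0.0, None)
    else:
        excess = np.zeros_like(y)

    peaks = []
    for i in idx:
        center = float(e[i])
        height = float(max(y[i] - background_vals[i], 0.0))
        flagged = center > pseudo_cutoff
        peaks.append((center, height, flagged))
    # pseudo-resonances above the cutoff are artifacts: drop their excess
    attachment_vals = np.where(e > pseudo_cutoff, 0.0, excess)

    background = ChannelTable(channel=Channel.ELASTIC, energies=e,
                              values=background_vals,
                              note="smooth background (pure elastic)")
    attachment = ChannelTable(channel=Channel.ATTACHMENT, energies=e,
                              values=attachment_vals,
                              note="resonant excess (electron attachment)")
    return ResonanceDecomposition(input_curve=curve, background=background,
                                  attachment=attachment, peaks=tuple(peaks))


@dataclass
class PartitionSpec:
    """Per-energy split of the inelastic residual into vibrational/electronic.

    ``anchor_energies``/``anchor_weights`` give the electronic fraction
    w_e(E) at calibration energies; between anchors w_e is interpolated
    linearly in log E, outside them the nearest anchor applies, and below
    ``electronic_threshold_ev`` it is forced to 0.
    """

    vibrational_threshold_ev: float = 0.7
    electronic_threshold_ev: float = 4.0
    anchor_energies: np.ndarray = field(default_factory=lambda: np.array([4.0]))
    anchor_weights: np.ndarray = field(default_factory=lambda: np.array([0.0]))

    def __post_init__(self) -> None:
        self.anchor_energies = np.asarray(self.anchor_energies, dtype=float)
        self.anchor_weights = np.asarray(self.anchor_weights, dtype=float)
        if self.vibrational_threshold_ev >= self.electronic_threshold_ev:
            raise ConfigError("vibrational threshold must lie below electronic")
        if self.anchor_energies.shape != self.anchor_weights.shape:
            raise ConfigError("anchor energies and weights must align")
        if np.any((self.anchor_weights < 0) | (self.anchor_weights > 1)):
            raise ConfigError("anchor weights must lie in [0, 1]")
        if not np.all(np.diff(self.anchor_energies) > 0):
            raise ConfigError("anchor energies must be strictly increasing")

    def electronic_weight(self, energy: float) -> float:
        """w_e(E): electronic share of the residual at ``energy``."""
        e = float(energy)
        if e < self.electronic_threshold_ev:
            return 0.0
        w = float(np.interp(np.log(e), np.log(self.anchor_energies),
                            self.anchor_weights))
        return min(max(w, 0.0), 1.0)


def partition_inelastic(residual: ChannelTable,
                        spec: PartitionSpec) -> tuple[ChannelTable, ChannelTable]:
    """Split the post-ionization, post-attachment inelastic residual.

    Returns ``(vibrational, electronic)`` tables on the residual grid with
    electronic = w_e(E) * residual and vibrational the exact remainder
    (residual minus electronic), so their sum reconstructs the residual to
    within one rounding unit at every grid energy.
    """
    e = residual.energies
    r = residual.values
    w = np.array([spec.electronic_weight(x) for x in e])
    electronic = w * r
    vibrational = r - electronic
    vib = ChannelTable(channel=Channel.VIBRATIONAL, energies=e,
                       values=vibrational,
                       threshold=spec.vibrational_threshold_ev,
                       note="residual partition, vibrational share")
    ele = ChannelTable(channel=Channel.ELECTRONIC, energies=e,
                       values=electronic,
                       threshold=spec.electronic_threshold_ev,
                       note="residual partition, electronic share")
    return vib, ele


def calibrate_partition(vibrational: ChannelTable,
                        electronic: ChannelTable,
                        vibrational_threshold_ev: float = 0.7,
                        electronic_threshold_ev: float = 4.0) -> PartitionSpec:
    """Anchor partition weights from tabulated vibrational/electronic columns.

    At each energy where the two channels' sum is positive the electronic
    fraction is recorded as an anchor weight; this makes the (otherwise
    unspecified) sampling procedure behind the published partition explicit
    and reusable.
    """
    if not np.array_equal(vibrational.energies, electronic.energies):
        raise ConfigError("vibrational and electronic grids must match")
    total = vibrational.values + electronic.values
    keep = total > 0
    if not np.any(keep):
        raise ConfigError("no energies with a positive inelastic residual")
    weights = electronic.values[keep] / total[keep]
    return PartitionSpec(
        vibrational_threshold_ev=vibrational_threshold_ev,
        electronic_threshold_ev=electronic_threshold_ev,
        anchor_energies=vibrational.energies[keep],
        anchor_weights=weights,
    )
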