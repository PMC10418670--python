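"""Semiempirical double-differential inelastic cross-section model.

The model factorizes the DDCS into the elastic angular shape times a linear
attenuation in the fractional energy transfer:

    d^2 sigma / (dOmega dDeltaE)  ~  (dsigma/dOmega)_el(E, theta) * (1 - k DeltaE / E)

with a single dimensionless parameter ``k`` calibrated per molecule from
measured angular distributions at a representative (E, DeltaE); for 1M5NI
the calibrated value is k = 1.3 (measured at E = 97 eV, DeltaE = 30 eV).
The relation is a proportionality: absolute scale is fixed by normalizing
the double integral to the relevant channel's integral cross-section, which
is the only closure consistent with a self-consistent set.  Negative values
of the attenuation factor (k DeltaE > E) are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, DomainError, NormalizationError

__all__ = ["DDCSModel", "NormalizedDDCS", "ddcs_shape", "normalize",
           "sample_deflection", "estimate_k", "KEstimate"]

DEFAULT_K = 1.3  # calibrated for 1M5NI

#: quadrature grid size over mu = cos(theta)
_N_MU = 2001


def _eval_dcs(dcs, energy: float, theta_deg: np.ndarray) -> np.ndarray:
    """Evaluate a DCS provider on an angle array (vectorized when possible)."""
    try:
        out = np.asarray(dcs(energy, theta_deg), dtype=float)
        if out.shape != theta_deg.shape:
            raise TypeError
    except (TypeError, ValueError):
        out = np.array([float(dcs(energy, t)) for t in theta_deg])
    return np.clip(out, 0.0, None)


@dataclass
class DDCSModel:
    """Eq-style semiempirical DDCS: elastic DCS provider plus weight ``k``.

    ``elastic_dcs(E_eV, theta_deg)`` must return 1e-20 m^2/sr.
    """

    elastic_dcs: Callable[[float, float], float]
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigError("k must be > 0")


def ddcs_shape(model: DDCSModel, energy: float, delta_e: float,
               theta_deg: float) -> float:
    """Unnormalized DDCS shape at (E, DeltaE, theta).

    Non-negative and non-increasing in DeltaE at fixed (E, theta); the
    attenuation factor is clamped at zero once k DeltaE exceeds E.
    """
    if delta_e <= 0 or delta_e > energy:
        raise DomainError(
            f"transferred energy must satisfy 0 < dE <= E "
            f"(got dE={delta_e}, E={energy})")
    if not 0 <= theta_deg <= 180:
        raise DomainError("theta must be in [0, 180] degrees")
    factor = max(0.0, 1.0 - model.k * delta_e / energy)
    return max(0.0, float(model.elastic_dcs(energy, theta_deg))) * factor


@dataclass
class NormalizedDDCS:
    """Tabulated d^2 sigma / dOmega dDeltaE on a (DeltaE, mu) grid."""

    energy: float
    delta_e_grid: np.ndarray       # eV
    mu_grid: np.ndarray            # cos(theta), increasing
    values: np.ndarray             # (n_dE, n_mu), 1e-20 m^2 / sr / eV

    def integral(self) -> float:
        """Double integral over solid angle and the DeltaE grid."""
        per_de = 2.0 * np.pi * np.trapezoid(self.values, self.mu_grid, axis=1)
        return float(np.trapezoid(per_de, self.delta_e_grid))


def normalize(model: DDCSModel, energy: float, sigma_channel: float,
              delta_e_grid: Sequence[float], n_mu: int = _N_MU) -> NormalizedDDCS:
    """Close the proportionality: scale the shape so its double integral over
    solid angle and the DeltaE grid equals ``sigma_channel`` (1e-20 m^2)."""
    de = np.asarray(delta_e_grid, dtype=float)
    if de.ndim != 1 or de.size < 2 or not np.all(np.diff(de) > 0):
        raise DomainError("DeltaE grid must be increasing with >= 2 points")
    if de[0] <= 0 or de[-1] > energy:
        raise DomainError("DeltaE grid must lie within (0, E]")
    if sigma_channel < 0:
        raise DomainError("channel cross-section must be >= 0")
    mu = np.linspace(-1.0, 1.0, n_mu)
    theta = np.degrees(np.arccos(mu))
    angular = _eval_dcs(model.elastic_dcs, energy, theta)
    factors = np.clip(1.0 - model.k * de / energy, 0.0, None)
    shape = factors[:, None] * angular[None, :]
    raw = NormalizedDDCS(energy, de, mu, shape).integral()
    if sigma_channel == 0.0:
        return NormalizedDDCS(energy, de, mu, np.zeros_like(shape))
    if raw <= 0:
        raise NormalizationError(
            "DDCS shape integrates to zero (fully clamped) but the channel "
            f"cross-section is {sigma_channel}")
    return NormalizedDDCS(energy, de, mu, shape * (sigma_channel / raw))


def sample_deflection(model: DDCSModel, energy: float, delta_e: float,
                      rng: np.random.Generator, n_mu: int = _N_MU) -> float:
    """Draw a polar deflection angle (degrees) at (E, DeltaE).

    Inverse-CDF sampling over mu = cos(theta) of the normalized angular
    profile; the energy-transfer factor is angle-independent so the profile
    is the elastic DCS itself.  Azimuth is the caller's to draw uniformly.
    """
    # validate the (E, dE) pair exactly as ddcs_shape does
    ddcs_shape(model, energy, delta_e, 0.0)
    sampler = getattr(model.elastic_dcs, "sample_mu", None)
    if sampler is not None:
        mu_sample = float(sampler(energy, rng))
        return float(np.degrees(np.arccos(np.clip(mu_sample, -1.0, 1.0))))
    mu = np.linspace(-1.0, 1.0, n_mu)
    theta = np.degrees(np.arccos(mu))
    pdf = _eval_dcs(model.elastic_dcs, energy, theta)
    if not np.any(pdf > 0):
        raise NormalizationError("elastic DCS is identically zero")
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                           * np.diff(mu))])
    cdf /= cdf[-1]
    u = rng.random()
    mu_sample = float(np.interp(u, cdf, mu))
    return float(np.degrees(np.arccos(np.clip(mu_sample, -1.0, 1.0))))


@dataclass(frozen=True)
class KEstimate:
    k: float
    k_stderr: float
    scale: float

    def within(self, true_k: float, n_sigma: float = 2.0) -> bool:
        return abs(self.k - true_k) <= n_sigma * self.k_stderr


def estimate_k(theta_deg: Sequence[float], intensity: Sequence[float],
               uncertainty: Sequence[float] | None,
               energy: float, delta_e: float | Sequence[float],
               elastic_dcs: Callable[[float, float], float]) -> KEstimate:
    """Weighted least-squares fit of ``k`` from measured DDCS intensities.

    The model is I_i = c * g(theta_i) * (1 - k dE_i / E) with g the elastic
    DCS.  Identifiability depends on the measurement layout:

    * a single transferred energy (scalar ``delta_e``, the typical angular
      scan): the attenuation factor is the same at every angle, so a free
      scale would absorb it entirely.  The intensities must then be
      absolute (same units as ``elastic_dcs``); the fit fixes c = 1 and
      solves for k alone.
    * several transferred energies (array ``delta_e`` per point, not all
      equal): (c, k) are fitted jointly via the linearization
      (a, b) = (c, c*k), I = a g - b g dE/E, and k = b/a with a
      delta-method standard error.  This mode is invariant to rescaling
      all intensities.
    """
    th = np.asarray(theta_deg, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if th.size < 3:
        raise DomainError("need at least 3 angles to fit k")
    de = np.broadcast_to(np.asarray(delta_e, dtype=float), th.shape)
    if np.any(de < 0) or (np.all(de == 0)):
        raise DomainError("k is unidentifiable at DeltaE = 0 "
                          "(the attenuation factor is constant)")
    if uncertainty is None:
        sig = np.ones_like(y)
    else:
        sig = np.asarray(uncertainty, dtype=float)
        if np.any(sig <= 0):
            raise DomainError("uncertainties must be > 0")
    g = np.array([max(0.0, float(elastic_dcs(energy, t))) for t in th])
    if not np.any(g > 0):
        raise DomainError("elastic DCS vanishes at all supplied angles")
    w = 1.0 / sig
    single_transfer = np.all(de == de[0])
    if single_transfer:
        # absolute intensities, c = 1:  g - I = k * (g dE / E)
        x = g * de / energy
        target = g - y
        xw, tw = x * w, target * w
        denom = float(xw @ xw)
        if denom == 0:
            raise DomainError("degenerate fit: zero design norm")
        k_hat = float(xw @ tw) / denom
        resid = tw - k_hat * xw
        dof = max(th.size - 1, 1)
        s2 = 1.0 if uncertainty is not None else float(resid @ resid) / dof
        return KEstimate(k=k_hat, k_stderr=float(np.sqrt(s2 / denom)),
                         scale=1.0)
    X = np.column_stack([g, -g * de / energy])
    Xw = X * w[:, None]
    yw = y * w
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    a, b = beta
    if a == 0:
        raise DomainError("degenerate fit: zero overall scale")
    dof = max(th.size - 2, 1)
    resid = yw - Xw @ beta
    s2 = 1.0 if uncertainty is not None else float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    k_hat = b / a
    grad = np.array([-b / a**2, 1.0 / a])
    k_var = float(grad @ cov @ grad)
    return KEstimate(k=float(k_hat), k_stderr=float(np.sqrt(max(k_var, 0.0))),
                     scale=float(a))
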