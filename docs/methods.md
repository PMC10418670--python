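# Methods and modelling notes

This note records what the package actually computes, the assumptions
behind each component, and the choices made where the underlying
measurements or published tables leave the design open.

## Units and conventions

Cross-sections are carried internally in 10⁻²⁰ m², identical to Å²;
energies in eV; angles in degrees at the API surface (radians internally
for quadrature). Channel tables live on strictly increasing energy grids
and a channel contributes exactly zero below its opening (threshold)
energy.

## The cross-section set and its interpolation

The packaged 1M5NI set spans 0.1–1000 eV with eight channels: elastic,
electron attachment, vibrational excitation, electronic excitation,
ionization, the experimental and reference (missing-angle-corrected)
totals, and — outside the closure sum — dipole rotational excitation.

Interpolation between grid nodes is log–log linear: integral
cross-sections here are positive, smooth, and span more than three decades
in both axes, and a power-law segment is exact for the asymptotic
high-energy behaviour while always staying between the bracketing values.
Where either bracketing value is zero (a channel opening, or a blank table
cell recorded as zero) the segment falls back to linear–linear, which
preserves positivity and monotonicity. Linear interpolation throughout is
available per table (`loglog=False`) for sub-eV resonant structure on a
coarse grid. No extrapolation is performed: energies outside the tabulated
span raise rather than guess, and transport inherits that refusal.

Blank cells in the published recommended table are read as "closed or
negligible" and stored as zeros; the per-channel `threshold_eV` header
distinguishes zero-by-threshold from zero-by-omission. The ionization
opening is set at its first tabulated entry (15 eV); the transport
configuration carries a separate ionization potential (below).

### Closure

`validate_consistency` sums the five physical channels on the reference
grid and compares to the reference total. In the packaged set all rows
close within 0.15×10⁻²⁰ m² except 70 eV, where the printed channel
entries (33.6 + 11.5 + 12.5 = 57.6) disagree with the printed total (66.4)
and the electronic-excitation entry breaks the monotone trend between 50
and 100 eV. The row is reported as a flagged anomaly and never repaired.
A second known inconsistency: above ~150 eV the printed corrected-TCS
reference and the recommended-set totals drift apart by up to
0.35×10⁻²⁰ m² (e.g. 36.12 vs 35.9 at 200 eV), so reconstructions of the
partition against the reference table are only asserted up to 150 eV.

## Missing-angle correction

A transmission-beam TCS cannot distinguish electrons elastically scattered
into the forward acceptance cone from the unscattered beam. The correction
integrates a user-supplied elastic DCS over that cone,
Δσ = 2π ∫₀^θacc dσ/dΩ sinθ dθ (plus an analogous backward cone when
configured), by adaptive quadrature; tests pin it against closed forms for
isotropic and polynomial-in-cosθ shapes to six figures.

## Resonance extraction

The low-energy "elastic plus attachment" curve is decomposed into a smooth
background (pure elastic) and a resonant excess (attachment). No
functional form for the background is prescribed by the data, so the
package uses an iterative-clipping fit chosen for stability:

1. fit a low-order polynomial (default degree 4) to the curve in log–log
   coordinates;
2. estimate the noise scale robustly from the *negative* residuals only —
   resonances are strictly positive excursions and cannot contaminate
   them;
3. mark residual maxima exceeding both `clip_band` (default 2.5) noise
   scales and a relative floor of 1% of the local background as
   significant peaks; remove the contiguous positive-residual support of
   each peak; refit (removal only, ≤ 20 rounds, until stable).

The attachment is the non-negative excess over the converged background;
inputs with no significant peak decompose to exactly zero attachment, so
the operation is idempotent on its own background output. Peaks centred
above the pseudo-resonance cutoff (default 10 eV — spurious structures
produced when inelastic channels are omitted from an elastic-only
scattering calculation) are flagged and their excess removed.

Limitations, verified on synthetic curves: isolated peaks of width
~0.2–0.3 eV near 2 eV are recovered with centres within one grid spacing
and areas within 5% on a 60-point log grid; heavy Lorentzian tails
(half-width ≳ 0.4 eV) lose ~5–10% of their area into the background, and
structures much broader than ~0.5 eV standard deviation are partially or
wholly absorbed by the background fit. The polynomial degree, band,
floor and cutoff are all exposed parameters.

## Vibrational/electronic partition

The published table fixes only the *sum* of vibrational and electronic
excitation (through closure); the split procedure is not given in formula
form. The package makes it explicit as per-energy anchor weights
w_e(E) ∈ [0, 1] — the electronic fraction of the inelastic residual —
interpolated linearly in log E between anchors, forced to zero below the
electronic threshold (4.0 eV, the first tabulated electronic entry), with
the vibrational channel taking the exact remainder. `calibrate_partition`
recovers the anchors from the published columns; the round trip reproduces
both columns within 0.15×10⁻²⁰ m² wherever the reference table has exact
rows up to 150 eV (see the closure caveat above).

## Semiempirical DDCS model

Inelastic angular distributions follow
d²σ/(dΩ dΔE) ∝ (dσ/dΩ)_el(E, θ)·(1 − k ΔE/E), with k = 1.3 the calibrated
value for 1M5NI (measured at E = 97 eV, ΔE = 30 eV). Choices:

- the proportionality is closed by normalizing the double integral to the
  channel's integral cross-section at each E — the only constant
  consistent with the closure rule;
- the attenuation factor is clamped at zero for k ΔE > E, where the linear
  form goes unphysical;
- because the factor is angle-independent, deflection sampling reduces to
  inverse-CDF sampling of the elastic angular shape at (E, ΔE);
- `estimate_k`: at a single transferred energy the attenuation factor is
  one number, so a free overall scale would absorb it completely and k
  would be unidentifiable. The fit therefore treats single-transfer data
  as absolute (scale fixed at 1) and fits k alone; when the data span
  several transferred energies, scale and k are fitted jointly and the
  estimate is invariant to rescaling all intensities. Standard errors come
  from the weighted-least-squares covariance (delta method in the joint
  mode).

## Born dipole rotational excitation

1M5NI's 4.4 D permanent dipole makes rotational excitation an ever-open
long-range channel. The package implements the standard point-dipole
first-Born rigid-rotor result, collapsed onto a single effective
transition at the thermally averaged rotational transfer (0.617 meV at
300 K) because rotational constants and level populations are not
available — this is the module's core approximation. In atomic units
dσ/dΩ = (4/3) D² (k_f/k_i)/K², integrated in closed form over the allowed
angular range (the quadrature oracle in the tests confirms six figures).

The forward Born divergence is regularized by a minimum transferred
energy (default equal to the 0.617 meV transfer) translated to a minimum
angle through binary-encounter kinematics, θ_cut = arcsin(√(ε_cut/E)).
Only trends are meaningful — the monotone decrease of the integral
cross-section over 0.1–1000 eV, the D² scaling, the growth of the ICS as
the cutoff tightens; absolute values from a rigid-rotor single-transition
FBA are qualitative and the channel is excluded from closure sums.

## Fragment samplers

Anion branching ratios are anchored at the two measured energies. The
printed numbers are NO₂⁻ 58% at 3.1 eV and NO₂⁻ 35% / CN⁻ 21% / CNO⁻ 10%
at 4.7 eV; every other entry in the packaged table is a documented
synthetic fill: CN⁻ 10% and CNO⁻ 5% at 3.1 eV (consistent with both
rising toward their 4.7 eV maxima), and the five minor channels (C₂N₂Hₓ⁻,
C₃N₂Hₓ⁻, C₄N₂Hₓ⁻, NO-loss, OH/CH₃-loss) sharing the remaining probability
equally (27% at 3.1 eV, 34% at 4.7 eV — bracketing the reported 23–30%
combined yield). Between anchors the categorical distribution is linearly
interpolated and renormalized; outside the window the nearest anchor
applies, since no branching is measured elsewhere. A transport
configuration can disable DEA fragment species assignment outside the
window by restricting the table.

Fragment kinetic energies peak near 0 eV with isotropic emission; the
sampler draws an exponential KE with species means that are explicit
configuration, not measurements: NO₂⁻ 0.05 eV, CN⁻ 0.2 eV (markedly
broader, as observed), others 0.05 eV.

Cation relative intensities were measured at 67 eV only and are treated
as energy-independent — a documented limitation; sampling probabilities
are intensities normalized to their sum, making them invariant to overall
rescaling.

## Transport conventions

The data set itself prescribes no transport rules, so every convention
lives in `TransportConfig` with explicit defaults:

| parameter | default | status |
| --- | --- | --- |
| number density | 10²⁵ m⁻³ | user-set scene parameter |
| energy cutoff | 0.1 eV | data-set floor |
| ionization potential | 9.0 eV | placeholder assumption, not a measured value |
| ionization loss spectrum | ∝ 1/ΔE² on [IP, (E+IP)/2] | binary-encounter-like tail, swappable |
| vibrational loss | 0.15 eV fixed quantum | assumption |
| electronic loss | 4.0 eV (threshold) | assumption |
| k | 1.3 | calibrated |
| max events per cascade | 100 000 | truncation backstop |

Channel semantics per collision: elastic deflects without energy loss
(recoil at mass ratio ~1/230 000 is neglected); vibrational/electronic
subtract their loss and deflect through the DDCS model at (E, ΔE);
ionization draws a total loss ΔE, deposits the IP, hands ΔE − IP to an
isotropically emitted secondary (pushed on a stack and transported
identically) and samples a cation label; attachment terminates the
electron, deposits its remaining kinetic energy and samples an anion
species with a KE draw — the anion KE represents energy released from the
molecular rearrangement and is deliberately outside the electron energy
ledger.

Electrons below the cutoff deposit their residual locally
("thermalized"). Additionally, once no energy-loss channel is open at the
electron's energy (below the 0.7 eV vibrational opening only elastic
scattering remains) the electron would random-walk forever; by default it
is then thermalized on the spot (`terminate_elastic_only`, disable to
recover the pure elastic random walk). Per cascade, the primary energy
equals the sum of all deposits plus thermalized and truncation residuals
to better than 10⁻⁶ relative (in practice ~10⁻¹⁴).

Elastic angular sampling uses a user-supplied DCS table when available;
otherwise the packaged screened-Coulomb toy shape
(∝ 1/(1 + 2η − cosθ)², normalized analytically to the elastic ICS) stands
in and the run is stamped `elastic_dcs_is_fallback`. The toy shape is
synthetic: it carries forward peaking but no molecule-specific angular
structure, so angular observables under the fallback are qualitative.

## What the synthetic generators do and do not emulate

`make_resonance_curve` produces smooth-background-plus-peak curves with
the true decomposition retained, exercising exactly the inverse problem
the extraction solves — but with noiseless or white-noise data and
isolated analytic lineshapes, not the overlapping vibronic structure of a
real calculation. `make_toy_dcs` provides a normalizable forward-peaked
shape, not a real angular distribution. Passing tests therefore
demonstrate the correctness of the machinery under controlled conditions,
not the fidelity of the toy inputs to 1M5NI; the packaged integral tables
are the measured/calculated substance.

## Problem sizes

Default test and script sizes were chosen as the smallest that make the
statistical assertions sharp: 10⁵ draws for sampler frequencies (3σ
binomial half-widths ≲ 0.5 percentage points), 2×10⁴ draws for
Kolmogorov–Smirnov and free-path checks, 10–20 cascades at 500 eV for the
energy audit (the audit is exact per track, so track count only broadens
coverage), and a 60-point log grid for extraction oracles.
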