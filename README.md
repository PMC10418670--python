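# eltrack

Electron-scattering cross-sections and event-by-event track-structure
simulation for **1-methyl-5-nitroimidazole (1M5NI)**, a nitroimidazole-class
candidate molecular radiosensitizer (mass 127 u, permanent dipole 4.4 D).

Radiosensitizers of this class work through electron-driven chemistry: the
low-energy secondary electrons liberated along an ionizing-radiation track
attach to and dissociate the molecule, producing reactive radicals (NO₂⁻,
CN⁻, CNO⁻, …) that damage nearby DNA. Modelling that chemistry requires the
interaction probability of *every* open scattering channel — elastic,
electron attachment, vibrational, electronic excitation, ionization — over
the full slowing-down energy range. `eltrack` packages a self-consistent
channel-resolved integral cross-section set for 1M5NI covering
0.1–1000 eV, the machinery used to assemble such a set, and a Monte Carlo
electron transport loop driven entirely by it.

The package is for computational radiation physicists who need either the
validated, interpolable 1M5NI data set itself, or the assembly/transport
tooling to build and exercise analogous data sets for other targets.

## The model

**Self-consistency (closure).** With σ_ch(E) the integral cross-section of
channel *ch*, the set is self-consistent when

    σ_el(E) + σ_att(E) + σ_vib(E) + σ_exc(E) + σ_ion(E) = TCS(E)

at every energy, where the reference TCS is a transmission-beam measurement
corrected for the "missing angles" (MA) systematic — the elastic flux
scattered inside the detector's forward acceptance cone,
Δσ = 2π ∫₀^θacc (dσ/dΩ)_el sinθ dθ, is added back. Dipole rotational
excitation is carried as a separate qualitative channel and deliberately
excluded from the closure sum. `validate_consistency` checks the closure
row by row; in the packaged set every tabulated energy closes within
0.15×10⁻²⁰ m² except the 70 eV row, a printed-table anomaly that is
flagged, never repaired.

**Assembly pipeline.** The total inelastic cross-section is the reference
TCS+MA minus the pure integral elastic; electron attachment is obtained by
extracting resonance peaks from the smooth elastic background of the
low-energy curve (peaks above 10 eV with no experimental confirmation are
pseudo-resonances and are discarded); ionization is subtracted; the
remaining residual is split between vibrational and electronic excitation
by threshold-constrained, data-calibrated weights.

**Energy-loss angular model.** Inelastic deflections follow the
semiempirical double-differential form

    d²σ/(dΩ dΔE) ∝ (dσ/dΩ)_el(E, θ) · (1 − k·ΔE/E),   k = 1.3 for 1M5NI

normalized so the double integral reproduces the channel's integral
cross-section. `estimate_k` refits k from measured angular distributions.

**Fragmentation.** Dissociative electron attachment (DEA) anion species are
sampled from branching ratios anchored at the measured 3.1–4.7 eV resonant
window (NO₂⁻ 58% at 3.1 eV; NO₂⁻ 35%, CN⁻ 21%, CNO⁻ 10% at 4.7 eV), with
near-zero-peaked isotropic kinetic-energy draws. Cations from 67 eV
electron-impact ionization are sampled from the measured relative-intensity
table (parent ion C₄H₅N₃O₂⁺ most intense; CHO⁺/parent = 0.768).

**Transport.** Free paths are exponential with 1/(n·σ_tot); channels are
chosen ∝ σ_ch(E); secondaries from ionization are transported identically;
per-cascade energy bookkeeping closes to machine precision.

## Worked example

```python
from eltrack import (Channel, DDCSModel, TransportConfig, TransportModels,
                     interpolate, make_toy_dcs, packaged_tables, run,
                     sum_channels, validate_consistency)

xs_set, branching, cations = packaged_tables()

sum_channels(xs_set, 20.0)            # 73.21  (printed total: 73.2e-20 m2)
validate_consistency(xs_set).failing_energies   # (70.0,) - known anomaly

elastic = xs_set[Channel.ELASTIC]
dcs = make_toy_dcs(lambda e: interpolate(elastic, e))   # synthetic angular shape
models = TransportModels(elastic_dcs=dcs, ddcs=DDCSModel(elastic_dcs=dcs),
                         anion_branching=branching, cation_intensities=cations,
                         elastic_dcs_is_fallback=True)
tracks = run(TransportConfig(density_m3=1e25, seed=42), xs_set, models,
             primary_energy=500.0, n_primaries=20)
```

Output of the run above:

```
channel totals: {'elastic': 69528, 'ionization': 517, 'electronic': 825,
                 'vibrational': 4288, 'attachment': 394}
fragments: [('NO2-', 192), ('C4H5N3O2+', 91), ('CHO+', 76),
            ('C2H4N2+', 63), ('CH3NO+', 62)]
max energy-balance error: 1.07e-14
```

Twenty 500 eV electrons in 1M5NI vapor at 10²⁵ m⁻³ undergo ~75 000
collisions, dominated by elastic scattering; each cascade's primary energy
is recovered exactly from the recorded deposits, and the fragment inventory
is led by NO₂⁻ (DEA) and the parent cation (ionization), as expected from
the branching tables.

The same functionality is exposed on the command line:

```
eltrack validate --set 1m5ni_recommended --tol 0.15 --anomaly 70
eltrack simulate --e0 1000 --n 100 --density 1e25 --seed 42 --out tracks.jsonl
eltrack sample-fragments --kind anion --e 3.1 --n 100000 --seed 1
```

## Layout

- `src/eltrack/xs.py` — cross-section tables, interpolation, closure checks
- `src/eltrack/assembly.py` — missing-angle correction, resonance
  extraction, inelastic partition
- `src/eltrack/ddcs.py` — semiempirical energy-loss angular model
- `src/eltrack/fragmentation.py` — DEA anion and cation samplers
- `src/eltrack/rotational.py` — Born dipole rotational excitation
- `src/eltrack/transport.py` — event-by-event Monte Carlo cascades
- `src/eltrack/fixtures.py`, `src/eltrack/data/` — packaged tables and
  synthetic generators
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
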