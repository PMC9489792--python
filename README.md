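# gevikit

Photophysics and MD post-processing toolkit for rhodopsin-based genetically
encoded voltage indicators (GEVIs).

Archaerhodopsin-3 derivatives such as the QuasArs and Archons report membrane
voltage as a change in near-infrared fluorescence. Characterising them spans
several very different measurements: femtosecond transient absorption of the
retinal photocycle, TCSPC/FLIM and streak-camera fluorescence decays,
steady-state absorption/emission photophysics, HPLC retinal-isomer analysis,
and molecular-dynamics trajectories under an applied transmembrane voltage.
`gevikit` implements the analysis layer for all of these stages as a single
tested Python package, together with synthetic-data generators that emulate
every input type with known ground truth, so the whole pipeline can be
validated at desk scale.

## What it computes

* **Global target analysis of transient absorption** (`gevikit.global_kinetics`)
  — ΔA(λ, t) is modelled as sequential (or branched) first-order compartments,
  each convolved with a Gaussian IRF. The fit uses variable projection: the
  nonlinear search runs over the time constants τ₀…τₙ (log-parameterised),
  while the evolution-associated difference spectra (EADS) are eliminated by an
  exact linear solve. A terminal non-decaying compartment is supported as
  rate 0, and the photoisomerisation yield is estimated from the ratio of
  terminal to initial EADS amplitude at the ground-state-bleach wavelength.
* **Fluorescence decay analysis** (`gevikit.lifetime`) — iterative
  reconvolution fitting of photon histograms, I(t) = Σᵢ αᵢ e^(−t/τᵢ) ⊗ IRF,
  with fractional amplitudes βᵢ = αᵢτᵢ/Σⱼαⱼτⱼ, the population-weighted mean
  lifetime τ̄_pop = Σ βᵢτᵢ, the amplitude-weighted mean
  τ_avg = Σ τₙAₙ / Σ Aₙ, and a Hill-model fit of slow depolarisation time
  courses F(t) = f₀ + (f_max − f₀)·tⁿ/(tⁿ + t½ⁿ).
* **Steady-state photophysics** (`gevikit.steady_state`) — Nernst calibration
  V = (RT/zF)·ln([K]out/[K]in); relative quantum yield
  Φ = Φ_ref·(f_ref/f_s)·(F_s/F_ref)·(n_s/n_ref)² with f = 1 − 10^(−A);
  two-state Henderson–Hasselbalch pKa fitting; baseline-corrected HPLC isomer
  fractions; Stern–Volmer quenching slopes.
* **Trajectory post-processing** (`gevikit.structure`) — hydrogen bonds at the
  3 Å / 150° donor–hydrogen–acceptor criteria with the carboxylate
  deduplication rule, inward/outward side-chain classification by minimal
  distances to reference atom sets, distance–angle distributions, pocket-water
  counts, and equilibrated-tail frame selection.
* **Synthetic data with ground truth** (`gevikit.synthetic`) — generators for
  every input above, seeded and bit-reproducible.
* **I/O and CLI** (`gevikit.io`, `gevikit.cli`) — CSV matrices with
  `# key=value` metadata, two-column CSV traces, multi-MODEL PDB trajectories,
  and a `gevikit` command with `simulate`, `fit-tas`, `fit-decay`,
  `fit-depol`, `nernst`, `qy`, `pka`, `hplc` and `hbonds` subcommands.

## Worked example

Simulate a QuasAr2-like five-component transient-absorption surface (time
constants 183 fs, 4 ps, 40 ps, 288 ps and a non-decaying component, 1% noise)
and recover the constants by global fitting:

```python
import numpy as np
from gevikit import (KineticScheme, default_tau_init, fit_global,
                     quasar2_tas_spec, simulate_tas)

data = simulate_tas(quasar2_tas_spec(noise_relative=0.01, seed=42))
init = KineticScheme(
    "sequential",
    tuple(default_tau_init(data.delays, 4)) + (np.inf,),
    irf_sigma=0.080 / 2.3548,
)
result = fit_global(data, init)
for i, tau in enumerate(result.scheme.time_constants):
    label = "inf" if np.isinf(tau) else f"{tau:.3g} ps"
    print(f"tau_{i} = {label}")
print(f"rms residual = {result.rms_residual:.2e}")
```

Output:

```
tau_0 = 0.176 ps
tau_1 = 3.8 ps
tau_2 = 39.8 ps
tau_3 = 270 ps
tau_4 = inf
rms residual = 9.45e-03
```

All four finite constants come back within a few percent of the generator's
values (0.183, 4, 40, 288 ps); the residual RMS matches the injected 1%
noise floor. The same pattern works from the shell:

```sh
gevikit nernst --kout 150 --kin 10     # -> 68.4 mV
gevikit simulate chrom --seed 3 --out out/
gevikit hplc out/chromatogram.csv --window 7:9:13-cis --window 11:13:all-trans
```

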