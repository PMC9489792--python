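# Methods

This note documents the models, numerical choices and limitations behind
`gevikit`, stage by stage.

## Kinetic model for time-resolved spectra

A transient-absorption surface is modelled as
ΔA(λ, t) = Σₖ cₖ(t) Sₖ(λ), with the compartment populations cₖ(t) given by a
unidirectional first-order cascade convolved with a Gaussian instrument
response of centre μ and width σ. The elementary building block is the
analytic convolution of a normalised Gaussian with a step-exponential,

c(t; τ) = ½ exp(σ²/2τ² − (t − μ)/τ) · erfc((σ/τ − (t − μ)/σ)/√2),

evaluated through the scaled complementary error function (`erfcx`) on the
rising flank so the expression stays finite for τ/σ from 10⁻³ to 10⁹ and
|t − μ| up to ~50σ. A non-decaying terminal compartment is the τ → ∞ limit,
the Gaussian cumulative. Cascade populations follow the Bateman closed form
with these convolved exponentials as the basis; rates closer than 10⁻⁶
relative are split by a 10⁻⁶ perturbation (with a warning) to avoid the
degenerate-denominator singularity.

Two topologies are provided. *Sequential* (1 → 2 → … → n) yields
evolution-associated difference spectra when fitted globally. *Branched*
models photoproduct formation: the excited state splits with branch fraction
φ into a photointermediate chain (I640 → I620 → non-decaying) and with
1 − φ into a recovered-ground sink carrying a zero difference spectrum.
With the sink included the populations sum to the IRF cumulative at every
delay, which the tests assert.

## Global fitting

`fit_global` uses variable projection: the outer optimiser
(`scipy.optimize.least_squares`, TRF) searches over log τ (and optionally μ
and log σ), and at every trial point the component spectra are the exact
weighted linear least-squares solution. Log-parameterisation enforces
positivity and conditions the fs-to-µs dynamic range. Finite constants are
sorted ascending before reporting; permuting the initial guesses changes the
EADS assignment during the search but not the converged loss, which the test
suite checks. Standard errors for τ come from the Gauss–Newton curvature at
the optimum. Default initialisation is log-spaced across the positive delay
decades. Reconstruction (concentrations · spectra + residual = data) is an
identity by construction of the inner solve.

The photoisomerisation yield is estimated as
|S_terminal(λ_GSB)| / |S_initial(λ_GSB)| — the fraction of the initial
ground-state bleach that never recovers. The synthetic branched generator
places its photoproduct bands at 640/620 nm (σ = 12 nm) with amplitude 0.2
against a unit bleach at 590 nm (σ = 15 nm), so photoproduct absorption leaks
less than 1% of the bleach amplitude into the estimator and the recovery is
unbiased by construction. On real spectra with stronger band overlap the
estimator would inherit that overlap as bias.

## Decay reconvolution

Photon histograms are fitted with I(t) = Σ αᵢ e^(−t/τᵢ) convolved with the
IRF on the channel grid, again by variable projection (outer: log τ and a
scalar IRF/decay time-origin shift; inner: linear amplitudes). Weighting is
two-stage: a first pass with Neyman weights 1/√max(counts, 1), then a refit
with Pearson weights from the fitted model, which removes the classic
low-count lifetime bias of observed-count weighting. Channels before the IRF
rise are included — reconvolution handles them naturally.

Two IRF treatments are available. The default uses the measured IRF
histogram directly as a delta comb with the exponential kernel integrated
exactly over each channel cell; this is standard TCSPC practice but carries a
sub-percent lifetime bias from the finite channel width and the counting
noise of the IRF itself. The `gaussian` mode fits a parametric Gaussian
(μ, σ) to the IRF histogram and uses the analytic convolution — appropriate
for streak-camera data and whenever the response is known to be Gaussian; in
that mode the noise-free round trip closes to machine precision and the
reported standard errors are calibrated (±2 SE covers the truth in ≥90% of
seeded runs, asserted in the suite). Lifetimes fitted below the IRF FWHM are
flagged as below the resolution floor rather than rejected, mirroring how a
~14 ps component is invisible to a 50–120 ps detector but resolvable with a
3 ps streak system.

Derived quantities: fractional amplitudes βᵢ = αᵢτᵢ/Σαⱼτⱼ (sum to 1 exactly);
population-weighted mean τ̄_pop = Σβᵢτᵢ; amplitude-weighted mean
τ_avg = ΣτₙAₙ/ΣAₙ. The printed per-component percentages of multiexponential
FLIM fits are interpreted as the fractional amplitudes βᵢ — only that reading
reproduces the quoted ~260/~220 ps means (reading them as αᵢ gives ≈1.8 ns).
For any decay with positive amplitudes τ_avg ≤ τ̄_pop, and both lie within
[min τ, max τ]; these orderings are property-tested.

## Steady-state calculations

* **Nernst**: V = (RT/zF)·ln([K]out/[K]in) in mV, R = 8.314 J mol⁻¹ K⁻¹,
  F = 96485 C mol⁻¹. Default temperature 293.15 K (room temperature); the
  0.5/10/150 mM gradients then give −75.7, 0 and +68.4 mV, matching the
  rounded calibration values within a millivolt.
* **Relative quantum yield**: decadic absorbance convention, f = 1 − 10^(−A);
  absorbances above 0.05 OD trigger a reabsorption warning per the dilution
  rule.
* **pKa**: A(pH) = A_deprot + (A_prot − A_deprot)/(1 + 10^(n·(pH − pKa))),
  Hill coefficient fitted by default (1 = a single protonatable site, the
  retinal Schiff base). The fit is invariant under affine transforms of the
  absorbance axis and under flipping which band is monitored. Series with
  fewer than 5 points or under 2 pH units of coverage are flagged, not
  rejected.
* **HPLC fractions**: trapezoidal areas over user windows after subtracting a
  straight baseline anchored on the *mean* signal in short edge segments
  (default 5% of the window per side); averaging the anchors keeps single
  noisy samples from tilting the baseline, which at 1% noise would otherwise
  shift small fractions by more than a percentage point. Negative corrected
  areas clip to zero with a warning; fractions normalise to 1.
* **Stern–Volmer**: ordinary linear regression of F₀/F on quencher
  concentration; the intercept is reported as a sanity check (≈1).

## Trajectory analysis

Hydrogen bonds use inclusive cutoffs — donor–acceptor distance ≤ 3 Å and
donor–hydrogen–acceptor interior angle ≥ 150° (180° = linear) — so the
printed thresholds are attainable. When one donor satisfies the criteria
with both carboxyl oxygens of the same Asp/Glu, the pair counts once (the
closer oxygen is reported). Orientation classification compares the minimal
probe distance to an inward and an outward reference set; exact ties are
classed outward, a deterministic convention chosen for reproducibility at a
measure-zero boundary. Pocket waters are oxygen atoms of HOH/SOL/WAT
residues within a radius of a centre that may be a fixed point or the
per-frame midpoint of named atoms. The equilibrated-window selector keeps
frames with t ≥ t_end − window (closed interval, so window 0 keeps the final
frame). All geometry is plain Cartesian: hydrogens must be explicit, and no
periodic-boundary minimum image is applied — real MD output must be
pre-wrapped with molecules whole. Probabilities are reported per trajectory;
replicate averaging (mean ± SD across runs) is left to the caller.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure each fit assumes:
Gaussian-IRF-convolved cascades with Gaussian spectral bands and additive
Gaussian noise for ΔA surfaces (instrument-limited detection; default noise
1% of max |ΔA|, an explicit choice exposed as a parameter); Poisson photon
counting for decays (defaults mirror the FLIM acquisition: 1024 channels of
19.5 ps, 60 ps FWHM pulse; FWHM↔σ via σ = FWHM/2.3548); Gaussian
chromatogram peaks whose analytic areas equal the prescribed isomer
fractions; two-state titration curves; Hill-kinetics rises; and scripted toy
trajectories in which hydrogen-bond occupancy, side-chain flips and
pocket-water counts hold exactly by construction (occupancy schedules use
deterministic Bresenham interleaving, so a 0.30 occupancy over 200 frames
marks exactly 60 frames). Spectral bands are Gaussians in wavelength rather
than wavenumber — a deliberate simplification of spectroscopic convention.

None of this emulates real protein dynamics: no force-field physics, no
solvent structure, no spectral congestion beyond the scripted bands, no
detector afterpulsing or pile-up. Passing recovery tests therefore shows the
estimators are correct and well-conditioned at realistic noise levels — not
that real measurements are free of the systematic effects the generators
omit. Quantities that require microsecond MD ensembles or wet-lab data
(voltage-resolved hydrogen-bond probabilities, ΔF/F sensitivities, absolute
quantum yields) are exercised only through estimator-recovery and property
tests.

## Problem sizes and numerical defaults

Simulated surfaces default to 150 wavelengths × 200 delays (50 linear points
through the IRF region, 150 log-spaced out to 3.3 ns, matching pump–probe
practice of linear-then-logarithmic sampling); decay histograms to 1024
channels; titrations to 13 pH points; depolarisation traces to 15 one-minute
points — the sizes at which the corresponding experiments are actually
reported. Fits at these sizes complete in well under a second each. Time is
handled internally in ps (readers normalise fs/ns/µs), coordinates in Å,
frame times in ns.

## Known limitations

* The sequential global fit assumes distinct rates; genuinely equal rates are
  perturbed rather than handled with the t·e^(−kt) degenerate solution.
* No wavelength-dependent IRF dispersion (coherent-artifact modelling), no
  target analysis with arbitrary compartmental matrices, no anisotropy.
* The measured-IRF reconvolution mode retains a sub-percent bias at coarse
  channel widths (see above); use the Gaussian mode when the instrument
  response is known to be Gaussian.
* The yield estimator assumes the photoproduct bands are spectrally separated
  from the bleach at the evaluation wavelength.
* PDB is the only trajectory format (text, MODEL/ENDMDL); binary MD formats
  are out of scope.
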