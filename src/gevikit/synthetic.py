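"""Synthetic-data generators with known ground truth.

Every input type the analysis pipeline consumes can be generated here with a
fixed seed and the statistical structure the downstream fits assume:

* transient-absorption surfaces — Gaussian-IRF-convolved sequential or
  branched exponential cascades with Gaussian spectral bands and additive
  Gaussian noise (instrument-limited detection);
* photon-counting decay histograms — multiexponential kinetics convolved with
  a Gaussian IRF, Poisson-sampled (TCSPC physics);
* HPLC chromatograms — Gaussian peaks whose analytic areas match prescribed
  isomer fractions, on a flat baseline;
* pH titrations — two-state protonation curves;
* depolarisation time courses — Hill kinetics;
* toy coordinate trajectories — scripted hydrogen-bond occupancies,
  side-chain flips and pocket-water schedules.

Each generator stores its ground-truth parameters on the returned object
(``.truth`` or the attached scheme), so recovery tests compare against the
record, never against re-derived values.  A fixed seed gives bit-identical
output.  Spectral bands are Gaussians in wavelength (not wavenumber) — a
documented simplification of spectroscopic convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .global_kinetics import (
    KineticScheme,
    TimeResolvedSpectra,
    sequential_populations,
)
from .lifetime import DecayTrace, InstrumentResponse
from .steady_state import Chromatogram, TitrationSeries
from .structure import Trajectory

__all__ = [
    "FWHM_TO_SIGMA",
    "TasSimSpec",
    "DecaySimSpec",
    "ChromSimSpec",
    "TitrationSimSpec",
    "TrajSimSpec",
    "simulate_tas",
    "simulate_decay_trace",
    "simulate_chromatogram",
    "simulate_titration",
    "simulate_depolarization_trace",
    "simulate_trajectory",
    "default_delay_grid",
    "quasar2_tas_spec",
    "archon1_tas_spec",
    "branched_tas_spec",
]

#: conversion factor between a Gaussian FWHM and its sigma
FWHM_TO_SIGMA = 1.0 / 2.3548


def gaussian_bands(wavelengths: np.ndarray, bands) -> np.ndarray:
    """Sum of Gaussian bands: iterable of (center_nm, sigma_nm, amplitude)."""
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wl)
    for center, sigma, amp in bands:
        if sigma <= 0:
            raise ValueError("band widths must be positive")
        out += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return out


def default_delay_grid(
    t_min: float = -1.0,
    t_lin_end: float = 1.0,
    t_max: float = 3300.0,
    n_linear: int = 50,
    n_log: int = 150,
) -> np.ndarray:
    """Pump-probe delay grid: linear through the IRF region, then log-spaced.

    Defaults give 50 linear points across [-1, 1] ps and 150 log points out
    to 3.3 ns (the mechanical-delay limit of a typical fs setup).
    """
    lin = np.linspace(t_min, t_lin_end, n_linear, endpoint=False)
    log = np.geomspace(t_lin_end, t_max, n_log)
    return np.concatenate([lin, log])


# ---------------------------------------------------------------------------
# transient absorption surfaces
# ---------------------------------------------------------------------------

@dataclass
class TasSimSpec:
    """Recipe for a synthetic transient-absorption surface.

    ``bands`` holds, per kinetic component, a tuple of Gaussian spectral
    features (center_nm, sigma_nm, signed_amplitude).  ``noise_sd`` is
    additive Gaussian noise in dA units; with ``noise_mode='relative_max'``
    it is interpreted as a fraction of the noise-free max |dA| (the default
    study condition is 1% of max).
    """

    scheme: KineticScheme
    bands: tuple
    wavelengths: np.ndarray
    delays: np.ndarray
    noise_sd: float = 0.0
    noise_mode: str = "absolute"
    seed: int = 0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_mode not in ("absolute", "relative_max"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        if len(self.bands) != self.scheme.n_components:
            raise ValueError(
                f"need one band list per component "
                f"({self.scheme.n_components}), got {len(self.bands)}"
            )
        for comp in self.bands:
            for _, sigma, _ in comp:
                if sigma <= 0:
                    raise ValueError("band widths must be positive")


def simulate_tas(spec: TasSimSpec) -> TimeResolvedSpectra:
    """dA(lambda, t) = sum_k c_k(t) S_k(lambda) + noise.

    Concentrations come from the IRF-convolved cascade of ``spec.scheme``
    (sequential or branched); component spectra are Gaussian band sums.  The
    ground-truth scheme and spectra are stored in ``.meta['truth']``.
    """
    conc = sequential_populations(spec.scheme, spec.delays)
    spectra = np.vstack(
        [gaussian_bands(spec.wavelengths, comp) for comp in spec.bands]
    )
    clean = conc @ spectra
    sd = spec.noise_sd
    if spec.noise_mode == "relative_max":
        sd = sd * np.max(np.abs(clean))
    rng = np.random.default_rng(spec.seed)
    surface = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean
    data = TimeResolvedSpectra(
        wavelengths=spec.wavelengths,
        delays=spec.delays,
        delta_a=surface,
        time_unit="ps",
    )
    data.meta["truth"] = {
        "scheme": spec.scheme,
        "spectra": spectra,
        "concentrations": conc,
        "noise_sd": sd,
        "seed": spec.seed,
    }
    return data


# default band sets ---------------------------------------------------------

_ESA, _GSB, _SE = 510.0, 590.0, 705.0   # nm, band centres of the dA features


def quasar2_tas_spec(noise_relative: float = 0.01, seed: int = 0,
                     n_wavelengths: int = 150) -> TasSimSpec:
    """Five-component sequential surface with the QuasAr2 photocycle constants.

    Time constants 183 fs, 4 ps, 40 ps, 288 ps and a terminal non-decaying
    component; IRF sigma 34 fs (80 fs FWHM).  The component spectra evolve
    through a decaying excited-state pattern (ESA + bleach + stimulated
    emission) into small photoproduct bands at 640/620 nm.
    """
    scheme = KineticScheme(
        topology="sequential",
        time_constants=(0.183, 4.0, 40.0, 288.0, np.inf),
        irf_center=0.0,
        irf_sigma=0.080 * FWHM_TO_SIGMA,
    )
    bands = (
        ((_ESA - 5, 30.0, 1.00), (_GSB, 15.0, -0.80), (_SE, 30.0, -0.60)),
        ((_ESA, 30.0, 0.90), (_GSB, 15.0, -0.80), (_SE + 5, 30.0, -0.50)),
        ((_ESA + 5, 30.0, 0.70), (_GSB, 15.0, -0.75), (_SE + 5, 30.0, -0.40)),
        ((640.0, 12.0, 0.08), (_GSB, 15.0, -0.10)),
        ((620.0, 12.0, 0.05), (_GSB, 15.0, -0.04)),
    )
    return TasSimSpec(
        scheme=scheme,
        bands=bands,
        wavelengths=np.linspace(360.0, 720.0, n_wavelengths),
        delays=default_delay_grid(),
        noise_sd=noise_relative,
        noise_mode="relative_max",
        seed=seed,
    )


def archon1_tas_spec(noise_relative: float = 0.01, seed: int = 0,
                     n_wavelengths: int = 150) -> TasSimSpec:
    """Two excited-state components (14 and 75 ps) plus a terminal component."""
    scheme = KineticScheme(
        topology="sequential",
        time_constants=(14.0, 75.0, np.inf),
        irf_center=0.0,
        irf_sigma=0.080 * FWHM_TO_SIGMA,
    )
    bands = (
        ((_ESA, 30.0, 1.00), (585.0, 15.0, -0.80), (_SE, 30.0, -0.60)),
        ((_ESA + 5, 30.0, 0.75), (585.0, 15.0, -0.80), (_SE + 5, 30.0, -0.45)),
        ((640.0, 12.0, 0.005), (585.0, 15.0, -0.02)),
    )
    return TasSimSpec(
        scheme=scheme,
        bands=bands,
        wavelengths=np.linspace(360.0, 720.0, n_wavelengths),
        delays=default_delay_grid(),
        noise_sd=noise_relative,
        noise_mode="relative_max",
        seed=seed,
    )


def branched_tas_spec(phi: float, noise_relative: float = 0.01, seed: int = 0,
                      n_wavelengths: int = 150) -> TasSimSpec:
    """Branched scheme for photoproduct-yield simulations.

    The excited state decays in 40 ps; a fraction ``phi`` enters the
    photoproduct chain I640 -> I620 (288 ps, then non-decaying), the rest
    returns to the ground state (zero difference spectrum).  I-state bands
    sit at 640/620 nm (sigma 12 nm) with amplitude 0.2 against a unit bleach
    at 590 nm (sigma 15 nm), keeping their leakage into the bleach centre
    below 1% so the amplitude-ratio yield estimator is unbiased by
    construction.
    """
    scheme = KineticScheme(
        topology="branched",
        time_constants=(40.0, 288.0, np.inf),
        branch_fraction=phi,
        irf_center=0.0,
        irf_sigma=0.080 * FWHM_TO_SIGMA,
    )
    bands = (
        ((_ESA, 30.0, 0.80), (_GSB, 15.0, -1.00), (_SE, 30.0, -0.50)),  # S1
        ((640.0, 12.0, 0.20), (_GSB, 15.0, -1.00)),                     # I640
        ((620.0, 12.0, 0.20), (_GSB, 15.0, -1.00)),                     # I620
        ((_GSB, 15.0, 1e-12),),                                         # ground sink
    )
    return TasSimSpec(
        scheme=scheme,
        bands=bands,
        wavelengths=np.linspace(360.0, 720.0, n_wavelengths),
        delays=default_delay_grid(t_max=5000.0),
        noise_sd=noise_relative,
        noise_mode="relative_max",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# photon-counting decays
# ---------------------------------------------------------------------------

@dataclass
class DecaySimSpec:
    """Recipe for a TCSPC/streak decay histogram.

    Defaults mirror the FLIM acquisition: 1024 channels of 19.5 ps and a
    60 ps FWHM excitation pulse.  ``peak_counts`` is the expected count in
    the maximum channel.  ``truncated`` is flagged when the window covers
    less than 5x the longest lifetime.
    """

    lifetimes: tuple                  # ps
    amplitudes: tuple                 # unitless, >= 0
    irf_fwhm: float = 60.0            # ps
    irf_center: float | None = None   # ps; default 5% of the window
    channel_width: float = 19.5       # ps
    n_channels: int = 1024
    peak_counts: float = 1e4
    noise_model: str = "poisson"      # poisson | gaussian | none
    seed: int = 0

    def __post_init__(self):
        self.lifetimes = tuple(float(t) for t in self.lifetimes)
        self.amplitudes = tuple(float(a) for a in self.amplitudes)
        if any(t <= 0 for t in self.lifetimes):
            raise ValueError("lifetimes must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if len(self.lifetimes) != len(self.amplitudes):
            raise ValueError("lifetimes and amplitudes must align")
        if self.peak_counts <= 0:
            raise ValueError("peak_counts must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def window(self) -> float:
        return self.n_channels * self.channel_width

    @property
    def truncated(self) -> bool:
        return self.window < 5.0 * max(self.lifetimes)


def simulate_decay_trace(spec: DecaySimSpec):
    """Simulate (decay, IRF) histograms on a shared channel grid.

    Expected decay counts are the Gaussian-IRF convolution of the
    multiexponential model, scaled to ``peak_counts`` at the maximum, then
    sampled under the chosen noise model.  The IRF is returned as a trace of
    the same peak counts on the same grid (sampled under the same model).
    """
    from .global_kinetics import exp_conv_irf  # local import: avoid cycle at module load

    t = np.arange(spec.n_channels) * spec.channel_width
    sigma = spec.irf_fwhm * FWHM_TO_SIGMA
    center = spec.irf_center if spec.irf_center is not None else 0.05 * spec.window

    expected = np.zeros_like(t)
    for tau, amp in zip(spec.lifetimes, spec.amplitudes):
        expected += amp * exp_conv_irf(tau, center, sigma, t)
    if expected.max() > 0:
        expected *= spec.peak_counts / expected.max()
    irf_expected = np.exp(-0.5 * ((t - center) / sigma) ** 2) * spec.peak_counts

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "poisson":
        counts = rng.poisson(expected).astype(float)
        irf_counts = rng.poisson(irf_expected).astype(float)
    elif spec.noise_model == "gaussian":
        counts = np.clip(expected + rng.normal(0, np.sqrt(np.maximum(expected, 1.0))), 0, None)
        irf_counts = np.clip(
            irf_expected + rng.normal(0, np.sqrt(np.maximum(irf_expected, 1.0))), 0, None
        )
    else:
        counts = expected
        irf_counts = irf_expected

    truth = {
        "lifetimes": spec.lifetimes,
        "amplitudes": spec.amplitudes,
        "irf_center": center,
        "irf_sigma": sigma,
        "truncated": spec.truncated,
        "seed": spec.seed,
    }
    decay = DecayTrace(channel_times=t, counts=counts,
                       channel_width=spec.channel_width,
                       meta={"truth": truth})
    irf = InstrumentResponse(channel_times=t, counts=irf_counts,
                             channel_width=spec.channel_width,
                             meta={"truth": truth})
    return decay, irf


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------

@dataclass
class ChromSimSpec:
    """Gaussian-peak chromatogram with prescribed area fractions."""

    peak_centers: tuple               # min
    peak_sigmas: tuple                # min
    peak_area_fractions: tuple        # sum to 1
    baseline: float = 0.0
    noise_sd: float = 0.0
    t_start: float = 0.0
    t_end: float | None = None
    n_points: int = 2000
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.peak_area_fractions) - 1.0) > 1e-9:
            raise ValueError("peak_area_fractions must sum to 1 (tol 1e-9)")
        if any(f < 0 for f in self.peak_area_fractions):
            raise ValueError("fractions must be non-negative")
        if any(s <= 0 for s in self.peak_sigmas):
            raise ValueError("peak sigmas must be positive")
        if not (len(self.peak_centers) == len(self.peak_sigmas)
                == len(self.peak_area_fractions)):
            raise ValueError("peak parameter lengths must align")

    @property
    def overlapping(self) -> bool:
        cs = sorted(zip(self.peak_centers, self.peak_sigmas))
        for (c1, s1), (c2, s2) in zip(cs, cs[1:]):
            if c2 - c1 <= 2.0 * (s1 + s2):
                return True
        return False


def simulate_chromatogram(spec: ChromSimSpec) -> Chromatogram:
    """signal(t) = baseline + sum_j A_j Gauss(t; c_j, s_j) + noise.

    Peak amplitudes are scaled so the analytic area of peak j equals
    ``peak_area_fractions[j]``.  Unresolvable peak spacing is recorded in
    ``truth['overlapping']``.
    """
    import warnings as _warnings

    if spec.overlapping:
        _warnings.warn("peaks closer than 2(s_i+s_j); flagged overlapping",
                       RuntimeWarning)
    t_end = spec.t_end
    if t_end is None:
        t_end = max(c + 8 * s for c, s in zip(spec.peak_centers, spec.peak_sigmas))
    t = np.linspace(spec.t_start, t_end, spec.n_points)
    signal = np.full_like(t, spec.baseline)
    for c, s, f in zip(spec.peak_centers, spec.peak_sigmas,
                       spec.peak_area_fractions):
        signal += f / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - c) / s) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0, spec.noise_sd, size=t.shape)
    return Chromatogram(
        retention_time=t,
        signal=signal,
        truth={
            "centers": spec.peak_centers,
            "sigmas": spec.peak_sigmas,
            "fractions": spec.peak_area_fractions,
            "baseline": spec.baseline,
            "overlapping": spec.overlapping,
            "seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# titrations and depolarisation traces
# ---------------------------------------------------------------------------

@dataclass
class TitrationSimSpec:
    """Two-state protonation titration curve."""

    pka: float
    a_protonated: float
    a_deprotonated: float
    ph_grid: tuple
    hill_n: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        ph = np.asarray(self.ph_grid, dtype=float)
        if ph.size == 0:
            raise ValueError("empty ph_grid")
        if np.any(np.diff(ph) <= 0):
            raise ValueError("ph_grid must be strictly increasing")
        if self.a_protonated == self.a_deprotonated:
            raise ValueError("asymptotes must differ")
        self.ph_grid = tuple(ph)


def simulate_titration(spec: TitrationSimSpec) -> TitrationSeries:
    """A(pH) = A_deprot + (A_prot - A_deprot)/(1 + 10^(n (pH - pKa))) + noise."""
    ph = np.asarray(spec.ph_grid)
    a = spec.a_deprotonated + (spec.a_protonated - spec.a_deprotonated) / (
        1.0 + 10.0 ** (spec.hill_n * (ph - spec.pka))
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        a = a + rng.normal(0, spec.noise_sd, size=ph.shape)
    return TitrationSeries(
        ph=ph,
        absorbance=a,
        truth={
            "pka": spec.pka,
            "hill_n": spec.hill_n,
            "a_protonated": spec.a_protonated,
            "a_deprotonated": spec.a_deprotonated,
            "seed": spec.seed,
        },
    )


def simulate_depolarization_trace(
    t_half: float,
    hill_n: float,
    f0: float,
    f_max: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Hill-kinetics intensity rise F(t) = f0 + (f_max-f0) t^n/(t^n + t_half^n).

    Returns (times, intensities, truth).  Times in minutes.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if hill_n <= 0:
        raise ValueError("hill_n must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    f = np.full_like(t, float(f0))
    pos = t > 0
    tn = t[pos] ** hill_n
    f[pos] = f0 + (f_max - f0) * tn / (tn + t_half**hill_n)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0, noise_sd, size=t.shape)
    truth = {"t_half": t_half, "hill_n": hill_n, "f0": f0, "f_max": f_max,
             "seed": seed}
    return t, f, truth


# ---------------------------------------------------------------------------
# toy trajectories
# ---------------------------------------------------------------------------

def _interleave(n: int, fraction: float) -> np.ndarray:
    """Deterministic Bresenham schedule: exactly floor(n*fraction) True flags,
    spread evenly across the n frames."""
    i = np.arange(n)
    return (np.floor((i + 1) * fraction) - np.floor(i * fraction)) >= 1


@dataclass
class TrajSimSpec:
    """Scripted toy trajectory for the geometry analyses.

    The fixture contains a backbone N-H donor, an aspartate carboxylate whose
    two oxygens both satisfy the hydrogen-bond criteria in 'bonded' frames
    (so the dedup rule is exercised), an arginine Czeta probe alternating
    between inward and outward reference sites, and water oxygens moved in
    and out of a pocket sphere per schedule.
    """

    n_frames: int = 100
    frame_dt: float = 1.0                       # ns
    hbond_occupancy: float = 1.0
    inward_fraction: float = 0.5
    waters_in_pocket: int | tuple = 0           # constant or per-frame schedule
    geometry_noise: float = 0.0                 # A
    pocket_center: tuple = (10.0, 10.0, 10.0)
    pocket_radius: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hbond_occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if not 0.0 <= self.inward_fraction <= 1.0:
            raise ValueError("inward fraction must lie in [0, 1]")
        if self.geometry_noise < 0:
            raise ValueError("geometry_noise must be non-negative")
        if np.isscalar(self.waters_in_pocket):
            self.waters_in_pocket = tuple(
                [int(self.waters_in_pocket)] * self.n_frames
            )
        else:
            self.waters_in_pocket = tuple(int(w) for w in self.waters_in_pocket)
            if len(self.waters_in_pocket) != self.n_frames:
                raise ValueError("water schedule length must equal n_frames")


# reference geometry (A).  In bonded frames both carboxyl oxygens satisfy the
# 3 A / 150 deg criteria with the N-H donor; unbonded frames shift the whole
# carboxylate 5 A away.
_DONOR_N = np.array([0.0, 0.0, 0.0])
_DONOR_H = np.array([1.0, 0.0, 0.0])
_OD1_BOND = np.array([2.8, 0.0, 0.0])
_OD2_BOND = np.array([2.8, 1.0, 0.0])
_CG_BOND = np.array([3.6, 0.5, 0.0])
_UNBOND_SHIFT = np.array([5.0, 0.0, 0.0])
INWARD_SITE = np.array([0.0, 8.0, 0.0])
OUTWARD_SITE = np.array([0.0, -8.0, 0.0])


def simulate_trajectory(spec: TrajSimSpec) -> Trajectory:
    """Build the scripted multi-frame fixture described by ``spec``.

    Ground truth (per-frame bonded/inward/water-count series) is stored in
    ``traj.meta['truth']``.  With ``geometry_noise = 0`` the scripted
    per-frame classifications hold exactly when analysed with the same
    criteria and pocket definition used in construction.
    """
    n = spec.n_frames
    bonded = _interleave(n, spec.hbond_occupancy)
    inward = _interleave(n, spec.inward_fraction)
    max_w = max(spec.waters_in_pocket) if spec.waters_in_pocket else 0
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.pocket_center, dtype=float)

    serial, name, resname, resid, chain = [], [], [], [], []

    def add(nm, rn, ri):
        serial.append(len(serial) + 1)
        name.append(nm)
        resname.append(rn)
        resid.append(ri)
        chain.append("A")

    add("N", "GLY", 1)
    add("H", "GLY", 1)
    add("CG", "ASP", 2)
    add("OD1", "ASP", 2)
    add("OD2", "ASP", 2)
    add("CZ", "ARG", 3)          # probe
    add("CD", "GLU", 4)          # inward reference
    add("CD", "GLU", 5)          # outward reference
    for w in range(max_w):
        add("O", "HOH", 100 + w)
    n_atoms = len(serial)

    coords = np.zeros((n, n_atoms, 3))
    # fixed in-pocket sites (<= 80% of the radius) and a far parking row
    in_sites = center + 0.8 * spec.pocket_radius * np.array(
        [[np.cos(k), np.sin(k), 0.0] for k in np.linspace(0, 2 * np.pi, max(max_w, 1),
                                                          endpoint=False)]
    )
    for f in range(n):
        coords[f, 0] = _DONOR_N
        coords[f, 1] = _DONOR_H
        shift = np.zeros(3) if bonded[f] else _UNBOND_SHIFT
        coords[f, 2] = _CG_BOND + shift
        coords[f, 3] = _OD1_BOND + shift
        coords[f, 4] = _OD2_BOND + shift
        site = INWARD_SITE if inward[f] else OUTWARD_SITE
        coords[f, 5] = site + np.array([0.5, 0.0, 0.0])
        coords[f, 6] = INWARD_SITE
        coords[f, 7] = OUTWARD_SITE
        k = spec.waters_in_pocket[f]
        for w in range(max_w):
            if w < k:
                coords[f, 8 + w] = in_sites[w]
            else:
                coords[f, 8 + w] = center + np.array(
                    [4.0 * spec.pocket_radius + 3.0 * w, 0.0, 0.0]
                )
    if spec.geometry_noise > 0:
        coords = coords + rng.normal(0, spec.geometry_noise, size=coords.shape)

    traj = Trajectory(
        serial=np.array(serial),
        name=np.array(name),
        resname=np.array(resname),
        resid=np.array(resid),
        chain=np.array(chain),
        coords=coords,
        times=np.arange(n) * spec.frame_dt,
        meta={},
    )
    traj.meta["truth"] = {
        "bonded": bonded,
        "inward": inward,
        "waters": np.array(spec.waters_in_pocket),
        "pocket_center": tuple(center),
        "pocket_radius": spec.pocket_radius,
        "donor": "A:1:N",
        "hydrogen": "A:1:H",
        "acceptors": ("A:2:OD1", "A:2:OD2"),
        "probe": "A:3:CZ",
        "inward_refs": ("A:4:CD",),
        "outward_refs": ("A:5:CD",),
        "seed": spec.seed,
    }
    return traj
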