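"""Steady-state photophysics calculations.

Nernst calibration of the membrane voltage from a K+ gradient, relative
fluorescence quantum yield against a reference standard, two-state
(Henderson-Hasselbalch) pKa fitting of Schiff-base titrations, HPLC retinal
isomer-fraction integration, and Stern-Volmer quenching analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants
from scipy.optimize import curve_fit
from scipy.stats import linregress

FARADAY = physical_constants["Faraday constant"][0]

__all__ = [
    "NernstInput",
    "QYInput",
    "TitrationSeries",
    "Chromatogram",
    "PkaFit",
    "nernst_voltage",
    "relative_quantum_yield",
    "fit_pka",
    "integrate_isomer_peaks",
    "stern_volmer_fit",
]


# ---------------------------------------------------------------------------
# Nernst voltage
# ---------------------------------------------------------------------------

@dataclass
class NernstInput:
    k_out: float            # mM
    k_in: float             # mM
    temperature: float = 293.15   # K (room temperature, ~20 C)
    z: int = 1

    def __post_init__(self):
        if self.k_out <= 0 or self.k_in <= 0:
            raise ValueError("ion concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def nernst_voltage(inp: NernstInput) -> float:
    """Equilibrium membrane voltage V = (RT/zF) ln([K]out/[K]in), in mV."""
    v = (GAS_CONSTANT * inp.temperature / (inp.z * FARADAY)) * np.log(
        inp.k_out / inp.k_in
    )
    return float(v * 1000.0)


# ---------------------------------------------------------------------------
# relative quantum yield
# ---------------------------------------------------------------------------

@dataclass
class QYInput:
    """Inputs for a relative quantum-yield determination.

    ``absorbance_*`` are decadic OD at the excitation wavelength; the Methods
    dilution rule keeps them at or below ~0.05 to avoid reabsorption (larger
    values warn).  ``fluorescence_*`` are total (integrated) fluorescence
    counts.
    """

    absorbance_sample: float
    absorbance_ref: float
    fluorescence_sample: float
    fluorescence_ref: float
    phi_ref: float
    n_sample: float
    n_ref: float

    def __post_init__(self):
        for a in (self.absorbance_sample, self.absorbance_ref):
            if a <= 0:
                raise ValueError("absorbance must be positive (f = 0 otherwise)")
            if a > 0.05:
                warnings.warn(
                    f"absorbance {a} exceeds the dilution rule (~0.05 OD); "
                    "reabsorption may bias the yield",
                    RuntimeWarning,
                )
        if self.fluorescence_sample <= 0 or self.fluorescence_ref <= 0:
            raise ValueError("fluorescence totals must be positive")


def relative_quantum_yield(inp: QYInput) -> float:
    """Phi_sample relative to a standard of known yield.

    Phi_s = Phi_ref * f_ref/f_s * F_s/F_ref * n_s^2/n_ref^2 with
    f = 1 - 10^(-A) (one minus transmittance, decadic absorbance).
    """
    f_sample = 1.0 - 10.0 ** (-inp.absorbance_sample)
    f_ref = 1.0 - 10.0 ** (-inp.absorbance_ref)
    return float(
        inp.phi_ref
        * (f_ref / f_sample)
        * (inp.fluorescence_sample / inp.fluorescence_ref)
        * (inp.n_sample**2 / inp.n_ref**2)
    )


# ---------------------------------------------------------------------------
# pKa titration
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """Absorbance at a fixed wavelength across a pH series."""

    ph: np.ndarray
    absorbance: np.ndarray
    truth: dict | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.ph = np.asarray(self.ph, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.ph.size == 0:
            raise ValueError("empty pH grid")
        if self.ph.size != self.absorbance.size:
            raise ValueError("ph and absorbance lengths differ")
        if np.any(np.diff(self.ph) <= 0):
            raise ValueError("ph grid must be strictly increasing")


@dataclass
class PkaFit:
    pka: float
    hill_n: float
    a_protonated: float
    a_deprotonated: float
    stderr: dict
    flags: list = field(default_factory=list)


def _titration_model(ph, pka, hill_n, a_prot, a_deprot):
    return a_deprot + (a_prot - a_deprot) / (1.0 + 10.0 ** (hill_n * (ph - pka)))


def fit_pka(series: TitrationSeries, fit_hill: bool = True) -> PkaFit:
    """Two-state protonation-equilibrium fit of an absorbance titration.

    Model: A(pH) = A_deprot + (A_prot - A_deprot)/(1 + 10^(n (pH - pKa))),
    the Henderson-Hasselbalch form with an optional Hill coefficient
    (default fitted, 1 = a single protonatable site).  The fit is invariant
    under affine transforms of the absorbance axis and under flipping the
    sign of the absorbance change (monitoring the protonated or the
    deprotonated band).
    """
    ph, a = series.ph, series.absorbance
    flags = list(series.flags)
    if ph.size < 5 or ph[-1] - ph[0] < 2.0:
        flags.append("fewer than 5 points or <2 pH units of coverage; "
                     "fit not trusted")
    a_prot0, a_deprot0 = float(a[0]), float(a[-1])
    mid = 0.5 * (a_prot0 + a_deprot0)
    pka0 = float(np.interp(mid, a, ph) if a[0] < a[-1] else np.interp(
        mid, a[::-1], ph[::-1]
    ))
    if not np.isfinite(pka0) or not ph[0] < pka0 < ph[-1]:
        pka0 = float(ph.mean())
    if fit_hill:
        popt, pcov = curve_fit(
            _titration_model, ph, a, p0=[pka0, 1.0, a_prot0, a_deprot0],
            maxfev=20000,
        )
    else:
        popt, pcov = curve_fit(
            lambda x, pka, ap, ad: _titration_model(x, pka, 1.0, ap, ad),
            ph, a, p0=[pka0, a_prot0, a_deprot0], maxfev=20000,
        )
        popt = np.insert(popt, 1, 1.0)
        pcov = np.insert(np.insert(pcov, 1, 0.0, axis=0), 1, 0.0, axis=1)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if not ph[0] <= popt[0] <= ph[-1]:
        flags.append("fitted pKa outside the measured pH range "
                     "(asymptote-only data?)")
    span = abs(popt[2] - popt[3])
    if span < 1e-9 * max(np.abs(a).max(), 1.0):
        raise ValueError("no transition within the pH range")
    return PkaFit(
        pka=float(popt[0]),
        hill_n=float(popt[1]),
        a_protonated=float(popt[2]),
        a_deprotonated=float(popt[3]),
        stderr={"pka": float(se[0]), "hill_n": float(se[1])},
        flags=flags,
    )


# ---------------------------------------------------------------------------
# HPLC isomer fractions
# ---------------------------------------------------------------------------

@dataclass
class Chromatogram:
    """HPLC trace: retention time (min) vs detector signal (a.u.)."""

    retention_time: np.ndarray
    signal: np.ndarray
    truth: dict | None = None

    def __post_init__(self):
        self.retention_time = np.asarray(self.retention_time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.retention_time) <= 0):
            raise ValueError("retention_time must be strictly increasing")
        if self.retention_time.size != self.signal.size:
            raise ValueError("time and signal lengths differ")


def integrate_isomer_peaks(chrom: Chromatogram, windows,
                           edge_fraction: float = 0.05) -> dict:
    """Baseline-corrected peak areas, normalised to fractions.

    ``windows`` is a list of (start, end, label) in retention-time units,
    non-overlapping.  The baseline under each window is the straight line
    between the mean signal levels in short edge segments (``edge_fraction``
    of the window at each side, at least one point) — averaging the edges
    keeps single noisy samples from tilting the baseline.  Areas are
    trapezoidal; negative corrected areas are clipped to zero with a
    warning.  Fractions sum to 1.
    """
    t, y = chrom.retention_time, chrom.signal
    wins = sorted(windows, key=lambda w: w[0])
    for (s1, e1, _), (s2, _, _) in zip(wins, wins[1:]):
        if s2 < e1:
            raise ValueError("windows overlap")
    areas, labels = [], []
    for start, end, label in windows:
        if start < t[0] or end > t[-1]:
            raise ValueError(f"window {label!r} outside the time range")
        mask = (t >= start) & (t <= end)
        tw, yw = t[mask], y[mask]
        k = max(1, int(round(edge_fraction * tw.size)))
        left_t, left_y = tw[:k].mean(), yw[:k].mean()
        right_t, right_y = tw[-k:].mean(), yw[-k:].mean()
        if right_t > left_t:
            baseline = left_y + (tw - left_t) * (
                (right_y - left_y) / (right_t - left_t)
            )
        else:
            baseline = np.full_like(tw, left_y)
        area = float(np.trapezoid(yw - baseline, tw))
        if area < 0:
            warnings.warn(
                f"negative corrected area for {label!r}; clipped to 0",
                RuntimeWarning,
            )
            area = 0.0
        areas.append(area)
        labels.append(label)
    total = sum(areas)
    if total <= 0:
        raise ValueError("all peak areas are zero")
    return {lab: a / total for lab, a in zip(labels, areas)}


# ---------------------------------------------------------------------------
# Stern-Volmer quenching
# ---------------------------------------------------------------------------

def stern_volmer_fit(quencher_conc, f0_over_f) -> tuple:
    """Linear Stern-Volmer fit F0/F = intercept + K_sv [Q].

    Returns (K_sv per mM, intercept); the intercept is expected close to 1.
    """
    q = np.asarray(quencher_conc, dtype=float)
    r = np.asarray(f0_over_f, dtype=float)
    if q.size < 3:
        raise ValueError("need at least three concentrations")
    if np.ptp(q) == 0:
        raise ValueError("quencher concentrations are all equal; "
                         "slope unidentifiable")
    res = linregress(q, r)
    return float(res.slope), float(res.intercept)
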