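"""Global (target) analysis of time-resolved difference spectra.

Transient absorption surfaces DeltaA(lambda, t) are modelled as a small number
of kinetic compartments interconverting by first-order rates, each convolved
with a Gaussian instrument response function (IRF).  For a sequential scheme
(1 -> 2 -> 3 -> ...) the fitted component spectra are evolution-associated
difference spectra (EADS); for a parallel scheme they are decay-associated
spectra (DAS).  Fitting uses variable projection: the nonlinear optimiser
works on the time constants (and optionally the IRF parameters) only, while
the component spectra are eliminated by an exact linear least-squares solve at
every trial point.

Times are handled in a single declared unit (normalised to ps by the readers);
wavelengths in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc, erfcx, ndtr

__all__ = [
    "TimeResolvedSpectra",
    "KineticScheme",
    "ConvergenceReport",
    "GlobalFitResult",
    "exp_conv_irf",
    "sequential_populations",
    "fit_global",
    "default_tau_init",
    "estimate_photoproduct_yield",
]

_SQRT2 = np.sqrt(2.0)

#: relative rate difference below which a cascade is treated as degenerate
DEGENERACY_TOL = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TimeResolvedSpectra:
    """A wavelength x delay matrix of absorbance differences.

    ``delta_a`` has shape (n_delays, n_wavelengths).  ``time_unit`` declares
    the unit of ``delays`` once for the whole object.
    """

    wavelengths: np.ndarray
    delays: np.ndarray
    delta_a: np.ndarray
    time_unit: str = "ps"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if self.delta_a.shape != (self.delays.size, self.wavelengths.size):
            raise ValueError(
                f"delta_a shape {self.delta_a.shape} does not match "
                f"(n_delays={self.delays.size}, n_wavelengths={self.wavelengths.size})"
            )
        if not np.all(np.isfinite(self.delta_a)):
            raise ValueError("delta_a contains non-finite values")
        if self.time_unit not in ("fs", "ps", "ns", "us"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")


@dataclass
class KineticScheme:
    """Topology plus time constants of a compartmental kinetic model.

    ``time_constants`` are in the data's time unit; the last one may be
    ``inf`` (a non-decaying terminal compartment, implemented as rate 0).
    ``branch_fraction`` is the fraction of the excited population entering the
    photoproduct chain and is only meaningful for ``topology='branched'``.
    """

    topology: str
    time_constants: tuple
    branch_fraction: float | None = None
    irf_center: float = 0.0
    irf_sigma: float = 0.0

    def __post_init__(self):
        if self.topology not in ("sequential", "parallel", "branched"):
            raise ValueError(f"unknown topology {self.topology!r}")
        taus = tuple(float(t) for t in self.time_constants)
        if len(taus) == 0:
            raise ValueError("at least one time constant required")
        for i, t in enumerate(taus):
            if np.isinf(t):
                if i != len(taus) - 1:
                    raise ValueError("only the terminal time constant may be infinite")
            elif t <= 0:
                raise ValueError(f"finite time constants must be positive (got {t})")
        self.time_constants = taus
        if self.topology == "branched":
            if self.branch_fraction is None:
                raise ValueError("branched topology requires branch_fraction")
            if not 0.0 <= self.branch_fraction <= 1.0:
                raise ValueError("branch_fraction must lie in [0, 1]")
        elif self.branch_fraction is not None:
            raise ValueError("branch_fraction only valid for branched topology")
        if self.irf_sigma < 0:
            raise ValueError("irf_sigma must be non-negative")

    @property
    def n_components(self) -> int:
        """Number of spectral components carried by the scheme."""
        if self.topology == "branched":
            # excited state, I-photoproducts and the recovered-ground sink
            return len(self.time_constants) + 1
        return len(self.time_constants)


@dataclass
class ConvergenceReport:
    success: bool
    iterations: int
    message: str
    cost: float


@dataclass
class GlobalFitResult:
    """Result of a global fit: scheme, spectra, concentrations, diagnostics.

    Reconstruction identity: ``concentrations @ component_spectra +
    residual_matrix`` equals the input data exactly, by construction of the
    inner linear solve.
    """

    scheme: KineticScheme
    component_spectra: np.ndarray   # (n_components, n_wavelengths)
    concentrations: np.ndarray      # (n_delays, n_components)
    residual_matrix: np.ndarray
    rms_residual: float
    tau_stderr: tuple
    convergence: ConvergenceReport
    wavelengths: np.ndarray | None = None
    delays: np.ndarray | None = None


# ---------------------------------------------------------------------------
# IRF-convolved exponentials
# ---------------------------------------------------------------------------

def exp_conv_irf(tau: float, mu: float, sigma: float, t: np.ndarray) -> np.ndarray:
    """Analytic convolution of a normalised Gaussian IRF with an exponential.

    Returns ``exp(-(t)/tau) * step(t)`` convolved with ``N(mu, sigma)``.  An
    infinite ``tau`` gives the Gaussian cumulative (a step through the IRF).
    Stable for ``|t - mu|`` up to ~50 sigma and ``tau/sigma`` from 1e-3 to 1e9:
    the rising flank uses the scaled complementary error function ``erfcx`` to
    avoid overflow, the decaying flank the plain product form, which underflows
    gracefully.
    """
    t = np.asarray(t, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not np.isinf(tau) and tau <= 0:
        raise ValueError("tau must be positive or infinite")

    if sigma == 0.0:
        if np.isinf(tau):
            return (t >= mu).astype(float)
        out = np.zeros_like(t)
        m = t >= mu
        out[m] = np.exp(-(t[m] - mu) / tau)
        return out

    x = (t - mu) / sigma
    if np.isinf(tau):
        return ndtr(x)

    k = 1.0 / tau
    z = (k * sigma - x) / _SQRT2
    out = np.empty_like(x)
    pos = z >= 0
    # erfc(z) = erfcx(z) exp(-z^2); combining exponents leaves exp(-x^2/2)
    out[pos] = 0.5 * erfcx(z[pos]) * np.exp(-0.5 * x[pos] ** 2)
    neg = ~pos
    out[neg] = 0.5 * np.exp(0.5 * (k * sigma) ** 2 - k * (t[neg] - mu)) * erfc(z[neg])
    return out


def _perturb_degenerate(rates: np.ndarray) -> np.ndarray:
    """Split near-identical finite rates to avoid the Bateman singularity."""
    rates = rates.copy()
    finite = rates > 0
    for i in range(len(rates)):
        for j in range(i + 1, len(rates)):
            if finite[i] and finite[j]:
                if abs(rates[i] - rates[j]) / rates[i] < DEGENERACY_TOL:
                    warnings.warn(
                        "near-degenerate rates perturbed by 1e-6 relative",
                        RuntimeWarning,
                        stacklevel=3,
                    )
                    rates[j] *= 1.0 + 1e-6 * (j - i)
    return rates


def _cascade(rates: np.ndarray, mu: float, sigma: float, t: np.ndarray) -> np.ndarray:
    """IRF-convolved Bateman cascade populations for a unidirectional chain.

    ``rates[j]`` is the decay rate of compartment j (the last may be 0 for a
    non-decaying terminal compartment).  Returns shape (len(t), len(rates)).
    """
    rates = _perturb_degenerate(np.asarray(rates, dtype=float))
    n = len(rates)
    basis = np.column_stack(
        [exp_conv_irf(np.inf if k == 0 else 1.0 / k, mu, sigma, t) for k in rates]
    )
    conc = np.zeros((t.size, n))
    for j in range(n):
        ks = rates[: j + 1]
        prefactor = np.prod(rates[:j]) if j > 0 else 1.0
        for i in range(j + 1):
            denom = np.prod([ks[l] - ks[i] for l in range(j + 1) if l != i])
            conc[:, j] += prefactor / denom * basis[:, i]
    return conc


def sequential_populations(scheme: KineticScheme, t: np.ndarray) -> np.ndarray:
    """Concentration profiles c_k(t) for a sequential or branched scheme.

    Sequential: the classic 1 -> 2 -> ... cascade, each compartment
    IRF-convolved; compartment k carries rate 1/tau_k (0 if infinite).

    Branched: the first compartment (excited state) splits with fraction phi
    into the photoproduct chain (remaining time constants) and (1 - phi) into
    a recovered-ground sink, returned as the last column.  With the sink
    included, the populations sum to the IRF cumulative at every t.
    """
    t = np.asarray(t, dtype=float)
    rates = np.array(
        [0.0 if np.isinf(tau) else 1.0 / tau for tau in scheme.time_constants]
    )
    if scheme.topology == "sequential":
        return _cascade(rates, scheme.irf_center, scheme.irf_sigma, t)
    if scheme.topology == "branched":
        phi = scheme.branch_fraction
        chain = _cascade(rates, scheme.irf_center, scheme.irf_sigma, t)
        conc = np.empty((t.size, len(rates) + 1))
        conc[:, 0] = chain[:, 0]                      # excited state
        conc[:, 1:-1] = phi * chain[:, 1:]            # photoproduct chain
        # ground sink integrates (1-phi) of the excited-state decay flux
        sink_chain = _cascade(
            np.array([rates[0], 0.0]), scheme.irf_center, scheme.irf_sigma, t
        )
        conc[:, -1] = (1.0 - phi) * sink_chain[:, 1]
        return conc
    if scheme.topology == "parallel":
        return np.column_stack(
            [
                exp_conv_irf(tau, scheme.irf_center, scheme.irf_sigma, t)
                for tau in scheme.time_constants
            ]
        )
    raise ValueError(scheme.topology)


# ---------------------------------------------------------------------------
# variable-projection global fit
# ---------------------------------------------------------------------------

def default_tau_init(delays: np.ndarray, n_finite: int) -> tuple:
    """Log-spaced initial time constants spanning the data's time decades."""
    pos = delays[delays > 0]
    lo = max(pos.min(), 1e-6 * pos.max())
    hi = pos.max() / 3.0
    return tuple(np.geomspace(lo * 3.0, hi, n_finite))


def _design_matrix(taus_finite, has_infinite, scheme_init, mu, sigma, delays):
    taus = tuple(taus_finite) + ((np.inf,) if has_infinite else ())
    scheme = replace(
        scheme_init, time_constants=taus, irf_center=mu, irf_sigma=sigma
    )
    return sequential_populations(scheme, delays), scheme


def _solve_spectra(conc, data, weights=None):
    if weights is not None:
        w = weights[:, None]
        spectra, *_ = np.linalg.lstsq(conc * w, data * w, rcond=None)
    else:
        spectra, *_ = np.linalg.lstsq(conc, data, rcond=None)
    return spectra


def fit_global(
    data: TimeResolvedSpectra,
    scheme_init: KineticScheme,
    fit_irf: bool = False,
    weights: np.ndarray | None = None,
    max_nfev: int = 2000,
) -> GlobalFitResult:
    """Variable-projection global fit of a time-resolved spectral surface.

    The outer nonlinear optimisation runs over log(tau) for the finite time
    constants (and optionally the IRF centre and width); at each trial the
    component spectra are obtained by an exact linear least-squares solve, so
    they never appear as free parameters.  Finite time constants are sorted
    ascending before reporting (permuting the initial order does not change
    the converged loss).  Standard errors for the time constants come from the
    local curvature of the residual at the optimum.

    Parameters
    ----------
    data : TimeResolvedSpectra
    scheme_init : KineticScheme
        Initial topology and time constants; an infinite terminal constant is
        kept fixed (rate 0) and not optimised.
    fit_irf : bool
        Also optimise the IRF centre and sigma.
    weights : array (n_delays,), optional
        Per-delay weights applied to rows of the residual.
    """
    delays = data.delays
    surface = data.delta_a
    taus0 = scheme_init.time_constants
    has_inf = np.isinf(taus0[-1])
    finite0 = np.array([t for t in taus0 if not np.isinf(t)], dtype=float)
    if len(set(np.round(np.log(finite0), 12))) != len(finite0):
        raise ValueError("initial finite time constants must be distinct")
    if scheme_init.n_components > delays.size:
        raise ValueError("more components than delay points")

    n_finite = finite0.size
    p0 = list(np.log(finite0))
    if fit_irf:
        p0 += [scheme_init.irf_center, np.log(max(scheme_init.irf_sigma, 1e-6))]
    p0 = np.asarray(p0, dtype=float)

    def unpack(p):
        taus = np.exp(p[:n_finite])
        if fit_irf:
            mu, sigma = p[n_finite], np.exp(p[n_finite + 1])
        else:
            mu, sigma = scheme_init.irf_center, scheme_init.irf_sigma
        return taus, mu, sigma

    def residuals(p):
        taus, mu, sigma = unpack(p)
        conc, _ = _design_matrix(taus, has_inf, scheme_init, mu, sigma, delays)
        spectra = _solve_spectra(conc, surface, weights)
        res = surface - conc @ spectra
        if weights is not None:
            res = res * weights[:, None]
        return res.ravel()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = least_squares(
            residuals, p0, method="trf", x_scale="jac", max_nfev=max_nfev
        )

    taus, mu, sigma = unpack(sol.x)
    order = np.argsort(taus)
    taus = taus[order]
    conc, scheme = _design_matrix(taus, has_inf, scheme_init, mu, sigma, delays)
    if np.linalg.matrix_rank(conc) < conc.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient concentration matrix")
    spectra = _solve_spectra(conc, surface, weights)
    residual = surface - conc @ spectra
    rms = float(np.sqrt(np.mean(residual ** 2)))

    # curvature-based standard errors on log(tau) -> relative errors on tau
    m = sol.fun.size - sol.x.size - scheme.n_components * data.wavelengths.size
    sigma2 = 2.0 * sol.cost / max(m, 1)
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * sigma2
        se_log = np.sqrt(np.clip(np.diag(cov)[:n_finite], 0, None))[order]
        tau_se = tuple(taus * se_log)
    except np.linalg.LinAlgError:  # pragma: no cover
        tau_se = tuple(np.full(n_finite, np.nan))

    if not sol.success:
        warnings.warn(
            f"global fit did not converge: {sol.message}", RuntimeWarning
        )
    report = ConvergenceReport(
        success=bool(sol.success),
        iterations=int(sol.nfev),
        message=str(sol.message),
        cost=float(sol.cost),
    )
    return GlobalFitResult(
        scheme=scheme,
        component_spectra=np.asarray(spectra),
        concentrations=conc,
        residual_matrix=residual,
        rms_residual=rms,
        tau_stderr=tau_se,
        convergence=report,
        wavelengths=data.wavelengths,
        delays=delays,
    )


# ---------------------------------------------------------------------------
# photoproduct yield
# ---------------------------------------------------------------------------

def estimate_photoproduct_yield(
    result: GlobalFitResult,
    gsb_wavelength: float,
    initial_component: int = 0,
) -> float:
    """Fraction of the initial bleach that never recovers.

    The isomerisation (photoproduct) yield is estimated as the ratio of the
    terminal component spectrum to the earliest post-IRF component spectrum,
    both evaluated at the ground-state-bleach wavelength: the terminal
    amplitude measures molecules still absent from the ground state at late
    times, the initial amplitude the full excited population.
    """
    if result.component_spectra.shape[0] < 2:
        raise ValueError("need at least two components for a yield estimate")
    wl = result.wavelengths
    if wl is None or not (wl[0] <= gsb_wavelength <= wl[-1]):
        raise ValueError("gsb_wavelength outside the fitted wavelength range")
    first = np.interp(gsb_wavelength, wl, result.component_spectra[initial_component])
    last = np.interp(gsb_wavelength, wl, result.component_spectra[-1])
    scale = np.max(np.abs(result.component_spectra))
    if abs(first) < 1e-9 * scale:
        raise ValueError("initial bleach amplitude near zero; ratio undefined")
    return float(abs(last) / abs(first))
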