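"""FCS autocorrelation fitting and Stokes–Einstein hydrodynamics.

A single diffusing species in a 3D Gaussian confocal volume produces the
intensity autocorrelation

    G(τ) = (1/N) · (1 + τ/τ_D)^−1 · (1 + τ/(κ²·τ_D))^−1/2

with ``N`` the mean number of particles in the focus, ``τ_D`` the lateral
diffusion time and ``κ`` the axial-to-lateral aspect ratio of the focus.
Given the lateral focal radius ``w0`` from a calibration measurement, the
diffusion coefficient is ``D = w0²/(4·τ_D)`` and the hydrodynamic radius
follows from Stokes–Einstein, ``R_h = k_B·T/(6π·η·D)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

BOLTZMANN = 1.380649e-23  # J/K

#: dynamic viscosity of water at 30 °C, Pa·s
WATER_VISCOSITY_30C = 0.7972e-3


@dataclass
class FcsCurve:
    """Lag-time grid (seconds, strictly increasing) and correlation amplitudes."""

    lags: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.shape != self.G.shape:
            raise ValueError("lags and G must have equal length")
        if self.lags.size and (np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0)):
            raise ValueError("lags must be positive and strictly increasing")


@dataclass
class FcsFit:
    n_particles: float
    tau_D: float
    kappa: float
    rss: float
    stderr: dict = field(default_factory=dict)


@dataclass
class HydroResult:
    D: float          # m^2/s
    R_h: float        # nm
    T: float          # K
    eta: float        # Pa s
    w0: float         # m
    tau_D: float      # s


def fcs_model(lag, n_particles: float, tau_D: float, kappa: float):
    """Single-component 3D-diffusion autocorrelation G(τ)."""
    if n_particles <= 0 or tau_D <= 0 or kappa <= 0:
        raise ValueError("n_particles, tau_D and kappa must be positive")
    lag = np.asarray(lag, dtype=float)
    return (1.0 / n_particles) / ((1.0 + lag / tau_D) * np.sqrt(1.0 + lag / (kappa**2 * tau_D)))


def fit_fcs(curve: FcsCurve, fix_kappa: float = 6.0) -> FcsFit:
    """Least-squares fit of the 3D-diffusion model with fixed aspect ratio.

    Initial guesses come from the curve itself: the zero-lag amplitude gives
    1/N, and the lag at which G falls to half its amplitude estimates τ_D.
    Warns when the lag grid does not reach beyond τ_D (no decay information).
    """
    if curve.lags.size < 20:
        raise ValueError("need at least 20 lag points")
    g0 = curve.G[0]
    if g0 <= 0:
        raise ValueError("non-positive correlation amplitude at the shortest lag")
    n0 = 1.0 / g0
    half = np.argmin(np.abs(curve.G - g0 / 2.0))
    tau0 = max(curve.lags[half], curve.lags[0])

    def model(lag, n, tau):
        return fcs_model(lag, n, tau, fix_kappa)

    try:
        popt, pcov = curve_fit(
            model, curve.lags, curve.G, p0=(n0, tau0),
            bounds=([1e-6, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"FCS fit did not converge: {exc}") from exc
    resid = curve.G - model(curve.lags, *popt)
    fit = FcsFit(
        n_particles=float(popt[0]), tau_D=float(popt[1]), kappa=fix_kappa,
        rss=float(np.sum(resid**2)),
        stderr={"n_particles": float(np.sqrt(pcov[0, 0])), "tau_D": float(np.sqrt(pcov[1, 1]))},
    )
    if curve.lags[-1] < fit.tau_D:
        warnings.warn(
            "lag grid ends before the fitted diffusion time; fit is ill-conditioned",
            RuntimeWarning,
        )
    return fit


def hydrodynamic_radius(
    tau_D: float,
    w0: float,
    T: float = 303.15,
    eta: float = WATER_VISCOSITY_30C,
) -> HydroResult:
    """Diffusion coefficient and Stokes–Einstein hydrodynamic radius.

    Parameters are the diffusion time (s), lateral focal radius w0 (m),
    temperature (K, default 30 °C) and solvent viscosity (Pa·s, default
    water at 30 °C). Returns R_h in nm.
    """
    if tau_D <= 0 or w0 <= 0 or T <= 0 or eta <= 0:
        raise ValueError("all inputs must be positive")
    D = w0**2 / (4.0 * tau_D)
    R_h_m = BOLTZMANN * T / (6.0 * np.pi * eta * D)
    return HydroResult(D=D, R_h=R_h_m * 1e9, T=T, eta=eta, w0=w0, tau_D=tau_D)
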