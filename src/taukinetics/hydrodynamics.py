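"""Seed length estimation from dynamic light scattering.

A single-exponential intensity autocorrelation

    g2(τ) = 1 + β·exp(−2·D·q²·τ)

yields the translational diffusion coefficient D of the sonicated seeds,
which the Stokes–Einstein relation converts to a Stokes radius
Rs = kB·T/(6πηD).  The seed is then modelled as a prolate ellipsoid with
long axis a (fibril length) and short axis b (fibril thickness); equating
the ellipsoid friction 6πηa/ln(2a/b) to the sphere friction 6πηRs gives a
one-dimensional root problem for a, and the monomer spacing along the
fibril axis converts a to a seed length in monomers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from lmfit import Model as LmModel
from scipy.optimize import brentq

from .exceptions import FitError, InvalidInputError

__all__ = [
    "BOLTZMANN_J_PER_K",
    "InstrumentParams",
    "AutocorrelationCurve",
    "DiffusionFit",
    "SeedGeometry",
    "scattering_vector",
    "fit_autocorrelation",
    "stokes_radius",
    "diffusion_from_radius",
    "ellipsoid_long_axis",
    "seed_length_monomers",
    "size_seed",
]

BOLTZMANN_J_PER_K = 1.38e-23  # J/K

#: dynamic viscosity of water at 25 °C, Pa·s — default buffer viscosity
DEFAULT_VISCOSITY_PA_S = 0.89e-3
DEFAULT_TEMPERATURE_K = 298.0
#: axial rise per tau monomer along the fibril, nm
DEFAULT_MONOMER_SPACING_NM = 2.0


@dataclass(frozen=True)
class InstrumentParams:
    """DLS instrument and solvent parameters.

    lambda0 (laser wavelength, m) and theta (scattering angle, degrees) are
    instrument-specific and have no defaults; n is the solvent refractive
    index, T the temperature in K and eta the buffer viscosity in Pa·s.
    """

    lambda0: float
    theta: float
    n: float = 1.334
    T: float = DEFAULT_TEMPERATURE_K
    eta: float = DEFAULT_VISCOSITY_PA_S

    def __post_init__(self):
        if self.lambda0 <= 0 or self.n <= 0 or self.T <= 0 or self.eta <= 0:
            raise InvalidInputError("instrument parameters must be positive")
        if not 0 < self.theta < 180:
            raise InvalidInputError(
                f"scattering angle must be in (0, 180) degrees, got {self.theta}")


@dataclass(frozen=True)
class AutocorrelationCurve:
    """An intensity autocorrelation g2(τ), optionally replicate-averaged."""

    lags: np.ndarray  # s
    g2: np.ndarray
    replicates_averaged: int = 1

    def __post_init__(self):
        lags = np.asarray(self.lags, float)
        g2 = np.asarray(self.g2, float)
        if lags.shape != g2.shape or lags.ndim != 1 or lags.size < 5:
            raise InvalidInputError("need >= 5 equal-length lag/g2 points")
        if np.any(np.diff(lags) <= 0):
            raise InvalidInputError("lags must be strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g2", g2)


@dataclass(frozen=True)
class DiffusionFit:
    """Result of the single-exponential autocorrelation fit."""

    beta: float  # coherence factor
    D: float  # m²/s
    beta_stderr: float | None = None
    D_stderr: float | None = None

    def __post_init__(self):
        if not 0 < self.beta <= 1.5:
            raise InvalidInputError(f"coherence factor out of range: {self.beta}")
        if self.D <= 0:
            raise InvalidInputError(f"diffusion coefficient must be positive: {self.D}")


@dataclass(frozen=True)
class SeedGeometry:
    """Prolate-ellipsoid seed model and derived length."""

    a: float  # long axis (fibril length), nm
    b: float  # short axis (fibril thickness), nm
    spacing: float  # nm per monomer
    L: float  # seed length, monomers
    friction_equiv_Rs: float  # nm

    def __post_init__(self):
        if not (self.a > self.b > 0):
            raise InvalidInputError("need a > b > 0")
        if 2 * self.a / self.b <= 1:
            raise InvalidInputError("aspect ratio too small: ln(2a/b) undefined")

    def to_dict(self) -> dict:
        return {
            "a_nm": self.a,
            "b_nm": self.b,
            "spacing_nm_per_monomer": self.spacing,
            "L_monomers": self.L,
            "Rs_nm": self.friction_equiv_Rs,
        }


def scattering_vector(params: InstrumentParams) -> float:
    """Scattering wave vector q = (4πn/λ0)·sin(θ/2), in m⁻¹."""
    theta_rad = math.radians(params.theta)
    return 4.0 * math.pi * params.n / params.lambda0 * math.sin(theta_rad / 2.0)


def fit_autocorrelation(curve: AutocorrelationCurve, q: float) -> DiffusionFit:
    """Least-squares fit of g2(τ) = 1 + β·exp(−2Dq²τ).

    The baseline is fixed at exactly 1; β and D are free.  Fails with
    diagnostics when the curve carries no decay.
    """
    if q <= 0:
        raise InvalidInputError(f"scattering vector must be positive, got {q}")
    tau, g2 = curve.lags, curve.g2
    amp0 = g2[0] - 1.0
    if amp0 <= 1e-6 or (g2[0] - g2[-1]) < 0.05 * max(amp0, 1e-12):
        raise FitError(
            f"autocorrelation shows no decay (g2[0]={g2[0]:.6g}, "
            f"g2[-1]={g2[-1]:.6g}); nothing to fit"
        )

    # fit in terms of the decay rate Gamma = 2Dq^2 (order 1/τ), which is
    # numerically well scaled, then convert back to D
    def model(tau, beta, gamma):
        return 1.0 + beta * np.exp(-gamma * tau)

    # initial rate from the lag where the decay reaches 1/e of its amplitude
    target = 1.0 + amp0 / math.e
    idx = int(np.argmin(np.abs(g2 - target)))
    tau_e = max(tau[idx], tau[1])

    lm = LmModel(model)
    pars = lm.make_params(beta=min(max(amp0, 1e-3), 1.0), gamma=1.0 / tau_e)
    pars["beta"].set(min=1e-6, max=1.5)
    pars["gamma"].set(min=1e-12 / tau[-1])
    out = lm.fit(g2, pars, tau=tau)
    if not out.success:
        raise FitError(f"autocorrelation fit failed: {out.message}")
    b = out.params["beta"]
    g = out.params["gamma"]
    scale = 2.0 * q**2
    return DiffusionFit(beta=float(b.value), D=float(g.value) / scale,
                        beta_stderr=None if b.stderr is None else float(b.stderr),
                        D_stderr=None if g.stderr is None else float(g.stderr) / scale)


def stokes_radius(D: float, T: float = DEFAULT_TEMPERATURE_K,
                  eta: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Stokes–Einstein radius Rs = kB·T/(6πηD), in metres."""
    if D <= 0 or T <= 0 or eta <= 0:
        raise InvalidInputError("D, T and eta must all be positive")
    return BOLTZMANN_J_PER_K * T / (6.0 * math.pi * eta * D)


def diffusion_from_radius(Rs: float, T: float = DEFAULT_TEMPERATURE_K,
                          eta: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Inverse of :func:`stokes_radius` (same formula by symmetry)."""
    return stokes_radius(Rs, T, eta)


def ellipsoid_long_axis(Rs: float, b: float) -> float:
    """Long axis a of a prolate ellipsoid with sphere-equivalent friction.

    Solves a/ln(2a/b) = Rs for the elongated (a ≥ b·e/2) branch by
    bracketed root finding (Brent) on [b·e/2, 1000·Rs], then one Newton
    polish.  The friction function has its minimum b·e/2 at the branch
    point, so a solution exists iff Rs ≥ b·e/2; when equality holds the
    root is a = Rs exactly.  Inputs and output share one length unit
    (nm in typical use).
    """
    if Rs <= 0 or b <= 0:
        raise InvalidInputError("Rs and b must be positive")

    def residual(a):
        return a / math.log(2.0 * a / b) - Rs

    a_star = 0.5 * b * math.e  # branch point: minimum of a/ln(2a/b)
    if Rs < a_star * (1.0 - 1e-12):
        raise FitError(
            f"no ellipsoid solution: Rs = {Rs:.6g} below the friction "
            f"minimum b·e/2 = {a_star:.6g}"
        )
    if Rs <= a_star * (1.0 + 1e-12):
        return a_star  # tangent root, a = Rs
    hi = 1e3 * Rs
    if residual(hi) < 0:
        raise FitError(
            f"no sign change for a/ln(2a/b) = {Rs} in [{a_star:.4g}, {hi:.4g}] "
            f"with b = {b}; no ellipsoid solution"
        )
    a = brentq(residual, a_star, hi, xtol=1e-12 * Rs, rtol=8.9e-16)
    # one Newton polish: d/da [a/ln(2a/b)] = (ln(2a/b) - 1)/ln(2a/b)^2
    log_term = math.log(2.0 * a / b)
    deriv = (log_term - 1.0) / log_term**2
    if abs(deriv) > 1e-12:
        a -= residual(a) / deriv
    if abs(a / math.log(2.0 * a / b) - Rs) > 1e-9 * Rs:
        raise FitError("root polishing failed to meet tolerance")
    return a


def seed_length_monomers(a: float, spacing: float = DEFAULT_MONOMER_SPACING_NM) -> float:
    """Seed length in monomers, L = a/spacing (both in nm)."""
    if a <= 0 or spacing <= 0:
        raise InvalidInputError("a and spacing must be positive")
    return a / spacing


def size_seed(
    curve: AutocorrelationCurve,
    instrument: InstrumentParams,
    b_nm: float = 10.0,
    spacing_nm: float = DEFAULT_MONOMER_SPACING_NM,
) -> tuple[DiffusionFit, SeedGeometry]:
    """Full chain: autocorrelation → D → Rs → ellipsoid long axis → L."""
    q = scattering_vector(instrument)
    diff = fit_autocorrelation(curve, q)
    Rs_m = stokes_radius(diff.D, instrument.T, instrument.eta)
    Rs_nm = Rs_m * 1e9
    a_nm = ellipsoid_long_axis(Rs_nm, b_nm)
    L = seed_length_monomers(a_nm, spacing_nm)
    geom = SeedGeometry(a=a_nm, b=b_nm, spacing=spacing_nm, L=L,
                        friction_equiv_Rs=Rs_nm)
    return diff, geom


def report_json(diff: DiffusionFit, geom: SeedGeometry, path,
                instrument: InstrumentParams | None = None) -> None:
    """Write the seed-sizing report with all assumptions echoed."""
    payload = {
        "beta": diff.beta,
        "D_m2s": diff.D,
        "Rs_nm": geom.friction_equiv_Rs,
        "a_nm": geom.a,
        "L_monomers": geom.L,
        "assumptions": {
            "b_nm": geom.b,
            "spacing_nm_per_monomer": geom.spacing,
            "baseline_fixed_at_1": True,
        },
    }
    if instrument is not None:
        payload["instrument"] = {
            "lambda0_m": instrument.lambda0,
            "theta_deg": instrument.theta,
            "n": instrument.n,
            "T_K": instrument.T,
            "eta_Pa_s": instrument.eta,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
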