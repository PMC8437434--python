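"""Nucleation / saturating-elongation / fragmentation model of tau aggregation.

The model tracks two moments of the fibril length distribution: the number
concentration P(t) and the mass concentration M(t), both in µM, with time in
minutes.  New fibrils appear through primary nucleation from ``nc`` monomers
(rate ``kn·m^nc``) and through fragmentation of existing fibril mass (rate
``km·M``).  Fibril mass grows by monomer addition at both ends with a
saturating (Michaelis-Menten-like) dependence on the free monomer
concentration::

    dP/dt = kn·m^nc + km·M
    dM/dt = 2·kp·(KE·m / (KE + m))·P

The free monomer concentration is never integrated: mass conservation
``m = m0 + M0 − M`` is enforced algebraically, which reduces the system to
two ODEs and makes conservation exact by construction.

Units are µM and minutes throughout; rate constants carry the corresponding
units (documented on :class:`KineticParameters`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .datasets import Condition, MassTrace
from .exceptions import IntegrationError, InvalidInputError

__all__ = [
    "KineticParameters",
    "InitialConditions",
    "Trajectory",
    "derivatives",
    "simulate",
    "simulate_mass_curve",
    "seeded_initial_conditions",
]

#: default solver tolerances (stiff-capable LSODA)
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the aggregation model.

    Parameters
    ----------
    kn : float
        Primary nucleation rate constant, µM^(1−nc)·min⁻¹.
    kp : float
        Elongation rate constant, µM⁻¹·min⁻¹.
    km : float
        Fragmentation rate constant, min⁻¹.
    KE : float
        Elongation saturation constant, µM; the monomer concentration at
        half-maximal growth rate.
    nc : int
        Critical nucleus size (smallest growth-competent aggregate),
        dimensionless; fixed model setting, default 2, never fitted.
    """

    kn: float
    kp: float
    km: float
    KE: float
    nc: int = 2

    def __post_init__(self):
        for name in ("kn", "kp", "km"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.KE) or self.KE <= 0:
            raise InvalidInputError(f"KE must be positive, got {self.KE}")
        if int(self.nc) != self.nc or self.nc < 1:
            raise InvalidInputError(f"nc must be an integer >= 1, got {self.nc}")
        object.__setattr__(self, "nc", int(self.nc))

    def scaled(self, fn: float = 1.0, fp: float = 1.0, fm: float = 1.0) -> "KineticParameters":
        """Return a copy with kn, kp, km multiplied by (fn, fp, fm)."""
        return replace(self, kn=self.kn * fn, kp=self.kp * fp, km=self.km * fm)

    def to_dict(self) -> dict:
        return {
            "kn": {"value": self.kn, "units": f"uM^{1 - self.nc}.min^-1"},
            "kp": {"value": self.kp, "units": "uM^-1.min^-1"},
            "km": {"value": self.km, "units": "min^-1"},
            "KE": {"value": self.KE, "units": "uM"},
            "nc": {"value": self.nc, "units": "monomers"},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        vals = {k: (v["value"] if isinstance(v, dict) else v) for k, v in d.items()}
        return cls(**vals)


@dataclass(frozen=True)
class InitialConditions:
    """Initial state of a kinetic run.

    Unseeded runs have M0 = P0 = 0; seeded runs start from preformed fibril
    fragments of mass M0 and mean length L monomers, hence P0 = M0/L.
    """

    m0: float  # µM monomer
    M0: float = 0.0  # µM seed mass
    P0: float = 0.0  # µM seed number

    def __post_init__(self):
        if self.m0 <= 0 or not np.isfinite(self.m0):
            raise InvalidInputError(f"m0 must be positive, got {self.m0}")
        if self.M0 < 0 or self.P0 < 0:
            raise InvalidInputError("M0 and P0 must be non-negative")
        if self.M0 == 0 and self.P0 > 0:
            raise InvalidInputError("P0 > 0 requires M0 > 0")

    @property
    def total_mass(self) -> float:
        return self.m0 + self.M0


def seeded_initial_conditions(M0: float, L: float, m0: float) -> InitialConditions:
    """Initial conditions for a seeded run: P0 = M0/L.

    Parameters
    ----------
    M0 : float
        Seed mass concentration, µM.
    L : float
        Mean seed length in monomers (>= 1).
    m0 : float
        Initial free monomer concentration, µM.
    """
    if L < 1:
        raise InvalidInputError(f"seed length L must be >= 1 monomer, got {L}")
    if M0 < 0:
        raise InvalidInputError(f"seed mass must be >= 0, got {M0}")
    return InitialConditions(m0=m0, M0=M0, P0=M0 / L)


def derivatives(state, params: KineticParameters, total_mass: float):
    """Right-hand side of the moment equations, evaluated at one state.

    Parameters
    ----------
    state : tuple (M, P) or object with .M and .P
        Fibril mass and number concentrations, µM.  The free monomer is
        reconstructed as ``m = max(0, total_mass − M)``.
    params : KineticParameters
    total_mass : float
        Conserved total tau mass m0 + M0 of the trajectory, µM.

    Returns
    -------
    (dP_dt, dM_dt) : tuple of float, µM·min⁻¹
    """
    if hasattr(state, "M"):
        M, P = state.M, state.P
    else:
        M, P = state
    if not (np.isfinite(M) and np.isfinite(P)) or M < 0 or P < 0:
        raise InvalidInputError(f"invalid state (M={M}, P={P})")
    if not np.isfinite(total_mass) or total_mass < 0:
        raise InvalidInputError(f"invalid total mass {total_mass}")
    m = max(0.0, total_mass - M)
    dP = params.kn * m**params.nc + params.km * M
    dM = 2.0 * params.kp * (params.KE * m / (params.KE + m)) * P
    return dP, dM


@dataclass(frozen=True)
class Trajectory:
    """A simulated trajectory of the moment equations."""

    times: np.ndarray  # min
    m: np.ndarray  # µM free monomer
    M: np.ndarray  # µM fibril mass
    P: np.ndarray  # µM fibril number
    params: KineticParameters
    init: InitialConditions

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_min": self.times, "m_uM": self.m, "M_uM": self.M, "P_uM": self.P}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def mass_trace(self, condition: Condition | None = None) -> MassTrace:
        if condition is None:
            condition = Condition(
                m0=self.init.m0,
                seeded=self.init.M0 > 0,
                seed_mass=self.init.M0,
            )
        return MassTrace(self.times.copy(), self.M.copy(), condition)


def simulate(
    params: KineticParameters,
    init: InitialConditions,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the moment equations on a fixed output grid.

    ``times`` must be strictly increasing and start at 0.  The integrator is
    LSODA (switches to implicit BDF when the system stiffens near full
    conversion); the free monomer is clamped at zero inside the RHS to absorb
    numeric overshoot.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise InvalidInputError("times must be a 1-D array with >= 2 points")
    if times[0] != 0:
        raise InvalidInputError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise InvalidInputError("times must be strictly increasing")

    mtot = init.total_mass
    kn, kp, km, KE, nc = params.kn, params.kp, params.km, params.KE, params.nc

    def rhs(t, y):
        M, P = y
        m = mtot - M
        if m < 0.0:
            m = 0.0
        dP = kn * m**nc + km * M
        dM = 2.0 * kp * (KE * m / (KE + m)) * P
        return (dM, dP)

    sol = solve_ivp(
        rhs,
        (0.0, times[-1]),
        (init.M0, init.P0),
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed: {sol.message}", params=params
        )
    M = np.clip(sol.y[0], 0.0, mtot)
    P = np.maximum(sol.y[1], 0.0)
    m = mtot - M
    return Trajectory(times, m, M, P, params, init)


def simulate_mass_curve(
    params: KineticParameters,
    init: InitialConditions,
    times,
    condition: Condition | None = None,
    **kwargs,
) -> MassTrace:
    """Simulate and return the fibril mass trace (trajectory on ``.trajectory``)."""
    traj = simulate(params, init, times, **kwargs)
    trace = traj.mass_trace(condition)
    object.__setattr__(trace, "trajectory", traj)
    return trace
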