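"""Global kinetic fitting and chaperone mechanism dissection.

The baseline tau kinetics are fitted in two steps.  Unseeded data cannot
separate the elongation rate kp from the nucleation and fragmentation rates
(the mass curve depends only on the products kn·kp and km·kp), so step one
fixes kp ≡ 1 and fits the reduced composites k'n = kn·kp, k'm = km·kp and
the saturation constant KE globally across all monomer concentrations.
Step two breaks the degeneracy with seeded traces (P0 = M0/L) and fits kp
while tying kn = k'n/kp and km = k'm/kp so that the composites are
preserved.

Chaperone effects are quantified as per-concentration multiplicative scale
factors on individual microscopic rates: single-rate fits vary only kn or
only kp (km is held fixed — chaperones do not change fibril length
distributions), while the joint fit varies several factors simultaneously
on combined unseeded + seeded data.  Competing single-rate hypotheses are
ranked by their residuals.

All models follow a Model → fit() → Results pattern: the Model holds data
and configuration, ``fit`` runs the optimization, and the Results object
carries estimates, residual diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import differential_evolution, least_squares, minimize_scalar

from .datasets import KineticDataset, MassTrace
from .exceptions import (
    FitError,
    InsufficientDataError,
    IntegrationError,
    InvalidInputError,
)
from .kinetics import InitialConditions, KineticParameters, seeded_initial_conditions, simulate

__all__ = [
    "FitSettings",
    "ReducedRates",
    "RateUncertainty",
    "UnseededGlobalModel",
    "SeededGlobalModel",
    "ChaperoneRateModel",
    "ReducedRatesResults",
    "AbsoluteRatesResults",
    "ChaperoneEffectResults",
    "HypothesisComparison",
    "fit_unseeded_global",
    "fit_seeded_global",
    "fit_chaperone_single_rate",
    "fit_chaperone_joint",
    "compare_rate_hypotheses",
    "estimate_rate_errors",
]

_PENALTY = 1e8


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration shared by all kinetic fits.

    Multi-parameter searches use bounded differential evolution in
    log10-parameter space followed by a least-squares polish; one-parameter
    searches use a deterministic coarse log-grid scan refined by bounded
    scalar minimization.  ``rng_seed`` is recorded in every report and makes
    every fit bit-reproducible.
    """

    max_iterations: int = 60
    popsize: int = 12
    tolerance: float = 1e-3
    rng_seed: int = 0
    polish: bool = True
    ode_rtol: float = 1e-6
    ode_atol: float = 1e-9
    grid_points: int = 25
    #: linear-space (lo, hi) bounds per parameter name; all positive
    bounds: dict = field(default_factory=dict)
    weighting: str = "none"  # or "per_trace"

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo < hi):
                raise InvalidInputError(f"bounds for {name} must be finite positive")
        if self.weighting not in ("none", "per_trace"):
            raise InvalidInputError("weighting must be 'none' or 'per_trace'")

    def log_bounds(self, name: str, default: tuple) -> tuple:
        lo, hi = self.bounds.get(name, default)
        return (np.log10(lo), np.log10(hi))

    def settings_hash(self) -> str:
        payload = json.dumps(
            {k: (sorted(v.items()) if isinstance(v, dict) else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_DEFAULT_BOUNDS = {
    "kn_prime": (1e-8, 1.0),
    "km_prime": (1e-8, 1.0),
    "KE": (1e-2, 1e3),
    "kp": (1e-2, 1e4),
    "factor": (1e-4, 10.0),
}


@dataclass(frozen=True)
class ReducedRates:
    """Composite rates identifiable from unseeded data (kp ≡ 1 convention)."""

    kn_prime: float  # kn·kp
    km_prime: float  # km·kp
    KE: float  # µM

    def __post_init__(self):
        if self.kn_prime < 0 or self.km_prime < 0 or self.KE <= 0:
            raise InvalidInputError("reduced rates must be non-negative, KE > 0")

    def as_parameters(self, nc: int = 2) -> KineticParameters:
        """The kp ≡ 1 representative of the degenerate parameter family."""
        return KineticParameters(kn=self.kn_prime, kp=1.0, km=self.km_prime,
                                 KE=self.KE, nc=nc)

    def to_dict(self) -> dict:
        return {"kn_prime": self.kn_prime, "km_prime": self.km_prime, "KE": self.KE}


@dataclass(frozen=True)
class RateUncertainty:
    """Per-rate spread between independent replicate-set fits."""

    spreads: dict

    def __post_init__(self):
        for k, v in self.spreads.items():
            if v < 0:
                raise InvalidInputError(f"uncertainty for {k} negative")

    def __getitem__(self, key):
        return self.spreads[key]


# ---------------------------------------------------------------------------
# shared machinery


def _group_times(traces: list[MassTrace]) -> np.ndarray:
    union = np.unique(np.concatenate([tr.times for tr in traces]))
    if union[0] > 0:
        union = np.concatenate(([0.0], union))
    return union


def _simulate_on(params, init, union, rtol, atol):
    try:
        traj = simulate(params, init, union, rtol=rtol, atol=atol)
    except (IntegrationError, FloatingPointError):
        return None
    return traj.M


def _residuals_for_groups(groups, params_for_group, settings) -> np.ndarray:
    """Concatenated model-minus-data residuals over condition groups.

    ``groups`` maps an init-condition key to (InitialConditions, traces);
    ``params_for_group`` maps that key to KineticParameters.
    """
    out = []
    for key, (init, traces) in groups.items():
        union = _group_times(traces)
        M = _simulate_on(params_for_group[key], init, union,
                         settings.ode_rtol, settings.ode_atol)
        if M is None:
            return None
        for tr in traces:
            model = np.interp(tr.times, union, M)
            res = model - tr.M
            if settings.weighting == "per_trace":
                res = res / np.sqrt(tr.M.size)
            out.append(res)
    return np.concatenate(out)


def _rmse(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(residuals**2)))


# ---------------------------------------------------------------------------
# results objects


class _KineticResultsBase:
    """Common diagnostics for kinetic fit results."""

    def __init__(self, residuals, n_obs, settings):
        self.residuals = residuals
        self.n_obs = n_obs
        self.settings = settings
        self.rmse = _rmse(residuals)
        self.ssr = float(np.sum(residuals**2))
        self.uncertainty: RateUncertainty | None = None

    def _summary_lines(self, title, rows):
        width = 58
        lines = [title.center(width), "=" * width]
        for name, value, unit in rows:
            err = ""
            if self.uncertainty is not None and name in self.uncertainty.spreads:
                err = f" ± {self.uncertainty[name]:.3g}"
            lines.append(f"{name:<12}{value:>14.6g}{err:<14}{unit}")
        lines += [
            "-" * width,
            f"{'n_obs':<12}{self.n_obs:>14d}",
            f"{'RMSE':<12}{self.rmse:>14.6g}              uM",
            f"{'rng_seed':<12}{self.settings.rng_seed:>14d}",
            f"{'settings':<12}{self.settings.settings_hash():>14}",
        ]
        return "\n".join(lines)


class ReducedRatesResults(_KineticResultsBase):
    """Step-one global fit: composite rates under the kp ≡ 1 convention."""

    def __init__(self, rates: ReducedRates, nc, residuals, n_obs, settings,
                 per_trace_rmse=None):
        super().__init__(residuals, n_obs, settings)
        self.rates = rates
        self.nc = nc
        self.per_trace_rmse = per_trace_rmse or {}

    def rates_dict(self) -> dict:
        return self.rates.to_dict()

    def summary(self) -> str:
        r = self.rates
        rows = [
            ("kn_prime", r.kn_prime, "uM^(1-nc).uM^-1.min^-2 (kn.kp)"),
            ("km_prime", r.km_prime, "uM^-1.min^-2 (km.kp)"),
            ("KE", r.KE, "uM"),
        ]
        return self._summary_lines("Unseeded global kinetic fit (kp == 1)", rows)

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.to_dict(),
            "nc": self.nc,
            "rmse_uM": self.rmse,
            "n_obs": self.n_obs,
            "rng_seed": self.settings.rng_seed,
            "settings_hash": self.settings.settings_hash(),
            "uncertainty": None if self.uncertainty is None else self.uncertainty.spreads,
        }


class AbsoluteRatesResults(_KineticResultsBase):
    """Step-two fit: absolute rates after breaking the kp degeneracy with seeds."""

    def __init__(self, params: KineticParameters, reduced: ReducedRates, L,
                 residuals, n_obs, settings):
        super().__init__(residuals, n_obs, settings)
        self.params = params
        self.reduced = reduced
        self.seed_length = L

    def rates_dict(self) -> dict:
        p = self.params
        return {"kn": p.kn, "kp": p.kp, "km": p.km, "KE": p.KE}

    def summary(self) -> str:
        p = self.params
        rows = [
            ("kn", p.kn, f"uM^{1 - p.nc}.min^-1"),
            ("kp", p.kp, "uM^-1.min^-1"),
            ("km", p.km, "min^-1"),
            ("KE", p.KE, "uM"),
        ]
        return self._summary_lines(
            f"Seeded global kinetic fit (L = {self.seed_length:g} monomers)", rows)

    def to_dict(self) -> dict:
        return {
            "rates": self.rates_dict(),
            "nc": self.params.nc,
            "seed_length_monomers": self.seed_length,
            "rmse_uM": self.rmse,
            "n_obs": self.n_obs,
            "rng_seed": self.settings.rng_seed,
            "settings_hash": self.settings.settings_hash(),
            "uncertainty": None if self.uncertainty is None else self.uncertainty.spreads,
        }


class ChaperoneEffectResults:
    """Per-concentration rate scale factors under one mechanistic hypothesis."""

    def __init__(self, chaperone, hypothesis, factors, rmse_by_conc, n_obs_by_conc,
                 settings, n_free_parameters):
        self.chaperone = chaperone
        #: hypothesis label: 'kn', 'kp', or 'joint'
        self.hypothesis = hypothesis
        #: {conc: {'kn': fn, 'kp': fp, ...}} — absent rates are held at 1
        self.factors = factors
        self.rmse_by_conc = rmse_by_conc
        self.n_obs_by_conc = n_obs_by_conc
        self.settings = settings
        self.n_free_parameters = n_free_parameters

    @property
    def total_rmse(self) -> float:
        num = sum(self.rmse_by_conc[c] ** 2 * self.n_obs_by_conc[c]
                  for c in self.rmse_by_conc)
        den = sum(self.n_obs_by_conc.values())
        return float(np.sqrt(num / den))

    def factor(self, conc: float, rate: str) -> float:
        return self.factors[conc].get(rate, 1.0)

    def summary(self) -> str:
        width = 64
        lines = [
            f"Chaperone effect fit: {self.chaperone} "
            f"(hypothesis: {self.hypothesis})".center(width),
            "=" * width,
            f"{'conc_uM':>8} {'f_kn':>10} {'f_kp':>10} {'f_km':>10} {'RMSE_uM':>10}",
        ]
        for conc in sorted(self.factors):
            f = self.factors[conc]
            lines.append(
                f"{conc:>8.3g} {f.get('kn', 1.0):>10.4g} {f.get('kp', 1.0):>10.4g} "
                f"{f.get('km', 1.0):>10.4g} {self.rmse_by_conc[conc]:>10.4g}"
            )
        lines += ["-" * width, f"total RMSE = {self.total_rmse:.4g} uM, "
                  f"{self.n_free_parameters} free parameter(s) per concentration"]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "chaperone": self.chaperone,
            "hypothesis": self.hypothesis,
            "factors": {str(c): f for c, f in self.factors.items()},
            "rmse_by_conc_uM": {str(c): r for c, r in self.rmse_by_conc.items()},
            "total_rmse_uM": self.total_rmse,
            "rng_seed": self.settings.rng_seed,
        }


# ---------------------------------------------------------------------------
# step one: unseeded global fit


class UnseededGlobalModel:
    """Global fit of unseeded aggregation kinetics at several monomer
    concentrations.

    With no seeds the observable mass curve depends on (kn, kp, km) only
    through the composites kn·kp and km·kp, so kp is fixed at 1 and the fit
    determines ``ReducedRates``.  The amplitude of each trace is never
    fitted: it is fixed by that trace's total monomer concentration.
    """

    def __init__(self, dataset: KineticDataset, nc: int = 2):
        traces = list(dataset.unseeded) if isinstance(dataset, KineticDataset) else list(dataset)
        if any(tr.condition.seeded for tr in traces):
            raise InvalidInputError("unseeded model got seeded traces")
        m0s = np.unique([tr.condition.m0 for tr in traces])
        if m0s.size < 3:
            raise InsufficientDataError(
                f"unseeded global fit is underdetermined with {m0s.size} monomer "
                "concentration(s); need >= 3"
            )
        self.dataset = KineticDataset(traces)
        self.nc = int(nc)
        self._groups = {}
        for key, trs in self.dataset.group_by_condition().items():
            m0 = trs[0].condition.m0
            self._groups[key] = (InitialConditions(m0=m0), trs)
        self.n_obs = sum(tr.M.size for tr in traces)

    def _params_map(self, theta):
        kn_p, km_p, KE = 10.0 ** np.asarray(theta)
        p = KineticParameters(kn=kn_p, kp=1.0, km=km_p, KE=KE, nc=self.nc)
        return {key: p for key in self._groups}

    def _residuals(self, theta, settings):
        res = _residuals_for_groups(self._groups, self._params_map(theta), settings)
        if res is None:
            return np.full(self.n_obs, _PENALTY)
        return res

    def fit(self, settings: FitSettings | None = None) -> ReducedRatesResults:
        settings = settings or FitSettings()
        lb = [settings.log_bounds("kn_prime", _DEFAULT_BOUNDS["kn_prime"]),
              settings.log_bounds("km_prime", _DEFAULT_BOUNDS["km_prime"]),
              settings.log_bounds("KE", _DEFAULT_BOUNDS["KE"])]

        def objective(theta):
            r = self._residuals(theta, settings)
            return float(np.sum(r**2))

        de = differential_evolution(
            objective,
            bounds=lb,
            seed=settings.rng_seed,
            maxiter=settings.max_iterations,
            popsize=settings.popsize,
            tol=settings.tolerance,
            polish=False,
        )
        theta = de.x
        if settings.polish:
            ls = least_squares(
                lambda th: self._residuals(th, settings),
                theta, bounds=tuple(zip(*lb)), xtol=1e-10, ftol=1e-10,
            )
            if np.sum(ls.fun**2) <= de.fun:
                theta = ls.x
        res = self._residuals(theta, settings)
        if not np.all(np.isfinite(res)) or _rmse(res) >= _PENALTY / 2:
            raise FitError(f"unseeded global fit did not converge: {de.message}")
        kn_p, km_p, KE = 10.0 ** theta
        per_trace = {}
        i = 0
        for key, (init, trs) in self._groups.items():
            for tr in trs:
                n = tr.M.size
                per_trace[(key, tr.condition.replicate)] = _rmse(res[i:i + n])
                i += n
        return ReducedRatesResults(
            ReducedRates(kn_p, km_p, KE), self.nc, res, self.n_obs, settings,
            per_trace_rmse=per_trace,
        )


# ---------------------------------------------------------------------------
# step two: seeded fit for kp


class SeededGlobalModel:
    """Break the kp degeneracy with seeded traces.

    Seeds of mass M0 and length L monomers contribute P0 = M0/L fibril ends
    at t = 0; the early seeded growth rate then pins kp directly, while
    kn = k'n/kp and km = k'm/kp are tied so the unseeded composites are
    preserved.
    """

    def __init__(self, dataset: KineticDataset, reduced, L: float = 100.0,
                 nc: int = 2):
        if L <= 0:
            raise InvalidInputError(f"seed length must be positive, got {L}")
        if isinstance(reduced, ReducedRatesResults):
            nc = reduced.nc
            reduced = reduced.rates
        self.reduced = reduced
        self.L = float(L)
        self.nc = int(nc)
        traces = [tr for tr in dataset if tr.condition.seeded]
        if not traces or all(tr.condition.seed_mass == 0 for tr in traces):
            raise InvalidInputError(
                "seeded fit requires traces with seed mass M0 > 0 "
                "(degenerate with the unseeded case otherwise)"
            )
        self.dataset = KineticDataset(traces)
        self._groups = {}
        for key, trs in self.dataset.group_by_condition().items():
            c = trs[0].condition
            self._groups[key] = (
                seeded_initial_conditions(c.seed_mass, self.L, c.m0), trs)
        self.n_obs = sum(tr.M.size for tr in traces)

    def params_at(self, kp: float) -> KineticParameters:
        r = self.reduced
        return KineticParameters(kn=r.kn_prime / kp, kp=kp, km=r.km_prime / kp,
                                 KE=r.KE, nc=self.nc)

    def _residuals(self, log_kp, settings):
        p = self.params_at(10.0 ** float(log_kp))
        res = _residuals_for_groups(self._groups, {k: p for k in self._groups},
                                    settings)
        if res is None:
            return np.full(self.n_obs, _PENALTY)
        return res

    def fit(self, settings: FitSettings | None = None) -> AbsoluteRatesResults:
        settings = settings or FitSettings()
        lo, hi = settings.log_bounds("kp", _DEFAULT_BOUNDS["kp"])
        theta = _scan_refine(
            lambda x: float(np.sum(self._residuals(x, settings) ** 2)),
            lo, hi, settings.grid_points,
        )
        res = self._residuals(theta, settings)
        kp = 10.0 ** theta
        return AbsoluteRatesResults(self.params_at(kp), self.reduced, self.L,
                                    res, self.n_obs, settings)


def _scan_refine(objective, lo, hi, n_grid):
    """Deterministic 1-D minimization: coarse log-grid scan + bounded refine."""
    grid = np.linspace(lo, hi, n_grid)
    vals = [objective(x) for x in grid]
    i = int(np.argmin(vals))
    a = grid[max(0, i - 1)]
    b = grid[min(n_grid - 1, i + 1)]
    if a == b:
        return grid[i]
    out = minimize_scalar(objective, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-7})
    return float(out.x) if out.fun <= vals[i] else float(grid[i])


# ---------------------------------------------------------------------------
# chaperone mechanism fits


class ChaperoneRateModel:
    """Fit per-concentration rate scale factors for one chaperone.

    ``hypothesis`` selects which microscopic rates the chaperone is allowed
    to perturb:

    - ``'kn'`` or ``'kp'`` — a single rate varies, all others fixed at the
      chaperone-free baseline (one-parameter scan per concentration);
    - ``'joint'`` — kn and kp (and km when seeded traces are present) vary
      simultaneously on combined unseeded + seeded data.

    Each chaperone concentration is fitted independently.
    """

    _JOINT_RATES = ("kn", "kp", "km")

    def __init__(self, dataset: KineticDataset, baseline: KineticParameters,
                 hypothesis: str, L: float = 100.0):
        if hypothesis not in ("kn", "kp", "joint"):
            raise InvalidInputError(f"unknown hypothesis {hypothesis!r}")
        traces = list(dataset)
        if not traces:
            raise InvalidInputError("empty dataset")
        # chaperone-free wells (conc 0) may carry no chaperone label
        names = {tr.condition.chaperone for tr in traces
                 if tr.condition.chaperone_conc > 0}
        if len(names) > 1:
            raise InvalidInputError(f"dataset mixes chaperones: {sorted(map(str, names))}")
        self.chaperone = (next(iter(names)) or "none") if names else "none"
        self.baseline = baseline
        self.hypothesis = hypothesis
        self.L = float(L)
        self.dataset = KineticDataset(traces)
        self._by_conc: dict[float, dict] = {}
        for key, trs in self.dataset.group_by_condition().items():
            c = trs[0].condition
            init = (seeded_initial_conditions(c.seed_mass, self.L, c.m0)
                    if c.seeded else InitialConditions(m0=c.m0))
            self._by_conc.setdefault(c.chaperone_conc, {})[key] = (init, trs)
        self._has_seeded = any(tr.condition.seeded for tr in traces)

    def _n_obs(self, groups):
        return sum(tr.M.size for _, trs in groups.values() for tr in trs)

    def _residuals(self, factors: dict, groups, settings):
        p = self.baseline.scaled(fn=factors.get("kn", 1.0),
                                 fp=factors.get("kp", 1.0),
                                 fm=factors.get("km", 1.0))
        res = _residuals_for_groups(groups, {k: p for k in groups}, settings)
        if res is None:
            return np.full(self._n_obs(groups), _PENALTY)
        return res

    def _fit_single(self, groups, settings):
        lo, hi = settings.log_bounds("factor", _DEFAULT_BOUNDS["factor"])
        rate = self.hypothesis

        def objective(x):
            return float(np.sum(
                self._residuals({rate: 10.0 ** float(x)}, groups, settings) ** 2))

        theta = _scan_refine(objective, lo, hi, settings.grid_points)
        f = 10.0 ** theta
        res = self._residuals({rate: f}, groups, settings)
        return {rate: f}, res

    def _fit_joint(self, groups, settings, rates):
        lo, hi = settings.log_bounds("factor", _DEFAULT_BOUNDS["factor"])
        bounds = [(lo, hi)] * len(rates)

        def theta_to_factors(theta):
            return {r: 10.0 ** float(x) for r, x in zip(rates, theta)}

        def objective(theta):
            return float(np.sum(
                self._residuals(theta_to_factors(theta), groups, settings) ** 2))

        de = differential_evolution(
            objective, bounds=bounds, seed=settings.rng_seed,
            maxiter=settings.max_iterations, popsize=settings.popsize,
            tol=settings.tolerance, polish=False,
        )
        theta = de.x
        if settings.polish:
            ls = least_squares(
                lambda th: self._residuals(theta_to_factors(th), groups, settings),
                theta, bounds=tuple(zip(*bounds)), xtol=1e-10, ftol=1e-10,
            )
            if np.sum(ls.fun**2) <= de.fun:
                theta = ls.x
        factors = theta_to_factors(theta)
        return factors, self._residuals(factors, groups, settings)

    def fit(self, settings: FitSettings | None = None) -> ChaperoneEffectResults:
        settings = settings or FitSettings()
        if self.hypothesis == "joint":
            rates = self._JOINT_RATES if self._has_seeded else ("kn", "kp")
            if not self._has_seeded:
                warnings.warn(
                    "joint fit without seeded traces: km is unidentifiable and "
                    "held at 1; (kn, kp) factors may trade off", stacklevel=2)
        else:
            rates = (self.hypothesis,)
        factors_by_conc, rmse_by_conc, nobs_by_conc = {}, {}, {}
        for conc in sorted(self._by_conc):
            groups = self._by_conc[conc]
            if self.hypothesis == "joint":
                factors, res = self._fit_joint(groups, settings, rates)
            else:
                factors, res = self._fit_single(groups, settings)
            factors_by_conc[conc] = factors
            rmse_by_conc[conc] = _rmse(res)
            nobs_by_conc[conc] = self._n_obs(groups)
        return ChaperoneEffectResults(
            self.chaperone, self.hypothesis, factors_by_conc, rmse_by_conc,
            nobs_by_conc, settings, n_free_parameters=len(rates),
        )


# ---------------------------------------------------------------------------
# hypothesis comparison and uncertainties


@dataclass(frozen=True)
class HypothesisComparison:
    """RMSE-ranked comparison of mechanistic hypotheses."""

    ranking: tuple  # hypothesis labels, best first
    total_rmse: dict
    rmse_ratio_to_best: dict
    rmse_by_conc: dict
    tie: bool

    def summary(self) -> str:
        lines = ["Hypothesis ranking (total RMSE, ratio to best)", "-" * 48]
        for h in self.ranking:
            lines.append(f"{h:<10}{self.total_rmse[h]:>12.5g}"
                         f"{self.rmse_ratio_to_best[h]:>10.3f}")
        if self.tie:
            lines.append("note: tie on RMSE broken by parameter count")
        return "\n".join(lines)


def compare_rate_hypotheses(effects) -> HypothesisComparison:
    """Rank single-rate / joint hypotheses by total residual on shared traces."""
    effects = list(effects)
    if len(effects) < 2:
        raise InvalidInputError("need >= 2 hypotheses to compare")
    conc_sets = [tuple(sorted(e.rmse_by_conc)) for e in effects]
    if len(set(conc_sets)) != 1:
        raise InvalidInputError("hypotheses were fitted on different trace sets")
    nobs = [tuple(sorted(e.n_obs_by_conc.items())) for e in effects]
    if len(set(nobs)) != 1:
        raise InvalidInputError("hypotheses were fitted on different trace sets")
    totals = {e.hypothesis: e.total_rmse for e in effects}
    # parsimony tie-break: fewer free parameters wins at (numerically) equal RMSE
    order = sorted(effects, key=lambda e: (round(e.total_rmse, 12),
                                           e.n_free_parameters))
    best = order[0].total_rmse
    tie = len({round(e.total_rmse, 12) for e in effects}) < len(effects)
    return HypothesisComparison(
        ranking=tuple(e.hypothesis for e in order),
        total_rmse=totals,
        rmse_ratio_to_best={h: (v / best if best > 0 else 1.0)
                            for h, v in totals.items()},
        rmse_by_conc={e.hypothesis: dict(e.rmse_by_conc) for e in effects},
        tie=tie,
    )


def estimate_rate_errors(dataset: KineticDataset, fit_procedure) -> RateUncertainty:
    """Rate uncertainties from independent replicate-set fits.

    ``fit_procedure`` maps a KineticDataset to a results object exposing
    ``rates_dict()``.  With exactly two sets the uncertainty is half the
    absolute difference; with more it is the standard deviation across sets.
    """
    subsets = dataset.split_replicate_sets()
    if len(subsets) < 2:
        raise InsufficientDataError("need >= 2 replicate sets for error estimation")
    fits = [fit_procedure(sub) for sub in subsets]
    names = fits[0].rates_dict().keys()
    spreads = {}
    for name in names:
        vals = np.array([f.rates_dict()[name] for f in fits])
        if len(vals) == 2:
            spreads[name] = float(abs(vals[1] - vals[0]) / 2.0)
        else:
            spreads[name] = float(np.std(vals, ddof=1))
    return RateUncertainty(spreads)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_unseeded_global(dataset, nc: int = 2, settings=None) -> ReducedRatesResults:
    return UnseededGlobalModel(dataset, nc=nc).fit(settings)


def fit_seeded_global(dataset, reduced, L: float = 100.0, settings=None,
                      nc: int = 2) -> AbsoluteRatesResults:
    return SeededGlobalModel(dataset, reduced, L=L, nc=nc).fit(settings)


def fit_chaperone_single_rate(dataset, baseline, which_rate: str,
                              settings=None, L: float = 100.0) -> ChaperoneEffectResults:
    return ChaperoneRateModel(dataset, baseline, which_rate, L=L).fit(settings)


def fit_chaperone_joint(dataset, baseline, settings=None,
                        L: float = 100.0) -> ChaperoneEffectResults:
    return ChaperoneRateModel(dataset, baseline, "joint", L=L).fit(settings)
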