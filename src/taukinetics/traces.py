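"""Preprocessing of ThT plate-reader traces and half-time / scaling analysis.

Raw fluorescence time courses are baseline-subtracted, optionally binned,
and converted to fibril mass concentration by anchoring the long-term
plateau of the highest-monomer trace to that monomer concentration::

    M_i(t) = m_max · S_i(t) / S_max∞

Half-saturation times t½ are the first crossing of half the per-trace
plateau, and the scaling exponent γ is the slope of log10(t½) against
log10(m0), with a quadratic term diagnosing curvature (a signature of
saturating elongation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Condition, KineticDataset, MassTrace, RawTrace
from .exceptions import (
    AlignmentError,
    InsufficientDataError,
    InvalidInputError,
    NotSaturatedError,
)

__all__ = [
    "ConversionSpec",
    "HalfTimeResult",
    "ScalingResult",
    "subtract_baseline",
    "bin_trace",
    "signal_to_mass",
    "extract_half_time",
    "fit_scaling_exponent",
    "read_trace_csv",
    "write_trace_csv",
]


@dataclass(frozen=True)
class ConversionSpec:
    """Signal-to-mass conversion anchors.

    ``Smax_inf`` is the long-term ThT plateau of the trace with the highest
    monomer concentration ``mmax``; ``plateau_fraction`` is the share of
    trailing points averaged to estimate plateaus.
    """

    mmax: float  # µM
    Smax_inf: float  # a.u.
    plateau_fraction: float = 0.1

    def __post_init__(self):
        if self.mmax <= 0:
            raise InvalidInputError(f"mmax must be positive, got {self.mmax}")
        if self.Smax_inf <= 0:
            raise InvalidInputError(f"Smax_inf must be positive, got {self.Smax_inf}")
        if not 0 < self.plateau_fraction <= 0.5:
            raise InvalidInputError("plateau_fraction must be in (0, 0.5]")

    @classmethod
    def from_traces(cls, traces, plateau_fraction: float = 0.1) -> "ConversionSpec":
        """Estimate the spec from a trace collection.

        The anchor plateau is the mean of the final ``plateau_fraction`` of
        points of the trace with the highest m0.
        """
        traces = list(traces)
        if not traces:
            raise InvalidInputError("no traces supplied")
        top = max(traces, key=lambda tr: tr.condition.m0)
        n_tail = max(1, int(round(plateau_fraction * top.values.size)))
        smax = float(np.mean(top.values[-n_tail:]))
        return cls(mmax=top.condition.m0, Smax_inf=smax,
                   plateau_fraction=plateau_fraction)


@dataclass(frozen=True)
class HalfTimeResult:
    """Half-saturation time of a single trace."""

    t_half: float  # min
    plateau: float  # µM
    crossing_index: int  # index of the first point at/above plateau/2


@dataclass(frozen=True)
class ScalingResult:
    """Double-logarithmic half-time concentration scaling."""

    gamma: float
    gamma_stderr: float
    curvature_coeff: float
    curvature_stderr: float
    curvature_significant: bool


def subtract_baseline(trace: RawTrace, baseline: RawTrace) -> RawTrace:
    """Subtract a no-trigger baseline trace (interpolated onto the trace grid)."""
    t, s = trace.times, trace.signal
    bt, bs = baseline.times, baseline.signal
    if bt[0] > t[0] + 1e-9 or bt[-1] < t[-1] - 1e-9:
        raise AlignmentError(
            f"baseline range [{bt[0]}, {bt[-1]}] does not cover trace "
            f"range [{t[0]}, {t[-1]}]"
        )
    if bt.shape == t.shape and np.allclose(bt, t):
        corr = s - bs
    else:
        corr = s - np.interp(t, bt, bs)
    return trace.with_signal(corr)


def bin_trace(trace, bin_size: int):
    """Smooth a trace by averaging consecutive non-overlapping windows.

    Both times and values are replaced by window arithmetic means; a trailing
    partial window is averaged as-is.  ``bin_size`` must be 1–5.
    """
    if not (1 <= int(bin_size) == bin_size <= 5):
        raise InvalidInputError(f"bin_size must be an integer in 1..5, got {bin_size}")
    bin_size = int(bin_size)
    if bin_size == 1:
        return trace
    t, v = trace.times, trace.values
    n = t.size
    edges = np.arange(0, n, bin_size)
    tb = np.array([t[i:i + bin_size].mean() for i in edges])
    vb = np.array([v[i:i + bin_size].mean() for i in edges])
    if isinstance(trace, MassTrace):
        return MassTrace(tb, vb, trace.condition)
    return RawTrace(tb, vb, trace.condition)


def signal_to_mass(traces, spec: ConversionSpec) -> list[MassTrace]:
    """Convert ThT signals to fibril mass: M_i(t) = mmax·S_i(t)/Smax∞."""
    if spec.Smax_inf <= 0:
        raise InvalidInputError("Smax_inf must be positive")
    out = []
    for tr in traces:
        M = spec.mmax * tr.signal / spec.Smax_inf
        out.append(MassTrace(tr.times.copy(), M, tr.condition))
    return out


def extract_half_time(
    trace: MassTrace,
    plateau_fraction: float = 0.1,
    slope_tolerance: float = 0.01,
) -> HalfTimeResult:
    """Extract the half-saturation time of a mass trace.

    The plateau is the mean of the final ``plateau_fraction`` of points; the
    trace is rejected (``NotSaturatedError``) when the mean slope over that
    final window exceeds ``slope_tolerance`` times the peak rate, i.e. the
    trace is still rising.  t½ is the linearly interpolated first crossing
    of plateau/2.
    """
    t, M = trace.times, trace.M
    n_tail = max(2, int(round(plateau_fraction * t.size)))
    plateau = float(np.mean(M[-n_tail:]))
    if plateau <= 0:
        raise NotSaturatedError("trace has non-positive plateau (no aggregation)")
    rates = np.gradient(M, t)
    peak_rate = float(np.max(np.abs(rates)))
    # regression slope over the tail window is far less noise-sensitive
    # than averaging point-wise gradients; a rejection additionally requires
    # the slope to be statistically positive (> 3 SE) so that pure noise
    # cannot disqualify a genuinely flat plateau
    if n_tail >= 4:
        coef, cov = np.polyfit(t[-n_tail:], M[-n_tail:], 1, cov=True)
        tail_rate, tail_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    else:
        tail_rate = float(np.polyfit(t[-n_tail:], M[-n_tail:], 1)[0])
        tail_se = 0.0
    if (peak_rate > 0 and tail_rate > slope_tolerance * peak_rate
            and tail_rate > 3.0 * tail_se):
        raise NotSaturatedError(
            f"final-window slope {tail_rate:.3g} exceeds {slope_tolerance:.0%} "
            f"of peak rate {peak_rate:.3g}; trace not saturated"
        )
    half = plateau / 2.0
    above = np.nonzero(M >= half)[0]
    if above.size == 0:
        raise NotSaturatedError("trace never reaches half its plateau")
    i = int(above[0])
    if i == 0:
        t_half = float(t[0])
    else:
        # linear interpolation between the bracketing samples
        t_half = float(
            t[i - 1] + (half - M[i - 1]) * (t[i] - t[i - 1]) / (M[i] - M[i - 1])
        )
    return HalfTimeResult(t_half=t_half, plateau=plateau, crossing_index=i)


def fit_scaling_exponent(half_times) -> ScalingResult:
    """Fit the double-logarithmic half-time scaling exponent γ.

    Parameters
    ----------
    half_times : sequence of (m0, t_half)
        Initial monomer concentrations (µM) and half-times (min).

    Returns
    -------
    ScalingResult
        γ is the OLS slope of log10(t½) vs log10(m0); the curvature
        coefficient comes from a second-degree fit and is flagged
        significant when it exceeds twice its standard error.
    """
    pairs = [(float(m), float(th)) for m, th in half_times]
    m0 = np.array([p[0] for p in pairs])
    th = np.array([p[1] for p in pairs])
    if np.unique(m0).size < 3:
        raise InsufficientDataError("need >= 3 distinct monomer concentrations")
    if np.any(m0 <= 0) or np.any(th <= 0):
        raise InvalidInputError("concentrations and half-times must be positive")
    x, y = np.log10(m0), np.log10(th)

    # linear fit for gamma
    coeffs, cov = np.polyfit(x, y, 1, cov=True)
    gamma = float(coeffs[0])
    gamma_se = float(np.sqrt(cov[0, 0]))

    # quadratic fit for curvature
    if np.unique(m0).size >= 4:
        qc, qcov = np.polyfit(x, y, 2, cov=True)
        curv, curv_se = float(qc[0]), float(np.sqrt(qcov[0, 0]))
    else:
        qc = np.polyfit(x, y, 2)
        curv, curv_se = float(qc[0]), np.inf
    # the 1e-8 floor guards against flagging pure floating-point curvature
    significant = bool(np.isfinite(curv_se) and abs(curv) > 2 * curv_se
                       and abs(curv) > 1e-8)
    return ScalingResult(
        gamma=gamma,
        gamma_stderr=gamma_se,
        curvature_coeff=curv,
        curvature_stderr=curv_se,
        curvature_significant=significant,
    )


# ---------------------------------------------------------------------------
# tabular IO (long format)

_COLUMNS = [
    "time_min", "signal_au", "well", "m0_uM", "chaperone", "chaperone_uM",
    "seeded", "seed_mass_uM", "replicate",
]


def _condition_from_row(row) -> Condition:
    chap = row["chaperone"]
    if pd.isna(chap) or str(chap).lower() in ("none", ""):
        chap = None
    return Condition(
        m0=float(row["m0_uM"]),
        chaperone=chap,
        chaperone_conc=float(row["chaperone_uM"]),
        seeded=bool(row["seeded"]),
        seed_mass=float(row["seed_mass_uM"]),
        replicate=int(row["replicate"]),
    )


def read_trace_csv(path, kind: str = "raw"):
    """Read a long-format plate CSV into traces.

    ``kind='raw'`` expects a ``signal_au`` column and yields RawTrace;
    ``kind='mass'`` expects ``M_uM`` and yields MassTrace.
    """
    df = pd.read_csv(path)
    value_col = "signal_au" if kind == "raw" else "M_uM"
    if value_col not in df.columns:
        raise InvalidInputError(f"column {value_col!r} missing from {path}")
    out = []
    for _, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        cond = _condition_from_row(grp.iloc[0])
        t = grp["time_min"].to_numpy(float)
        v = grp[value_col].to_numpy(float)
        if kind == "raw":
            out.append(RawTrace(t, v, cond))
        else:
            out.append(MassTrace(t, v, cond))
    return out


def write_trace_csv(traces, path, kind: str = "raw") -> None:
    """Write traces to a long-format plate CSV (inverse of read_trace_csv)."""
    rows = []
    value_col = "signal_au" if kind == "raw" else "M_uM"
    for i, tr in enumerate(traces):
        c = tr.condition
        for t, v in zip(tr.times, tr.values):
            rows.append({
                "time_min": t,
                value_col: v,
                "well": f"W{i:03d}",
                "m0_uM": c.m0,
                "chaperone": c.chaperone or "none",
                "chaperone_uM": c.chaperone_conc,
                "seeded": c.seeded,
                "seed_mass_uM": c.seed_mass,
                "replicate": c.replicate,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def dataset_from_csv(path, kind: str = "mass") -> KineticDataset:
    return KineticDataset(list(read_trace_csv(path, kind=kind)))


def half_times_to_json(results: dict, path) -> None:
    """Serialize a {label: HalfTimeResult} mapping to JSON."""
    payload = {
        str(k): {"t_half_min": r.t_half, "plateau_uM": r.plateau}
        for k, r in results.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
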