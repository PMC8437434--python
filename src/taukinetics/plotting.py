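"""Quick-look plots for kinetic traces and fit diagnostics."""

from __future__ import annotations

import numpy as np


def plot_mass_traces(dataset, model_curves=None, ax=None):
    """Overlay mass traces (points) with optional model curves (lines).

    ``model_curves`` maps a condition key (see ``Condition.key``) to a
    (times, M) pair.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tr in dataset:
        label = f"m0={tr.condition.m0:g} uM"
        if tr.condition.chaperone_conc:
            label += f", {tr.condition.chaperone} {tr.condition.chaperone_conc:g} uM"
        ax.plot(tr.times, tr.values, ".", ms=3, alpha=0.6, label=label)
        if model_curves and tr.condition.key() in model_curves:
            t, M = model_curves[tr.condition.key()]
            ax.plot(t, M, "-", lw=1.2, color="k")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("fibril mass (uM)")
    return ax


def plot_half_time_scaling(half_times, scaling=None, ax=None):
    """Double-logarithmic half-time vs monomer concentration plot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m0 = np.array([m for m, _ in half_times])
    th = np.array([t for _, t in half_times])
    ax.loglog(m0, th, "o")
    if scaling is not None:
        grid = np.geomspace(m0.min(), m0.max(), 50)
        anchor = np.log10(th[np.argmin(m0)]) - scaling.gamma * np.log10(m0.min())
        ax.loglog(grid, 10 ** (anchor + scaling.gamma * np.log10(grid)), "-",
                  label=f"gamma = {scaling.gamma:.2f}")
        ax.legend()
    ax.set_xlabel("initial monomer (uM)")
    ax.set_ylabel("half-time (min)")
    return ax


def plot_rate_factors(effect, ax=None):
    """Chaperone-concentration dependence of the fitted rate scale factors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    concs = sorted(effect.factors)
    for rate in ("kn", "kp", "km"):
        vals = [effect.factors[c].get(rate) for c in concs]
        if any(v is not None for v in vals):
            ax.semilogy(concs, [v if v is not None else 1.0 for v in vals],
                        "o-", label=f"f_{rate}")
    ax.set_xlabel(f"{effect.chaperone} (uM)")
    ax.set_ylabel("rate scale factor")
    ax.legend()
    return ax
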