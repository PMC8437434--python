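"""Shared fixtures.

The expensive global fits are session-scoped so that unit tests and the
acceptance suite measure the same computations instead of re-running them.
All synthetic data use fixed seeds; every fit records its rng seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from taukinetics.fitting import (
    ChaperoneRateModel,
    FitSettings,
    SeededGlobalModel,
    UnseededGlobalModel,
)
from taukinetics.synthetic import (
    DEFAULT_BASELINE,
    NoiseSpec,
    ScenarioSpec,
    generate_aggregation_dataset,
)

SEED = 20260928


@pytest.fixture(scope="session")
def fit_settings():
    return FitSettings(rng_seed=3, max_iterations=40, popsize=10, grid_points=21)


@pytest.fixture(scope="session")
def baseline_dataset():
    """Five-concentration unseeded + seeded design, 1% noise, 3 replicates."""
    spec = ScenarioSpec(seed_spec=(1.0, 100.0))
    return generate_aggregation_dataset(
        spec, NoiseSpec(sigma=0.01, kind="relative", rng_seed=SEED % 2**31))


@pytest.fixture(scope="session")
def reduced_fit(baseline_dataset, fit_settings):
    dataset, _ = baseline_dataset
    return UnseededGlobalModel(dataset.unseeded).fit(fit_settings)


@pytest.fixture(scope="session")
def absolute_fit(baseline_dataset, reduced_fit, fit_settings):
    dataset, _ = baseline_dataset
    return SeededGlobalModel(dataset, reduced_fit, L=100.0).fit(fit_settings)


@pytest.fixture(scope="session")
def kp_suppressed():
    """10 µM tau with an elongation-suppressing chaperone (kp × 0.1)."""
    spec = ScenarioSpec(
        m0_series=(10.0,), chaperone="HSPB1",
        chaperone_effects={0.0: (1, 1, 1), 10.0: (1.0, 0.1, 1.0)},
    )
    return generate_aggregation_dataset(
        spec, NoiseSpec(sigma=0.01, kind="relative", rng_seed=(SEED + 1) % 2**31))


@pytest.fixture(scope="session")
def kn_suppressed():
    """10 µM tau with a nucleation-suppressing chaperone (kn × 0.03)."""
    spec = ScenarioSpec(
        m0_series=(10.0,), chaperone="DNAJB1",
        chaperone_effects={0.0: (1, 1, 1), 10.0: (0.03, 1.0, 1.0)},
    )
    return generate_aggregation_dataset(
        spec, NoiseSpec(sigma=0.01, kind="relative", rng_seed=(SEED + 2) % 2**31))


@pytest.fixture(scope="session")
def joint_suppressed():
    """10 µM tau, both nucleation and elongation suppressed, with seeds."""
    spec = ScenarioSpec(
        m0_series=(10.0,), chaperone="DNAJA2", seed_spec=(1.0, 100.0),
        chaperone_effects={0.0: (1, 1, 1), 5.0: (0.2, 0.3, 1.0)},
    )
    return generate_aggregation_dataset(
        spec, NoiseSpec(sigma=0.01, kind="relative", rng_seed=(SEED + 3) % 2**31))


@pytest.fixture(scope="session")
def mechanism_fits(kp_suppressed, kn_suppressed, fit_settings):
    """Single-rate hypothesis fits on both suppression datasets."""
    kp_ds, _ = kp_suppressed
    kn_ds, _ = kn_suppressed
    out = {}
    for label, ds in (("kp_data", kp_ds), ("kn_data", kn_ds)):
        out[label] = {
            hyp: ChaperoneRateModel(ds, DEFAULT_BASELINE, hyp).fit(fit_settings)
            for hyp in ("kn", "kp")
        }
    return out


@pytest.fixture(scope="session")
def joint_fit(joint_suppressed, fit_settings):
    ds, _ = joint_suppressed
    return ChaperoneRateModel(ds, DEFAULT_BASELINE, "joint").fit(fit_settings)
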