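"""Global fitting: two-step rate estimation, chaperone effects, uncertainties."""

import numpy as np
import pytest

from taukinetics.datasets import KineticDataset
from taukinetics.exceptions import InsufficientDataError, InvalidInputError
from taukinetics.fitting import (
    ChaperoneEffectResults,
    ChaperoneRateModel,
    FitSettings,
    ReducedRates,
    SeededGlobalModel,
    UnseededGlobalModel,
    compare_rate_hypotheses,
    estimate_rate_errors,
)
from taukinetics.kinetics import KineticParameters, simulate
from taukinetics.synthetic import (
    DEFAULT_BASELINE,
    NoiseSpec,
    ScenarioSpec,
    generate_aggregation_dataset,
)

FAST = FitSettings(rng_seed=5, max_iterations=25, popsize=8, grid_points=15)


def _small_dataset(baseline, m0_series=(2.5, 10.0, 40.0), sigma=0.0, seed=1,
                   dt=2.0, duration=500.0, replicates=1):
    spec = ScenarioSpec(baseline=baseline, m0_series=m0_series, dt=dt,
                        duration=duration, replicates=replicates)
    return generate_aggregation_dataset(
        spec, NoiseSpec(sigma=sigma, kind="relative", rng_seed=seed))


class TestUnseededGlobal:
    def test_noise_free_recovery(self):
        """Composite rates come back within 5% from noise-free data."""
        truth = KineticParameters(kn=5e-4, kp=1.0, km=1e-4, KE=5.0)
        ds, _ = _small_dataset(truth, m0_series=(2.5, 5.0, 10.0, 20.0, 40.0),
                               dt=0.25, duration=60.0)
        res = UnseededGlobalModel(ds).fit(FAST)
        assert res.rates.kn_prime == pytest.approx(5e-4, rel=0.05)
        assert res.rates.km_prime == pytest.approx(1e-4, rel=0.05)
        assert res.rates.KE == pytest.approx(5.0, rel=0.05)

    def test_null_fragmentation_recovered_as_negligible(self):
        truth = KineticParameters(kn=5e-4, kp=1.0, km=0.0, KE=5.0)
        ds, _ = _small_dataset(truth, dt=0.25, duration=60.0)
        res = UnseededGlobalModel(ds).fit(FAST)
        # recovered fragmentation contributes < 1% of nucleation flux at 10 uM
        assert res.rates.km_prime * 10.0 < 0.01 * res.rates.kn_prime * 10.0**2

    def test_degenerate_parameterizations_fit_identically(self):
        """Datasets related by (c*kn, kp/c, c*km) give the same reduced rates."""
        base = DEFAULT_BASELINE
        c = 10.0
        alt = KineticParameters(base.kn * c, base.kp / c, base.km * c, base.KE)
        ds1, _ = _small_dataset(base, dt=4.0)
        ds2, _ = _small_dataset(alt, dt=4.0)
        r1 = UnseededGlobalModel(ds1).fit(FAST).rates
        r2 = UnseededGlobalModel(ds2).fit(FAST).rates
        assert r1.kn_prime == pytest.approx(r2.kn_prime, rel=1e-3)
        assert r1.km_prime == pytest.approx(r2.km_prime, rel=1e-3)
        assert r1.KE == pytest.approx(r2.KE, rel=1e-3)

    def test_single_concentration_refused(self):
        ds, _ = _small_dataset(DEFAULT_BASELINE, m0_series=(10.0,), dt=4.0)
        with pytest.raises(InsufficientDataError):
            UnseededGlobalModel(ds)

    def test_bit_reproducible(self):
        ds, _ = _small_dataset(DEFAULT_BASELINE, sigma=0.01, seed=4, dt=4.0)
        tiny = FitSettings(rng_seed=9, max_iterations=8, popsize=6, grid_points=11)
        r1 = UnseededGlobalModel(ds).fit(tiny).rates
        r2 = UnseededGlobalModel(ds).fit(tiny).rates
        assert (r1.kn_prime, r1.km_prime, r1.KE) == (r2.kn_prime, r2.km_prime, r2.KE)


class TestSeededGlobal:
    def test_kp_recovery(self, baseline_dataset, reduced_fit, absolute_fit):
        _, truth = baseline_dataset
        assert absolute_fit.params.kp == pytest.approx(truth["baseline"]["kp"],
                                                       rel=0.10)

    def test_composites_preserved(self, reduced_fit, absolute_fit):
        p = absolute_fit.params
        assert p.kn * p.kp == pytest.approx(reduced_fit.rates.kn_prime, rel=1e-9)
        assert p.km * p.kp == pytest.approx(reduced_fit.rates.km_prime, rel=1e-9)

    def test_seed_length_tradeoff(self, baseline_dataset, reduced_fit,
                                  fit_settings):
        """Doubling L halves P0; recovered kp compensates so kp*P0 is stable."""
        dataset, _ = baseline_dataset
        products = []
        for L in (100.0, 200.0):
            res = SeededGlobalModel(dataset, reduced_fit, L=L).fit(fit_settings)
            products.append(res.params.kp / L)
        assert products[1] == pytest.approx(products[0], rel=0.15)

    def test_unseeded_only_refused(self, baseline_dataset, reduced_fit):
        dataset, _ = baseline_dataset
        with pytest.raises(InvalidInputError):
            SeededGlobalModel(dataset.unseeded, reduced_fit, L=100.0)

    def test_invalid_seed_length_refused(self, baseline_dataset, reduced_fit):
        dataset, _ = baseline_dataset
        with pytest.raises(InvalidInputError):
            SeededGlobalModel(dataset, reduced_fit, L=0.0)

    def test_amplitude_constraint_on_fitted_curves(self, baseline_dataset,
                                                   absolute_fit):
        """Model curves start at M0 and stay below the total monomer pool."""
        dataset, _ = baseline_dataset
        tr = next(iter(dataset.seeded))
        c = tr.condition
        from taukinetics.kinetics import seeded_initial_conditions

        init = seeded_initial_conditions(c.seed_mass, 100.0, c.m0)
        traj = simulate(absolute_fit.params, init, tr.times)
        assert traj.M[0] == pytest.approx(c.seed_mass)
        assert np.all(traj.M <= c.total_mass * (1 + 1e-9))


class TestChaperoneEffects:
    def test_zero_chaperone_scale_factor_is_unity(self, mechanism_fits):
        for fits in mechanism_fits.values():
            for hyp, res in fits.items():
                assert res.factor(0.0, hyp) == pytest.approx(1.0, rel=0.02)

    def test_elongation_suppression_recovered(self, mechanism_fits):
        res = mechanism_fits["kp_data"]["kp"]
        assert res.factor(10.0, "kp") == pytest.approx(0.1, rel=0.10)

    def test_nucleation_suppression_recovered(self, mechanism_fits):
        res = mechanism_fits["kn_data"]["kn"]
        assert res.factor(10.0, "kn") == pytest.approx(0.03, rel=0.25)

    def test_correct_hypothesis_has_smaller_residual(self, mechanism_fits):
        kp_fits = mechanism_fits["kp_data"]
        assert kp_fits["kp"].rmse_by_conc[10.0] <= 0.5 * kp_fits["kn"].rmse_by_conc[10.0]
        kn_fits = mechanism_fits["kn_data"]
        assert kn_fits["kn"].rmse_by_conc[10.0] <= 0.5 * kn_fits["kp"].rmse_by_conc[10.0]

    def test_joint_fit_recovers_simultaneous_suppression(self, joint_suppressed,
                                                         joint_fit):
        _, truth = joint_suppressed
        assert joint_fit.factor(5.0, "kn") == pytest.approx(0.2, rel=0.20)
        assert joint_fit.factor(5.0, "kp") == pytest.approx(0.3, rel=0.20)
        assert joint_fit.factor(0.0, "kn") == pytest.approx(1.0, rel=0.10)
        assert joint_fit.factor(0.0, "kp") == pytest.approx(1.0, rel=0.10)

    def test_joint_without_seeds_warns(self, kp_suppressed):
        ds, _ = kp_suppressed
        tiny = FitSettings(rng_seed=2, max_iterations=5, popsize=6, grid_points=9)
        model = ChaperoneRateModel(ds, DEFAULT_BASELINE, "joint")
        with pytest.warns(UserWarning, match="unidentifiable"):
            model.fit(tiny)

    def test_unknown_hypothesis_rejected(self, kp_suppressed):
        ds, _ = kp_suppressed
        with pytest.raises(InvalidInputError):
            ChaperoneRateModel(ds, DEFAULT_BASELINE, "KE")


def _stub_effect(hypothesis, rmse, n_free=1):
    return ChaperoneEffectResults(
        chaperone="X", hypothesis=hypothesis,
        factors={0.0: {hypothesis if hypothesis != "joint" else "kn": 1.0}},
        rmse_by_conc={0.0: rmse}, n_obs_by_conc={0.0: 100},
        settings=FAST, n_free_parameters=n_free,
    )


class TestCompareHypotheses:
    def test_tie_reported(self):
        cmp = compare_rate_hypotheses([_stub_effect("kn", 0.2),
                                       _stub_effect("kp", 0.2)])
        assert cmp.tie
        assert cmp.rmse_ratio_to_best["kp"] == pytest.approx(1.0)

    def test_ratio_and_ranking(self):
        cmp = compare_rate_hypotheses([_stub_effect("kn", 0.4),
                                       _stub_effect("kp", 0.1)])
        assert cmp.ranking == ("kp", "kn")
        assert cmp.rmse_ratio_to_best["kn"] == pytest.approx(4.0)

    def test_parsimony_tie_break(self):
        cmp = compare_rate_hypotheses([_stub_effect("joint", 0.1, n_free=3),
                                       _stub_effect("kp", 0.1, n_free=1)])
        assert cmp.ranking[0] == "kp"

    def test_mismatched_trace_sets_rejected(self):
        a = _stub_effect("kn", 0.1)
        b = ChaperoneEffectResults("X", "kp", {1.0: {"kp": 1.0}}, {1.0: 0.1},
                                   {1.0: 100}, FAST, 1)
        with pytest.raises(InvalidInputError):
            compare_rate_hypotheses([a, b])

    def test_ranking_on_simulated_mechanism_data(self, mechanism_fits):
        cmp = compare_rate_hypotheses(list(mechanism_fits["kp_data"].values()))
        assert cmp.ranking[0] == "kp"


class _StubFit:
    def __init__(self, rates):
        self._rates = rates

    def rates_dict(self):
        return self._rates


class TestRateErrors:
    def _dataset_with_sets(self, labels):
        ds, _ = _small_dataset(DEFAULT_BASELINE, m0_series=(10.0,), dt=50.0,
                               duration=500.0, replicates=len(labels))
        return KineticDataset(ds.traces, replicate_sets=labels)

    def test_identical_sets_zero_uncertainty(self):
        ds = self._dataset_with_sets([0, 1])
        unc = estimate_rate_errors(ds, lambda sub: _StubFit({"kn_prime": 1.0}))
        assert unc["kn_prime"] == 0.0

    def test_half_difference_rule(self):
        # truths differing by 10%: uncertainty = half the gap = 5% of the mean
        ds = self._dataset_with_sets([0, 1])
        vals = iter([1.0, 1.1])
        unc = estimate_rate_errors(
            ds, lambda sub: _StubFit({"kn_prime": next(vals)}))
        assert unc["kn_prime"] == pytest.approx(0.05, abs=1e-12)

    def test_single_set_refused(self):
        ds = self._dataset_with_sets([0, 0])
        with pytest.raises(InsufficientDataError):
            estimate_rate_errors(ds, lambda sub: _StubFit({}))

    def test_replicate_fits_bracket_truth(self, baseline_dataset, fit_settings):
        """Uncertainties from independent replicate fits are positive and of
        the order of the recovery error."""
        dataset, truth = baseline_dataset
        unseeded = dataset.unseeded
        tiny = FitSettings(rng_seed=7, max_iterations=15, popsize=8,
                           grid_points=11)
        unc = estimate_rate_errors(
            unseeded, lambda sub: UnseededGlobalModel(sub).fit(tiny))
        assert unc["kn_prime"] > 0
        # spread across 1%-noise replicate sets stays well below the value
        assert unc["kn_prime"] < 0.5 * truth["reduced"]["kn_prime"]
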