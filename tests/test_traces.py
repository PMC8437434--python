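"""Trace preparation: baseline subtraction, binning, conversion, half-times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taukinetics.datasets import Condition, MassTrace, RawTrace
from taukinetics.exceptions import (
    AlignmentError,
    InsufficientDataError,
    InvalidInputError,
    NotSaturatedError,
)
from taukinetics.kinetics import InitialConditions, KineticParameters, simulate
from taukinetics.traces import (
    ConversionSpec,
    bin_trace,
    extract_half_time,
    fit_scaling_exponent,
    read_trace_csv,
    signal_to_mass,
    subtract_baseline,
    write_trace_csv,
)

COND = Condition(m0=10.0)


def raw(times, signal, cond=COND):
    return RawTrace(np.asarray(times, float), np.asarray(signal, float), cond)


class TestSubtractBaseline:
    def test_identical_gives_zero(self):
        tr = raw([0, 1, 2, 3], [5, 6, 7, 8])
        out = subtract_baseline(tr, tr)
        assert np.all(out.signal == 0)

    def test_constant_shift(self):
        tr = raw([0, 1, 2, 3], [55, 56, 57, 58])
        base = raw([0, 1, 2, 3], [5, 6, 7, 8])
        assert np.all(subtract_baseline(tr, base).signal == 50)

    def test_coarser_baseline_interpolated(self):
        # baseline linear in time on a 2x coarser grid: interpolation is exact
        tr = raw([0, 1, 2, 3], [10, 20, 30, 40])
        base = raw([0, 2, 4, 6], [0, 4, 8, 12])  # slope 2/min
        out = subtract_baseline(tr, base)
        assert np.allclose(out.signal, [10, 18, 26, 34])

    def test_non_overlapping_ranges_rejected(self):
        tr = raw([0, 1, 2, 3], [1, 2, 3, 4])
        base = raw([10, 11, 12, 13], [0, 0, 0, 0])
        with pytest.raises(AlignmentError):
            subtract_baseline(tr, base)


class TestBinTrace:
    def test_identity_at_bin_one(self):
        tr = raw([0, 1, 2, 3], [1, 2, 3, 4])
        assert bin_trace(tr, 1) is tr

    def test_constant_signal_unchanged(self):
        tr = raw(np.arange(10.0), np.full(10, 7.0))
        out = bin_trace(tr, 3)
        assert np.all(out.signal == 7.0)
        assert out.times.size == 4  # ceil(10/3)

    def test_hand_example(self):
        tr = raw([0, 1, 2, 3], [0, 2, 4, 6])
        out = bin_trace(tr, 2)
        assert np.allclose(out.times, [0.5, 2.5])
        assert np.allclose(out.signal, [1, 5])

    def test_trailing_partial_window(self):
        tr = raw([0, 1, 2, 3, 4], [0, 2, 4, 6, 8])
        out = bin_trace(tr, 2)
        assert np.allclose(out.times, [0.5, 2.5, 4.0])
        assert np.allclose(out.signal, [1, 5, 8])

    @pytest.mark.parametrize("bad", [0, 6, -1, 2.5])
    def test_rejects_out_of_range_bin(self, bad):
        tr = raw([0, 1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(InvalidInputError):
            bin_trace(tr, bad)

    def test_preserves_mass_trace_type(self):
        tr = MassTrace(np.arange(6.0), np.arange(6.0), COND)
        assert isinstance(bin_trace(tr, 2), MassTrace)


class TestSignalToMass:
    SPEC = ConversionSpec(mmax=40.0, Smax_inf=1000.0)

    def test_anchor_maps_to_mmax(self):
        tr = raw([0, 1, 2, 3], [1000.0] * 4, Condition(m0=40.0))
        (out,) = signal_to_mass([tr], self.SPEC)
        assert np.allclose(out.M, 40.0)

    def test_zero_maps_to_zero_and_hand_value(self):
        tr = raw([0, 1, 2, 3], [0.0, 250.0, 500.0, 1000.0], Condition(m0=40.0))
        (out,) = signal_to_mass([tr], self.SPEC)
        assert np.allclose(out.M, [0.0, 10.0, 20.0, 40.0])

    def test_linearity(self):
        sig = np.array([0.0, 100.0, 400.0, 900.0])
        tr = raw([0, 1, 2, 3], sig)
        tr2 = raw([0, 1, 2, 3], 3.0 * sig)
        (a,), (b,) = signal_to_mass([tr], self.SPEC), signal_to_mass([tr2], self.SPEC)
        assert np.allclose(3.0 * a.M, b.M)

    def test_spec_from_traces_uses_highest_concentration(self):
        lo = raw(np.arange(10.0), np.linspace(0, 400, 10), Condition(m0=10.0))
        hi = raw(np.arange(10.0), np.full(10, 999.0), Condition(m0=40.0))
        spec = ConversionSpec.from_traces([lo, hi])
        assert spec.mmax == 40.0
        assert spec.Smax_inf == pytest.approx(999.0)


class TestExtractHalfTime:
    def test_linear_ramp(self):
        # linear 0 -> 10 over [0, 10] then flat: plateau 10, crossing at 5
        t = np.concatenate([np.linspace(0, 10, 11), np.linspace(11, 100, 90)])
        M = np.concatenate([np.linspace(0, 10, 11), np.full(90, 10.0)])
        res = extract_half_time(MassTrace(t, M, COND))
        assert res.t_half == pytest.approx(5.0, abs=1e-9)
        assert res.plateau == pytest.approx(10.0)

    def test_symmetric_logistic_center(self):
        t = np.linspace(0, 200, 401)
        M = 10.0 / (1.0 + np.exp(-(t - 100.0) / 5.0))
        res = extract_half_time(MassTrace(t, M, COND))
        assert res.t_half == pytest.approx(100.0, abs=0.5)

    def test_matches_dense_grid_oracle(self):
        p = KineticParameters(2e-9, 50.0, 4e-6, 5.0)
        coarse = np.arange(0.0, 500.5, 2.0)
        dense = np.arange(0.0, 500.05, 0.1)
        tr = simulate(p, InitialConditions(10.0), coarse).mass_trace()
        res = extract_half_time(tr)
        dense_traj = simulate(p, InitialConditions(10.0), dense)
        dres = extract_half_time(dense_traj.mass_trace())
        assert abs(res.t_half - dres.t_half) < 2.0  # one coarse interval

    def test_unsaturated_trace_rejected(self):
        t = np.linspace(0, 100, 51)
        M = 0.1 * t  # still rising at the end
        with pytest.raises(NotSaturatedError):
            extract_half_time(MassTrace(t, M, COND))

    def test_binning_shifts_half_time_less_than_one_bin(self):
        p = KineticParameters(2e-9, 50.0, 4e-6, 5.0)
        times = np.arange(0.0, 500.5, 2.0)
        tr = simulate(p, InitialConditions(10.0), times).mass_trace()
        t0 = extract_half_time(tr).t_half
        for b in (2, 5):
            tb = extract_half_time(bin_trace(tr, b)).t_half
            assert abs(tb - t0) < b * 2.0


class TestScalingExponent:
    def test_exact_power_law_recovered(self):
        m0 = np.array([2.5, 5, 10, 20, 40])
        th = 100.0 * m0**-0.5
        res = fit_scaling_exponent(list(zip(m0, th)))
        assert abs(res.gamma + 0.5) < 1e-10
        assert abs(res.curvature_coeff) < 1e-10
        assert not res.curvature_significant

    def test_constant_half_times(self):
        res = fit_scaling_exponent([(2.5, 50.0), (10.0, 50.0), (40.0, 50.0)])
        assert res.gamma == pytest.approx(0.0, abs=1e-12)

    def test_too_few_concentrations(self):
        with pytest.raises(InsufficientDataError):
            fit_scaling_exponent([(5.0, 10.0), (10.0, 8.0)])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(gamma=st.floats(-1.5, 1.5), amp=st.floats(1.0, 1000.0))
    def test_power_law_property(self, gamma, amp):
        m0 = np.array([2.5, 5, 10, 20, 40])
        th = amp * m0**gamma
        res = fit_scaling_exponent(list(zip(m0, th)))
        assert res.gamma == pytest.approx(gamma, abs=1e-9)


def test_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    traces = [
        RawTrace(np.arange(6.0), rng.uniform(0, 100, 6),
                 Condition(m0=m0, chaperone="HSPB1", chaperone_conc=2.0,
                           replicate=r))
        for m0 in (5.0, 10.0) for r in (0, 1)
    ]
    path = tmp_path / "plate.csv"
    write_trace_csv(traces, path, kind="raw")
    back = read_trace_csv(path, kind="raw")
    assert len(back) == len(traces)
    key = lambda tr: (tr.condition.m0, tr.condition.replicate)
    for a, b in zip(sorted(traces, key=key), sorted(back, key=key)):
        assert np.allclose(a.times, b.times)
        assert np.allclose(a.signal, b.signal)
        assert a.condition == b.condition
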