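"""Forward model: derivatives, simulation, conservation, degeneracy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taukinetics.exceptions import InvalidInputError
from taukinetics.kinetics import (
    InitialConditions,
    KineticParameters,
    derivatives,
    seeded_initial_conditions,
    simulate,
    simulate_mass_curve,
)


class TestDerivatives:
    @pytest.mark.parametrize(
        "state, params, total, expected",
        [
            # fully converted: nucleation and growth vanish, only breakage
            ((10.0, 0.5), KineticParameters(1e-3, 2.0, 0.001, 10.0), 10.0,
             (0.01, 0.0)),
            # no fibrils, no sources
            ((0.0, 0.0), KineticParameters(0.0, 2.0, 0.0, 10.0), 10.0,
             (0.0, 0.0)),
            # hand evaluation of the nucleation term: 1e-4 * 10^2
            ((0.0, 0.0), KineticParameters(1e-4, 0.0, 0.0, 10.0, nc=2), 10.0,
             (0.01, 0.0)),
            # hand evaluation of saturating growth: 2*2*(100/20)*0.05
            ((0.0, 0.05), KineticParameters(0.0, 2.0, 0.0, 10.0), 10.0,
             (0.0, 1.0)),
        ],
    )
    def test_hand_examples(self, state, params, total, expected):
        dP, dM = derivatives(state, params, total)
        assert dP == pytest.approx(expected[0], rel=1e-12)
        assert dM == pytest.approx(expected[1], rel=1e-12)

    def test_rejects_invalid_state(self):
        p = KineticParameters(1e-4, 1.0, 0.0, 10.0)
        with pytest.raises(InvalidInputError):
            derivatives((np.nan, 0.0), p, 10.0)
        with pytest.raises(InvalidInputError):
            derivatives((-1.0, 0.0), p, 10.0)

    def test_rejects_negative_rates(self):
        with pytest.raises(InvalidInputError):
            KineticParameters(-1e-4, 1.0, 0.0, 10.0)
        with pytest.raises(InvalidInputError):
            KineticParameters(1e-4, 1.0, 0.0, -10.0)
        with pytest.raises(InvalidInputError):
            KineticParameters(1e-4, 1.0, 0.0, 10.0, nc=0)


def _rk4_oracle(params, init, t_end, n_steps):
    """Independent fixed-step fourth-order integrator of the moment equations."""
    mtot = init.m0 + init.M0
    y = np.array([init.M0, init.P0])
    h = t_end / n_steps
    out = [y.copy()]

    def f(y):
        M, P = y
        m = max(0.0, mtot - M)
        return np.array([
            2.0 * params.kp * (params.KE * m / (params.KE + m)) * P,
            params.kn * m**params.nc + params.km * M,
        ])

    for _ in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)


class TestSimulate:
    def test_nothing_nucleates(self):
        p = KineticParameters(0.0, 50.0, 1e-4, 10.0)
        traj = simulate(p, InitialConditions(10.0), np.linspace(0, 100, 51))
        assert np.all(traj.M == 0)

    def test_full_conversion_plateau(self):
        p = KineticParameters(1e-4, 50.0, 1e-4, 10.0)
        traj = simulate(p, InitialConditions(10.0), np.linspace(0, 2000, 201))
        assert traj.M[-1] == pytest.approx(10.0, rel=1e-3)

    def test_against_fine_step_rk4(self):
        """LSODA trajectory matches an independent RK4 oracle at fine steps."""
        p = KineticParameters(kn=1e-5, kp=50.0, km=1e-4, KE=10.0)
        init = InitialConditions(10.0)
        times = np.linspace(0, 60, 61)
        traj = simulate(p, init, times, rtol=1e-10, atol=1e-12)
        oracle = _rk4_oracle(p, init, 60.0, 60 * 200)
        M_oracle = oracle[::200, 0]
        scale = np.maximum(M_oracle, 1e-9 * init.m0)
        assert np.max(np.abs(traj.M - M_oracle) / scale) < 1e-6

    def test_mass_conservation_exact(self):
        p = KineticParameters(1e-5, 50.0, 1e-4, 10.0)
        traj = simulate(p, InitialConditions(10.0, 1.0, 0.01),
                        np.linspace(0, 200, 101))
        assert np.max(np.abs(traj.m + traj.M - 11.0)) < 1e-8 * 11.0

    def test_early_time_quadratic_law(self):
        """For km=0, KE >> m0, nc=2: M(t) ~ kn*kp*m0^3 * t^2 as t -> 0."""
        kn, kp, m0 = 1e-6, 10.0, 5.0
        p = KineticParameters(kn, kp, 0.0, 1e5)
        t = np.array([0.0, 0.005, 0.01, 0.02])
        traj = simulate(p, InitialConditions(m0), t, rtol=1e-12, atol=1e-14)
        expected = kn * kp * m0**3 * t[1:] ** 2
        assert np.allclose(traj.M[1:], expected, rtol=0.01)

    def test_monotone_in_time(self):
        p = KineticParameters(1e-5, 50.0, 1e-4, 10.0)
        traj = simulate(p, InitialConditions(10.0), np.linspace(0, 500, 251))
        assert np.all(np.diff(traj.M) >= -1e-8 * 10.0)
        assert np.all(np.diff(traj.P) >= -1e-12)

    def test_rejects_bad_time_grid(self):
        p = KineticParameters(1e-5, 50.0, 0.0, 10.0)
        with pytest.raises(InvalidInputError):
            simulate(p, InitialConditions(10.0), [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            simulate(p, InitialConditions(10.0), [0.0, 2.0, 1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        log_kn=st.floats(-8, -3),
        log_kp=st.floats(0, 2.5),
        log_km=st.floats(-7, -3),
        KE=st.floats(0.5, 50.0),
        m0=st.floats(2.5, 40.0),
    )
    def test_conservation_and_bounds_property(self, log_kn, log_kp, log_km, KE, m0):
        """Mass conservation and amplitude bound hold across the rate space."""
        p = KineticParameters(10.0**log_kn, 10.0**log_kp, 10.0**log_km, KE)
        traj = simulate(p, InitialConditions(m0), np.linspace(0, 300, 61))
        assert np.max(np.abs(traj.m + traj.M - m0)) < 1e-8 * m0
        assert np.all(traj.M <= m0 * (1 + 1e-12))
        assert np.all(np.diff(traj.M) >= -1e-7 * m0)


class TestDegeneracy:
    """Unseeded observables depend on (kn, kp, km) only through the products
    kn*kp and km*kp; seeds break the degeneracy."""

    BASE = KineticParameters(kn=2e-9, kp=50.0, km=4e-6, KE=5.0)

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_unseeded_invariant(self, c):
        times = np.arange(0.0, 500.5, 2.0)
        p2 = KineticParameters(self.BASE.kn * c, self.BASE.kp / c,
                               self.BASE.km * c, self.BASE.KE)
        M1 = simulate(self.BASE, InitialConditions(10.0), times).M
        M2 = simulate(p2, InitialConditions(10.0), times).M
        scale = np.maximum(M1, 1e-9 * 10.0)
        assert np.max(np.abs(M1 - M2) / scale) < 1e-6

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_seeded_breaks_invariance(self, c):
        times = np.arange(0.0, 45.1, 0.25)
        init = seeded_initial_conditions(1.0, 100.0, 10.0)
        p2 = KineticParameters(self.BASE.kn * c, self.BASE.kp / c,
                               self.BASE.km * c, self.BASE.KE)
        M1 = simulate(self.BASE, init, times).M
        M2 = simulate(p2, init, times).M
        assert np.max(np.abs(M1 - M2)) > 0.05 * 10.0


class TestSeededInitialConditions:
    @pytest.mark.parametrize(
        "M0, L, m0, P0",
        [(1.0, 100.0, 10.0, 0.01), (0.0, 100.0, 10.0, 0.0),
         (0.5, 50.0, 10.0, 0.01)],
    )
    def test_values(self, M0, L, m0, P0):
        init = seeded_initial_conditions(M0, L, m0)
        assert init.P0 == pytest.approx(P0, abs=1e-15)
        assert init.M0 == M0 and init.m0 == m0

    def test_rejects_short_seed(self):
        with pytest.raises(InvalidInputError):
            seeded_initial_conditions(1.0, 0.5, 10.0)


def test_mass_trace_export_roundtrip(tmp_path):
    p = KineticParameters(1e-5, 50.0, 1e-4, 10.0)
    trace = simulate_mass_curve(p, InitialConditions(10.0),
                                np.linspace(0, 100, 26))
    traj = trace.trajectory
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["t_min", "m_uM", "M_uM", "P_uM"]
    assert np.allclose(df["M_uM"], traj.M)
    jpath = tmp_path / "params.json"
    p.to_json(jpath)
    assert KineticParameters.from_dict(
        __import__("json").loads(jpath.read_text())) == p
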