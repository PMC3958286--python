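import numpy as np
import pytest

import mediamp as ma
from mediamp.analysis import oxygen_sensitivity, response_time, sensitivity_sweep


def _synthetic_transient(t, i):
    return ma.Transient(
        t=np.asarray(t), current=np.asarray(i), state=None, i_st=float(i[-1]),
        t_r=np.nan, halt_reason="converged", epsilon=0.01,
    )


class TestCurrent:
    def test_zero_profile_zero_current(self, table1):
        g = ma.build_grid(table1, 50)
        st = ma.initial_state(table1, g)
        assert ma.current(st, table1, g) == 0.0

    def test_linear_profile_exact(self, table1):
        """The one-sided stencil is exact on linear profiles; the value
        is A*n_e*F*D_Mred1*gradient."""
        g = ma.build_grid(table1, 50)
        st = ma.initial_state(table1, g)
        st.m_red = 1e4 * g.x
        np.testing.assert_allclose(ma.current(st, table1, g), 1.3025610e-6, rtol=1e-6)

    def test_linearity_in_m_red(self, table1):
        g = ma.build_grid(table1, 10)
        st = ma.initial_state(table1, g)
        st.m_red = np.sin(g.x / g.x[-1]) * 1e-2
        i1 = ma.current(st, table1, g)
        st.m_red = 2.0 * st.m_red
        assert ma.current(st, table1, g) == 2.0 * i1

    def test_too_few_nodes(self, table1):
        g = ma.build_grid(table1, 1)
        st = ma.initial_state(table1, g)
        with pytest.raises(ValueError, match="at least 3"):
            ma.current(st, table1, g)


class TestResponseTime:
    def test_exponential_saturation(self):
        """For i(t) = 1 - exp(-t) the decay-rate criterion with
        epsilon = 0.01 is first met near t = 6.47 (root of
        t e^-t / (1 - e^-t) = 0.01)."""
        t = np.linspace(0, 12, 24001)
        tr = _synthetic_transient(t, 1 - np.exp(-t))
        assert 6.3 <= response_time(tr, 0.01) <= 6.6

    def test_constant_current_halts_immediately(self):
        t = np.linspace(0, 5, 100)
        tr = _synthetic_transient(t, np.ones_like(t))
        assert response_time(tr, 0.01) == t[1]

    def test_monotone_in_epsilon(self):
        t = np.linspace(0, 12, 24001)
        tr = _synthetic_transient(t, 1 - np.exp(-t))
        assert response_time(tr, 0.001) >= response_time(tr, 0.01)

    def test_never_met_warns_and_returns_nan(self):
        t = np.linspace(0, 1, 50)
        tr = _synthetic_transient(t, t)  # keeps rising
        with pytest.warns(UserWarning, match="never met"):
            assert np.isnan(response_time(tr, 1e-9))


class TestOxygenSensitivity:
    def test_k3_zero_gives_exactly_zero(self, table1):
        p = table1.replace(k3=0.0)
        opts = ma.SolverOptions(points_per_layer=6, dt=0.05, t_max=5.0)
        res = oxygen_sensitivity(p, opts)
        assert res.B_O2 == 0.0
        assert res.i_st_anaerobic == res.i_st_aerobic

    def test_identical_oxygen_levels_give_exactly_zero(self, table1):
        opts = ma.SolverOptions(points_per_layer=6, dt=0.05, t_max=5.0)
        res = oxygen_sensitivity(table1, opts, o0_anaerobic=table1.o0)
        assert res.B_O2 == 0.0

    def test_requires_substrate_and_mediator(self, table1):
        with pytest.raises(ValueError, match="s0 > 0"):
            oxygen_sensitivity(table1.replace(s0=0.0), ma.SolverOptions())


class TestCalibration:
    def test_zero_row_and_monotonicity(self, table1):
        opts = ma.SolverOptions(points_per_layer=8, dt=0.05, t_max=40.0)
        df = ma.calibration_curve(table1, opts, [0.0, 0.49, 4.98, 19.6])
        assert df.loc[0, "i_st"] == 0.0
        assert df["i_st"].is_monotonic_increasing

    def test_single_point_matches_direct_simulation(self, table1):
        opts = ma.SolverOptions(points_per_layer=8, dt=0.05, t_max=20.0)
        df = ma.calibration_curve(table1, opts, [4.98])
        tr = ma.simulate(table1, opts)
        assert df.loc[0, "i_st"] == tr.i_st


class TestSweep:
    def test_unknown_parameter(self, table1):
        with pytest.raises(ValueError, match="unknown sweep parameter"):
            sensitivity_sweep(table1, None, "k1", [1.0])

    def test_zero_k3_row_and_row_invariants(self, table1):
        opts = ma.SolverOptions(points_per_layer=6, dt=0.05, t_max=5.0)
        sw = sensitivity_sweep(table1, opts, "k3", [0.18, 0.0], s0_values=[4.98])
        df = sw.table
        assert list(df["k3"]) == [0.0, 0.18]  # sorted by swept value
        assert df.loc[df["k3"] == 0.0, "B_O2"].item() == 0.0
        assert (df["i_st_aerobic"] <= df["i_st_anaerobic"]).all()
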