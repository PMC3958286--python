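import numpy as np
import pytest

import mediamp as ma
from mediamp.solver import SolverError, _Session


class TestGrid:
    def test_reference_mesh(self, table1):
        g = ma.build_grid(table1, ma.SolverOptions(points_per_layer=50))
        assert g.n_nodes == 201
        assert g.x[50] == 5e-6  # node exactly on the enzyme/PVA interface
        assert g.x[-1] == table1.boundaries[-1]
        assert list(g.interfaces) == [50, 100, 150]

    def test_degenerate_single_interval_mesh(self, table1):
        g = ma.build_grid(table1, 1)
        np.testing.assert_array_equal(g.x, table1.boundaries)

    def test_uniform_spacing_within_layers(self, table1):
        g = ma.build_grid(table1, 7)
        for i in range(4):
            seg = g.x[i * 7 : (i + 1) * 7 + 1]
            np.testing.assert_allclose(np.diff(seg), g.h[i], rtol=1e-12)


class TestInitialState:
    def test_substrate_and_mediator_only_at_outer_edge(self, table1):
        g = ma.build_grid(table1, 10)
        st = ma.initial_state(table1, g)
        assert st.s[-1] == table1.s0 and st.m_ox[-1] == table1.m0
        assert np.all(st.s[:-1] == 0.0) and np.all(st.m_ox[:-1] == 0.0)
        assert np.all(st.m_red == 0.0)
        assert np.all(st.o == table1.o0)
        np.testing.assert_array_equal(st.e_ox + st.e_red, table1.e0)

    def test_anaerobic_start(self, table1):
        g = ma.build_grid(table1, 10)
        st = ma.initial_state(table1.replace(o0=0.0), g)
        assert np.all(st.o == 0.0)


class TestStepping:
    def test_empty_bulk_is_fixed_point(self, table1):
        p = table1.replace(s0=0.0, m0=0.0, o0=0.0)
        opts = ma.SolverOptions(points_per_layer=6, dt=0.1)
        g = ma.build_grid(p, opts)
        st0 = ma.initial_state(p, g)
        st1 = ma.step(st0, p, g, opts)
        for name in ("s", "m_ox", "m_red", "o", "e_red"):
            np.testing.assert_array_equal(getattr(st1, name), 0.0)
        np.testing.assert_array_equal(st1.e_ox, p.e0)

    def test_pure_diffusion_relaxes_to_flat_bulk_profiles(self, table1):
        """With every reaction off the steady state is the multilayer
        diffusion solution, which for these boundary conditions is the
        piecewise-linear profile of zero slope (no steady flux passes a
        zero-flux or equal-value boundary pair)."""
        p = table1.replace(k1=0.0, k2=0.0, k3=0.0)
        opts = ma.SolverOptions(points_per_layer=10, dt=1e10, picard_tol=1e-13)
        sess = _Session(p, opts)
        for _ in range(3):
            sess.step_once()
        st = sess.state
        np.testing.assert_allclose(st.s, p.s0, rtol=1e-10)
        np.testing.assert_allclose(st.m_ox, p.m0, rtol=1e-10)
        np.testing.assert_allclose(st.o, p.o0, rtol=1e-10)
        assert np.all(st.m_red == 0.0)
        np.testing.assert_array_equal(st.e_ox, p.e0)

    def test_picard_divergence_raises(self, table1):
        opts = ma.SolverOptions(points_per_layer=4, dt=0.5, picard_max_iter=2, t_max=1.0)
        with pytest.raises(SolverError, match="Picard"):
            ma.simulate(table1, opts)


class TestSimulate:
    def test_no_substrate_no_current(self, table1):
        p = table1.replace(s0=0.0)
        tr = ma.simulate(p, ma.SolverOptions(points_per_layer=4, dt=0.05, t_max=1.0))
        assert tr.halt_reason == "t_max"
        assert np.isnan(tr.t_r)
        np.testing.assert_array_equal(tr.current, 0.0)
        assert tr.i_st == 0.0

    def test_snapshots_recorded_at_requested_times(self, table1):
        opts = ma.SolverOptions(
            points_per_layer=4, dt=0.05, t_max=1.0, epsilon=1e-12,
            snapshot_times=[0.25, 0.8],
        )
        tr = ma.simulate(table1, opts)
        assert len(tr.snapshots) == 2
        assert tr.snapshots[0].t == pytest.approx(0.25, abs=opts.dt)
        assert tr.snapshots[1].t == pytest.approx(0.8, abs=opts.dt)

    def test_steady_state_wrapper_returns_final_fields(self, table1):
        opts = ma.SolverOptions(points_per_layer=4, dt=0.05, t_max=1.0, epsilon=1e-12)
        with pytest.warns(UserWarning, match="t_max"):
            st = ma.steady_state(table1, opts)
        tr = ma.simulate(table1, opts)
        np.testing.assert_array_equal(st.s, tr.state.s)
        assert st.t == tr.state.t

    def test_reference_transient_shape(self, reference_run):
        tr, _, opts = reference_run
        assert tr.halt_reason == "converged"
        assert tr.t_r == tr.t[-1]
        assert tr.i_st == tr.current[-1]
        assert np.all(np.diff(tr.t) > 0)
        # current rises monotonically to the plateau at these conditions
        assert tr.i_st > 0
        assert np.all(tr.current[:-1] <= tr.current[1:] + 1e-12 * tr.i_st)

    def test_enzyme_conservation_through_transient(self, reference_run, table1):
        tr, _, _ = reference_run
        dev = np.max(np.abs(tr.state.e_ox + tr.state.e_red - table1.e0))
        assert dev <= 1e-9 * table1.e0

    def test_positivity_and_bounds(self, reference_run, table1):
        st = reference_run[0].state
        for name in ("s", "m_ox", "m_red", "o", "e_ox", "e_red"):
            assert getattr(st, name).min() >= 0.0
        assert st.o.max() <= table1.o0 * (1 + 1e-12)  # O2 is only consumed
        assert st.s.max() <= table1.s0 * (1 + 1e-12)

    def test_electrode_dirichlet_rows_exact(self, reference_run, table1):
        st = reference_run[0].state
        assert st.m_red[0] == 0.0
        assert st.m_ox[-1] == table1.m0
        assert st.s[-1] == table1.s0

    def test_electrode_flux_antisymmetry(self, reference_run, table1):
        """The m_ox flux into the electrode mirrors the m_red flux out
        (the electrode converts one into the other 1:1)."""
        tr, g, _ = reference_run
        st = tr.state
        h = g.h[0]
        f_red = table1.D_Mred[0] * (4 * st.m_red[1] - st.m_red[2]) / (2 * h)
        f_ox = table1.D_Mox[0] * (-3 * st.m_ox[0] + 4 * st.m_ox[1] - st.m_ox[2]) / (2 * h)
        assert abs(f_red + f_ox) <= 1e-6 * abs(f_red)

    def test_interface_flux_continuity(self, reference_run, table1):
        """Diffusive flux is continuous across the PVA/terylene and
        terylene/diffusion-layer interfaces for the reaction-free
        substrate field at steady state."""
        tr, g, _ = reference_run
        s = tr.state.s
        for k in (1, 2):  # interfaces a2 and a3
            j = g.interfaces[k]
            f_left = table1.D_S[k] * (s[j] - s[j - 1]) / g.h[k]
            f_right = table1.D_S[k + 1] * (s[j + 1] - s[j]) / g.h[k + 1]
            assert abs(f_left - f_right) <= 1e-3 * abs(f_left)

    def test_anaerobic_equals_reaction_seven_off(self, table1):
        """o0 = 0 keeps the O2 field identically zero, which makes the
        mediator dynamics bitwise identical to a k3 = 0 run."""
        opts = ma.SolverOptions(points_per_layer=8, dt=0.02, t_max=2.0, epsilon=1e-12)
        tr_an = ma.simulate(table1.replace(o0=0.0), opts)
        tr_off = ma.simulate(table1.replace(k3=0.0), opts)
        np.testing.assert_array_equal(tr_an.current, tr_off.current)
        for name in ("s", "m_ox", "m_red", "e_ox", "e_red"):
            np.testing.assert_array_equal(
                getattr(tr_an.state, name), getattr(tr_off.state, name)
            )
        assert np.all(tr_an.state.o == 0.0)

    def test_refinement_stability(self, table1, reference_run):
        """i_st settles under simultaneous dt halving and grid doubling."""
        i_10 = ma.simulate(table1, ma.SolverOptions(points_per_layer=10, dt=0.02)).i_st
        i_20 = ma.simulate(table1, ma.SolverOptions(points_per_layer=20, dt=0.01)).i_st
        i_50 = reference_run[0].i_st
        assert abs(i_20 - i_10) > abs(i_50 - i_20)
        assert abs(i_50 - i_20) / i_50 < 0.005

    def test_k3_zero_substrate_profile_piecewise_linear(self, table1):
        """Without the O2 reaction the outer layers are reaction-free
        for every species, so the steady substrate profile there is the
        constant-flux piecewise-linear multilayer solution."""
        p = table1.replace(k3=0.0)
        opts = ma.SolverOptions(points_per_layer=10, dt=0.02)
        tr = ma.simulate(p, opts)
        g = ma.build_grid(p, opts)
        s = tr.state.s
        ppl = g.points_per_layer
        fluxes = []
        for layer in (1, 2, 3):  # layers 2-4, zero-based into h/D arrays
            j0 = layer * ppl
            slope = (s[j0 + ppl] - s[j0]) / (g.h[layer] * ppl)
            fluxes.append(p.D_S[layer] * slope)
        fluxes = np.array(fluxes)
        np.testing.assert_allclose(fluxes, fluxes[0], rtol=1e-2)
        # closed form anchored at the computed s(a1) and the bulk value
        resistance = np.sum(g.h[1:] * ppl / p.D_S[1:])
        flux = (p.s0 - s[ppl]) / resistance
        r_cum = np.concatenate(
            [np.zeros(1)]
            + [np.full(ppl, g.h[k] / p.D_S[k]) for k in (1, 2, 3)]
        ).cumsum()
        expected = s[ppl] + flux * r_cum
        np.testing.assert_allclose(s[ppl:], expected, rtol=1e-2)
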