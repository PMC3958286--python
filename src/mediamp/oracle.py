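"""Independent reference solution by the method of lines.

The same spatial semi-discretization the implicit solver uses
(:class:`~mediamp.solver.Discretization`: identical interior, interface
and boundary rows, identical current stencil) is integrated in time
with SciPy's adaptive stiff BDF integrator at tight tolerance.  Because
the spatial operator is shared, a solver-versus-reference comparison
isolates the time-integration error of the backward-Euler scheme;
spatial accuracy is assessed separately by grid refinement against the
piecewise-linear steady diffusion solution.

Not a production path: no steady-state detection, coarse grids only
(the full dense Jacobian factorizations get expensive beyond a few
hundred unknowns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .model import ModelParameters, Species, validate_parameters
from .solver import Discretization, Grid, State, Transient, initial_state

__all__ = ["OracleSolution", "reference_transient", "compare_transients", "TransientComparison"]


@dataclass
class OracleSolution:
    """Reference current trajectory with states at the evaluation times."""

    t: np.ndarray
    current: np.ndarray
    states: list[State]
    grid: Grid
    rtol: float
    atol: np.ndarray


class _Packing:
    """Index bookkeeping between full fields and the ODE unknown vector.

    Constrained nodes (bulk Dirichlet rows, the electrode Dirichlet row
    of m_red, and the algebraic electrode row of m_ox) are excluded
    from the state vector and reconstructed on evaluation.
    """

    def __init__(self, disc: Discretization):
        n = disc.g.n_nodes
        self.n = n
        self.n1 = disc.g.i_enzyme_edge
        self.sl_s = slice(0, n - 1)  # nodes 0..N-2
        self.sl_mox = slice(n - 1, 2 * n - 3)  # nodes 1..N-2
        self.sl_mred = slice(2 * n - 3, 3 * n - 5)  # nodes 1..N-2
        self.sl_o = slice(3 * n - 5, 4 * n - 6)  # nodes 0..N-2
        ne = self.n1 + 1
        self.sl_eox = slice(4 * n - 6, 4 * n - 6 + ne)
        self.sl_ered = slice(4 * n - 6 + ne, 4 * n - 6 + 2 * ne)
        self.size = 4 * n - 6 + 2 * ne

    def pack(self, st: State) -> np.ndarray:
        y = np.empty(self.size)
        y[self.sl_s] = st.s[:-1]
        y[self.sl_mox] = st.m_ox[1:-1]
        y[self.sl_mred] = st.m_red[1:-1]
        y[self.sl_o] = st.o[:-1]
        y[self.sl_eox] = st.e_ox
        y[self.sl_ered] = st.e_red
        return y

    def unpack(self, y: np.ndarray, disc: Discretization) -> State:
        p = disc.p
        n = self.n
        s = np.empty(n)
        m_ox = np.empty(n)
        m_red = np.empty(n)
        o = np.empty(n)
        s[:-1] = y[self.sl_s]
        s[-1] = p.s0
        m_ox[1:-1] = y[self.sl_mox]
        m_ox[-1] = p.m0
        m_red[0] = 0.0
        m_red[1:-1] = y[self.sl_mred]
        m_red[-1] = 0.0
        m_ox[0] = disc.electrode_mox(m_ox, m_red)
        o[:-1] = y[self.sl_o]
        o[-1] = p.o0
        return State(0.0, s, m_ox, m_red, o, y[self.sl_eox].copy(), y[self.sl_ered].copy())


def _rhs(disc: Discretization, pk: _Packing, y: np.ndarray) -> np.ndarray:
    p = disc.p
    st = pk.unpack(y, disc)
    w = disc.enzyme_weight
    n1 = pk.n1
    eox_ext = np.zeros(pk.n)
    ered_ext = np.zeros(pk.n)
    eox_ext[: n1 + 1] = st.e_ox
    ered_ext[: n1 + 1] = st.e_red
    r1 = p.k1 * w * eox_ext * st.s
    r2 = p.k2 * w * ered_ext * st.m_ox
    r3 = p.k3 * st.m_red * st.o
    ds = disc.apply(Species.S, st.s) - r1
    dmox = disc.apply(Species.M_OX, st.m_ox) - r2 + r3
    dmred = disc.apply(Species.M_RED, st.m_red) + r2 - r3
    do = disc.apply(Species.O, st.o) - r3
    deox = -p.k1 * st.e_ox * st.s[: n1 + 1] + p.k2 * st.e_red * st.m_ox[: n1 + 1]
    dy = np.empty_like(y)
    dy[pk.sl_s] = ds[:-1]
    dy[pk.sl_mox] = dmox[1:-1]
    dy[pk.sl_mred] = dmred[1:-1]
    dy[pk.sl_o] = do[:-1]
    dy[pk.sl_eox] = deox
    dy[pk.sl_ered] = -deox
    return dy


def _jac_sparsity(pk: _Packing) -> sparse.csr_matrix:
    """Generous sparsity pattern: couplings within two nodes, any species."""
    node_of = np.empty(pk.size, dtype=int)
    node_of[pk.sl_s] = np.arange(pk.n - 1)
    node_of[pk.sl_mox] = np.arange(1, pk.n - 1)
    node_of[pk.sl_mred] = np.arange(1, pk.n - 1)
    node_of[pk.sl_o] = np.arange(pk.n - 1)
    node_of[pk.sl_eox] = np.arange(pk.n1 + 1)
    node_of[pk.sl_ered] = np.arange(pk.n1 + 1)
    diff = np.abs(node_of[:, None] - node_of[None, :]) <= 2
    return sparse.csr_matrix(diff)


def reference_transient(
    p: ModelParameters,
    g: Grid,
    t_end: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
) -> OracleSolution:
    """Integrate the semi-discrete system with BDF at tight tolerance.

    ``t_eval`` defaults to 201 uniform times on ``[0, t_end]``.  The
    absolute tolerance is scaled per unknown to 1e-10 of the species'
    characteristic concentration, so the tiny oxygen field is resolved
    as sharply as the substrate.
    """
    from .analysis import current as _current

    p = validate_parameters(p)
    disc = Discretization(p, g)
    pk = _Packing(disc)
    if pk.n > 250:
        raise ValueError("the reference integrator is meant for coarse grids (<= ~250 nodes)")
    y0 = pk.pack(initial_state(p, g))
    scale = np.empty(pk.size)
    scale[pk.sl_s] = max(p.s0, 1e-30)
    scale[pk.sl_mox] = max(p.m0, 1e-30)
    scale[pk.sl_mred] = max(p.m0, 1e-30)
    scale[pk.sl_o] = max(p.o0, 1e-12 * p.m0, 1e-30)
    scale[pk.sl_eox] = max(p.e0, 1e-30)
    scale[pk.sl_ered] = max(p.e0, 1e-30)
    atol = 1e-10 * scale
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    sol = solve_ivp(
        lambda t, y: _rhs(disc, pk, y),
        (0.0, float(t_end)),
        y0,
        method="BDF",
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
        jac_sparsity=_jac_sparsity(pk),
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    states = []
    currents = np.empty(sol.t.size)
    for j in range(sol.t.size):
        st = pk.unpack(sol.y[:, j], disc)
        st.t = float(sol.t[j])
        states.append(st)
        currents[j] = _current(st, p, g)
    return OracleSolution(
        t=sol.t.copy(), current=currents, states=states, grid=g, rtol=rtol, atol=atol
    )


@dataclass
class TransientComparison:
    """Deviation report between a solver transient and a reference run."""

    max_rel_current_dev: float
    max_abs_current_dev: float
    profile_rel_dev: dict[str, float]
    t_window: tuple[float, float]


def compare_transients(a: Transient, b: OracleSolution) -> TransientComparison:
    """Interpolate both currents onto the overlapping window and compare.

    The relative metric normalizes by the larger of the two maximum
    currents, so it is symmetric under swapping the arguments.  The
    final-state profiles are compared species by species (relative to
    each species' maximum magnitude across both states).
    """
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if not t1 > t0:
        raise ValueError(f"disjoint time ranges: [{a.t[0]}, {a.t[-1]}] vs [{b.t[0]}, {b.t[-1]}]")
    tt = np.linspace(t0, t1, 400)
    ia = np.interp(tt, a.t, a.current)
    ib = np.interp(tt, b.t, b.current)
    norm = max(np.max(np.abs(ia)), np.max(np.abs(ib)))
    max_abs = float(np.max(np.abs(ia - ib)))
    max_rel = max_abs / norm if norm > 0 else 0.0
    prof: dict[str, float] = {}
    sb = b.states[-1]
    for sp in Species:
        ua = a.state.field_for(sp)
        ub = sb.field_for(sp)
        scale = max(np.max(np.abs(ua)), np.max(np.abs(ub)))
        prof[sp.value] = float(np.max(np.abs(ua - ub)) / scale) if scale > 0 else 0.0
    return TransientComparison(
        max_rel_current_dev=max_rel,
        max_abs_current_dev=max_abs,
        profile_rel_dev=prof,
        t_window=(t0, t1),
    )
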