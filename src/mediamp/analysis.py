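"""Observable outputs of the simulated biosensor.

The measured signal is the faradaic current from mediator reoxidation
at the electrode,

    i(t) = A n_e F D_Mred,1 * d(m_red)/dx |_{x=0},

with the gradient evaluated by the one-sided second-order stencil.  The
steady-state current i_st and the response time t_r come from the
decay-rate halting test; the oxygen-sensitivity statistic

    B_O2 = (i_st(o0=0) - i_st(o0=c_O2)) / i_st(o0=0)

is the relative current loss caused by the competing oxidation of the
reduced mediator by dissolved O2.  Because B_O2 differences two nearly
identical currents (the signal is ~1e-6 relative at the reference
parameters), the aerobic and anaerobic runs are stepped in lockstep on
the identical grid and time step and both are read at the same final
time, so that discretization error cancels between them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ModelParameters, validate_parameters
from .solver import (
    Grid,
    SolverOptions,
    State,
    Transient,
    _Session,
)

__all__ = [
    "current",
    "response_time",
    "SensitivityResult",
    "SweepTable",
    "oxygen_sensitivity",
    "calibration_curve",
    "sensitivity_sweep",
    "SWEEPABLE_PARAMETERS",
    "DEFAULT_S0_VALUES",
]

logger = logging.getLogger(__name__)

#: Substrate concentrations at which the sensitivity sweeps are run by
#: default, mol/m^3 (one low, the reference, one high).
DEFAULT_S0_VALUES = (0.498, 4.98, 49.8)

#: Decay-rate threshold used for sensitivity (paired) runs; tighter than
#: the ordinary response-time threshold because B_O2 needs the two
#: currents resolved to ~1e-7 relative.
SENSITIVITY_EPSILON = 1e-4

SWEEPABLE_PARAMETERS = ("k2", "k3", "d4")


def current(state: State, p: ModelParameters, g: Grid) -> float:
    """Faradaic current, A, from the electrode-surface m_red gradient.

    Uses the one-sided second-order stencil
    ``(-3 u0 + 4 u1 - u2) / (2 h)`` on the first three enzyme-layer
    nodes (all with the layer-1 spacing).
    """
    if g.points_per_layer < 2:
        raise ValueError("current needs at least 3 nodes inside the enzyme layer")
    m = state.m_red
    grad = (-3.0 * m[0] + 4.0 * m[1] - m[2]) / (2.0 * g.h[0])
    return p.A * p.n_e * p.F * p.D_Mred[0] * grad


def response_time(
    tr: Transient,
    epsilon: float,
    current_floor_fraction: float = 1e-3,
) -> float:
    """First time at which the guarded decay-rate test holds.

    The test at sample k is ``(t_k / i_k) |i_k - i_{k-1}| / (t_k -
    t_{k-1}) < epsilon``, evaluated only where ``i_k > 0`` and ``i_k``
    exceeds ``current_floor_fraction`` of the running maximum.  Returns
    NaN with a warning when the criterion is never met.
    """
    t = np.asarray(tr.t, dtype=float)
    i = np.asarray(tr.current, dtype=float)
    if t.size < 2:
        raise ValueError("response_time needs at least two samples")
    di = np.abs(np.diff(i)) / np.diff(t)
    run_max = np.maximum.accumulate(i)
    ik, tk = i[1:], t[1:]
    admissible = (ik > 0.0) & (ik >= current_floor_fraction * run_max[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(admissible, tk / ik * di, np.inf)
    hits = np.nonzero(rate < epsilon)[0]
    if hits.size == 0:
        warnings.warn(f"decay-rate test (epsilon={epsilon:g}) never met on this transient")
        return float("nan")
    return float(tk[hits[0]])


@dataclass(frozen=True)
class SensitivityResult:
    """Paired anaerobic/aerobic steady currents and the derived B_O2."""

    i_st_anaerobic: float
    i_st_aerobic: float
    B_O2: float
    t_final: float
    s0: float
    param_name: str | None = None
    param_value: float | None = None


@dataclass(frozen=True)
class SweepTable:
    """Cross of a swept parameter against substrate concentrations.

    ``table`` columns: the swept parameter name, ``s0``,
    ``i_st_anaerobic``, ``i_st_aerobic``, ``B_O2``; rows sorted by
    (swept value, s0).
    """

    param: str
    table: pd.DataFrame


def oxygen_sensitivity(
    p: ModelParameters,
    opts: SolverOptions | None = None,
    o0_aerobic: float | None = None,
    o0_anaerobic: float = 0.0,
) -> SensitivityResult:
    """B_O2 from a lockstep pair of anaerobic/aerobic simulations.

    Both runs share the grid and the time step and are advanced
    together; stepping stops once both satisfy the decay-rate test (or
    t_max), so both currents are read at the identical final time — the
    larger of the two response times, rounded up to the common step.
    ``o0_aerobic`` defaults to ``p.o0``.
    """
    p = validate_parameters(p)
    if not (p.s0 > 0 and p.m0 > 0):
        raise ValueError("oxygen_sensitivity requires s0 > 0 and m0 > 0")
    opts = opts or SolverOptions()
    eps = min(opts.epsilon, SENSITIVITY_EPSILON)
    if o0_aerobic is None:
        o0_aerobic = p.o0
    sess = {
        "an": _Session(p.replace(o0=o0_anaerobic), opts),
        "ae": _Session(p.replace(o0=o0_aerobic), opts),
    }
    prev = {k: s.current() for k, s in sess.items()}
    i_now = dict(prev)
    i_max = dict(prev)
    done = {k: False for k in sess}
    n_steps = int(round(opts.t_max / opts.dt))
    t = 0.0
    for k in range(1, n_steps + 1):
        t = k * opts.dt
        for key, s in sess.items():
            s.step_once()
            prev[key] = i_now[key]
            i_now[key] = s.current()
            i_max[key] = max(i_max[key], i_now[key])
            if not done[key]:
                i = i_now[key]
                if i > 0.0 and i >= opts.current_floor_fraction * i_max[key]:
                    if t / i * abs(i - prev[key]) / opts.dt < eps:
                        done[key] = True
        if all(done.values()):
            break
    if not all(done.values()):
        logger.warning("paired sensitivity runs hit t_max=%g s before converging", opts.t_max)
    i_an, i_ae = i_now["an"], i_now["ae"]
    if i_an == 0.0:
        raise ValueError("sensitivity undefined at zero response (i_st_anaerobic = 0)")
    return SensitivityResult(
        i_st_anaerobic=i_an,
        i_st_aerobic=i_ae,
        B_O2=(i_an - i_ae) / i_an,
        t_final=t,
        s0=p.s0,
    )


def calibration_curve(
    p: ModelParameters, opts: SolverOptions | None, s0_values: Sequence[float]
) -> pd.DataFrame:
    """Steady-state current and response time versus bulk substrate.

    One full simulation per entry of *s0_values* with every other
    parameter fixed; returns a frame with columns ``s0, i_st, t_r``.
    """
    from .solver import simulate

    opts = opts or SolverOptions()
    rows = []
    for s0 in s0_values:
        if s0 < 0:
            raise ValueError(f"negative substrate concentration {s0!r}")
        tr = simulate(p.replace(s0=s0), opts)
        rows.append({"s0": s0, "i_st": tr.i_st, "t_r": tr.t_r})
    return pd.DataFrame(rows)


def sensitivity_sweep(
    p: ModelParameters,
    opts: SolverOptions | None,
    param_name: str,
    values: Sequence[float],
    s0_values: Sequence[float] = DEFAULT_S0_VALUES,
) -> SweepTable:
    """B_O2 over the cross of one swept parameter and substrate levels.

    ``param_name`` is one of ``k2`` (enzyme reoxidation rate), ``k3``
    (mediator oxidation by O2) or ``d4`` (diffusion-layer thickness).
    Each cell is a full paired aerobic/anaerobic run.
    """
    if param_name not in SWEEPABLE_PARAMETERS:
        raise ValueError(f"unknown sweep parameter {param_name!r}; expected one of "
                         f"{SWEEPABLE_PARAMETERS}")
    rows = []
    for v in sorted(values):
        if v < 0:
            raise ValueError(f"negative sweep value {v!r} for {param_name}")
        for s0 in s0_values:
            pv = p.replace(**{param_name: v, "s0": s0})
            res = oxygen_sensitivity(pv, opts)
            rows.append(
                {
                    param_name: v,
                    "s0": s0,
                    "i_st_anaerobic": res.i_st_anaerobic,
                    "i_st_aerobic": res.i_st_aerobic,
                    "B_O2": res.B_O2,
                }
            )
    return SweepTable(param=param_name, table=pd.DataFrame(rows))
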