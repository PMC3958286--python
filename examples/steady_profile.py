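"""Steady-state concentration profiles at the reference conditions.

Runs the four-layer simulation to steady state and reports what the
profiles look like at the electrode surface: how far substrate and
oxygen are depleted relative to the bulk, and the resulting current.
A substrate drop of ~20% means glucose consumption competes with its
transport; the tiny oxygen drop (~4%) shows the mediator-O2 reaction
is slow compared with O2 diffusion.
"""

import mediamp as ma

p = ma.default_parameters()
opts = ma.SolverOptions(points_per_layer=50, dt=0.01)
tr = ma.simulate(p, opts)
st = tr.state

print(f"steady state reached at t_r = {tr.t_r:.1f} s  (decay rate < {opts.epsilon:g})")
print(f"steady-state current i_st = {tr.i_st:.4e} A")
print(f"substrate at electrode: {st.s[0]:.3f} mol/m^3 "
      f"({100 * (p.s0 - st.s[0]) / p.s0:.1f}% below bulk {p.s0} mol/m^3)")
print(f"oxygen at electrode:    {st.o[0]:.3e} mol/m^3 "
      f"({100 * (p.o0 - st.o[0]) / p.o0:.1f}% below bulk {p.o0:.3g} mol/m^3)")
print(f"reduced mediator at electrode is pinned to 0 (fast electrode reaction): "
      f"{st.m_red[0]:g}")
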