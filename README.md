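# mediamp

A reaction–diffusion simulator for a mediated amperometric glucose
biosensor, built for electrochemists and modellers who want to ask
*does dissolved oxygen corrupt an aerobic measurement?* before going
back to the glovebox.

## The model

The sensor is a sandwich on a carbon-paste electrode: an enzyme layer
(soluble PQQ-dependent glucose dehydrogenase, thickness d₁), a
polyvinyl-alcohol film (d₂), a terylene membrane (d₃), and a Nernst
diffusion layer (d₄) beyond which convection holds every concentration
at its bulk value. Four reactions drive the signal:

    E_ox + S     →(k₁)  E_red + P₁        enzyme reduction by glucose
    E_red + M_ox →(k₂)  E_ox  + M_red     enzyme reoxidation by the mediator (PMS)
    M_red + O₂   →(k₃)  M_ox  + P₂        the competing oxygen pathway
    M_red        →      M_ox + n_e e⁻     electrode reaction (fast), x = 0

Mass-action kinetics couple to one-dimensional diffusion with
layer-specific diffusivities; the enzyme forms are immobile and exist
only in the enzyme layer. The measured response is the faradaic
current

    i(t) = A n_e F D_Mred,1 ∂m_red/∂x |_{x=0},

its plateau i_st is detected by the decay-rate rule
(t/i)|di/dt| < ε, and the oxygen sensitivity is

    B_O2 = [i_st(o₀=0) − i_st(o₀=c_O2)] / i_st(o₀=0),

the relative signal lost to the M_red + O₂ reaction when the same
experiment is run aerobically.

Numerically: per-layer uniform grids sharing interface nodes, backward
Euler in time with Picard relinearization of the bilinear reaction
terms (each species update is one banded solve), finite-volume flux
matching at the layer interfaces, and an independent method-of-lines
reference integration (SciPy BDF on the identical spatial operator)
for verification.

## A worked example

```python
import mediamp as ma

p = ma.default_parameters()                  # reference sensor, aerobic
opts = ma.SolverOptions(points_per_layer=50, dt=0.01)
tr = ma.simulate(p, opts)
st = tr.state
print(f"i_st = {tr.i_st:.4e} A at t_r = {tr.t_r:.1f} s")
print(f"substrate at electrode: {st.s[0]:.3f} mol/m^3")
print(f"oxygen drop at electrode: {100*(p.o0 - st.o[0])/p.o0:.2f} %")
```

prints

```
i_st = 3.3238e-06 A at t_r = 159.7 s
substrate at electrode: 3.887 mol/m^3
oxygen drop at electrode: 3.60 %
```

meaning: the current plateaus at 3.3 µA about 160 s after sample
addition; glucose at the electrode sits ~22% below its bulk
4.98 mol/m³ (consumption competes with transport through the
membranes), while oxygen is depleted by only 3.6% — its consumption by
the mediator is slow compared with O₂ diffusion. A paired
aerobic/anaerobic run (`ma.oxygen_sensitivity(p, opts)`) puts the
oxygen-induced signal loss B_O2 many orders of magnitude below one,
i.e. anaerobic sample handling buys nothing for this design.

The `examples/` scripts walk through each capability (steady profiles,
transients, B_O2, parameter sweeps); the `mediamp` command exposes the
same operations from the shell (`mediamp profile --config table1`,
`mediamp sweep --param k3 ...`, `mediamp verify`).

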