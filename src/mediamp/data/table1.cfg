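# Reference parameter set of the modelled glucose biosensor.
# Layers, electrode-outward: 1 enzyme, 2 PVA, 3 terylene, 4 Nernst diffusion layer.
# Strict SI units: m, s, mol/m^3, m^2/s, m^3 mol^-1 s^-1, m^2, C/mol.

d1 = 5e-6
d2 = 1e-6
d3 = 1.2e-5
d4 = 1.5e-4

D_S_1 = 1.5e-10
D_S_2 = 4.2e-10
D_S_3 = 3.75e-10
D_S_4 = 6.77e-10

D_Mox_1 = 1.5e-10
D_Mox_2 = 4.2e-10
D_Mox_3 = 3.75e-10
D_Mox_4 = 4.57e-10

D_Mred_1 = 1.5e-10
D_Mred_2 = 4.2e-10
D_Mred_3 = 3.75e-10
D_Mred_4 = 4.57e-10

D_O2_1 = 1.970e-9
D_O2_2 = 1.970e-9
D_O2_3 = 1.970e-9
D_O2_4 = 1.970e-9

e0 = 1e-3
m0 = 5e-2
s0 = 4.98
o0 = 2.53e-7          # dissolved O2 reference; set 0 for anaerobic runs

k1 = 8.1e2
k2 = 6.7e4
k3 = 1.8e-1

n_e = 2
A = 4.5e-6
F = 96486
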