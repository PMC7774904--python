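# Reference parameter set: located by the documented sweep (see docs/methods.md).
# Turing-unstable with D_C > D_F, stable when D_C = D_F; Pax6 reaction monostable.
D_C: 1.0
D_F: 0.01
D_T: 0.01
K_hill: 1.0
R_tot: 1.1
beta: 7.98
delta_C: 0.293
delta_F: 1.58
delta_P: 1.0
delta_T: 0.734
gamma: 1.0
k_b: 0.824
k_off: 3.5
k_on: 6.57
k_u: 1.45
n_hill: 2.0
rho_F: 6.26
rho_P: 3.79
rho_T: 1.4
sigma_P: 0.493
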