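# Example configuration: diffusion-dominated peeling at F/γ = 0.2.
# Units: kBT, kappa in J; k in N/m; f_beta in N; D in μm²/s; rates in
# 1/s; concentrations in molecules/μm² (× the ribbon depth l_lat);
# lengths in μm.  Unknown keys are rejected.

[parameters]
kBT = 4.11e-21
kappa = 1e-19
k = 2.5e-4
D1 = 0.25
D2 = 0.5
koff_bar = 0.0
reactions_on = false
Kbar = 2.0
c0 = 2.5e3
R0 = 10.0
s_hat0 = 2.5
L0 = 35.0
F_over_gamma = 0.2
compliant = false
crowding = false

[solver]
check_every = 4
rtol = 1e-5
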