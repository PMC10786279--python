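# Reference "wildtype" parameter set of the GDF5/NOG/pSMAD network.
# Units: lengths um, times h, concentrations in an arbitrary consistent unit.
# Calibrated once so that (i) the homogeneous steady state is unique and
# Turing-unstable with a margin of stability to homogeneous perturbations,
# (ii) the simulated pattern wavelength (~275 um) matches the scale of newly
# initiated phalanges, (iii) the simulated phases reproduce the in-vivo
# relations (GDF5/NOG mRNA in phase, antiphase to pSMAD, free GDF5 protein
# in phase with pSMAD), and (iv) doubling NOG removal shortens the predicted
# wavelength while the network stays pattern-forming. See docs/methods.md.
D_G: 143.65881983273434
D_N: 341.23395110982324
D_C: 6724.528079522666
k_on: 26.701979722796874
k_off: 2.4748780659150262
alpha_G: 1.0669145276644645
alpha_N: 0.4365298100578804
beta_G: 3.5525813493722334
beta_N: 1.0881817327763144
delta_mG: 0.6186417719267707
delta_mN: 0.2362728262926187
delta_G: 0.3894602260743218
delta_N: 1.0633681030920272
delta_C: 0.0264290752769347
K_S: 0.1953835428576485
h_S: 3.0
S_max: 5.1793828200928775
K_G: 0.1681525127750071
h_G: 5.0
K_N: 0.4303155189955893
h_N: 3.0
tau_S: 0.0
nog_regulation: repressed
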