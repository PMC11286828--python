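# red_marrow: reference red bone marrow.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.03
element,mass_fraction_pct
H,10.500000
C,41.400000
N,3.400000
O,43.900000
P,0.100000
S,0.200000
Cl,0.200000
K,0.200000
Fe,0.100000
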