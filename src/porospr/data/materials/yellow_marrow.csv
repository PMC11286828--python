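# yellow_marrow: reference yellow bone marrow.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 0.98
element,mass_fraction_pct
H,11.500000
C,64.400000
N,0.700000
O,23.100000
Na,0.100000
S,0.100000
Cl,0.100000
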