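# insert_cortical_bone: cortical bone insert, nominal.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.92
element,mass_fraction_pct
H,3.400000
C,15.500000
N,4.200000
O,43.500000
Na,0.100000
Mg,0.200000
P,10.300000
S,0.300000
Ca,22.500000
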