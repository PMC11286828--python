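# insert_adipose: adipose insert, nominal.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 0.967
element,mass_fraction_pct
H,11.400000
C,59.800000
N,0.700000
O,27.800000
Na,0.100000
S,0.100000
Cl,0.100000
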