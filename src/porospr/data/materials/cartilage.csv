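# cartilage: reference cartilage.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.1
element,mass_fraction_pct
H,9.600000
C,9.900000
N,2.200000
O,74.400000
Na,0.500000
P,2.200000
S,0.900000
Cl,0.300000
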