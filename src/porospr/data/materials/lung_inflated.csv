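# lung_inflated: reference inflated lung tissue.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 0.26
element,mass_fraction_pct
H,10.300000
C,10.500000
N,3.100000
O,74.900000
Na,0.200000
P,0.200000
S,0.300000
Cl,0.300000
K,0.200000
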