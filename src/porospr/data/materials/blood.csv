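# blood: reference whole blood.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.06
element,mass_fraction_pct
H,10.200000
C,11.000000
N,3.300000
O,74.500000
Na,0.100000
P,0.100000
S,0.200000
Cl,0.300000
K,0.200000
Fe,0.100000
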