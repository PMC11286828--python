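# skin: reference skin.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.09
element,mass_fraction_pct
H,10.000000
C,20.400000
N,4.200000
O,64.500000
Na,0.200000
P,0.100000
S,0.200000
Cl,0.300000
K,0.100000
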