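# spongiosa: reference spongiosa (trabecular bone + marrow).
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.18
element,mass_fraction_pct
H,8.500000
C,40.400000
N,2.800000
O,36.700000
Na,0.100000
Mg,0.100000
P,3.400000
S,0.200000
Cl,0.200000
K,0.100000
Ca,7.400000
Fe,0.100000
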