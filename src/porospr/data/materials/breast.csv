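# breast: reference breast (mammary gland).
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.02
element,mass_fraction_pct
H,10.600000
C,33.200000
N,3.000000
O,52.700000
Na,0.100000
P,0.100000
S,0.200000
Cl,0.100000
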