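# brain: reference whole brain.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.04
element,mass_fraction_pct
H,10.700000
C,14.500000
N,2.200000
O,71.200000
Na,0.200000
P,0.400000
S,0.200000
Cl,0.300000
K,0.300000
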