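# insert_liver: liver insert, nominal.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.071
element,mass_fraction_pct
H,10.200000
C,13.900000
N,3.000000
O,71.600000
Na,0.200000
P,0.300000
S,0.300000
Cl,0.200000
K,0.300000
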