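# eye_lens: reference eye lens.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.07
element,mass_fraction_pct
H,9.600000
C,19.500000
N,5.700000
O,64.600000
Na,0.100000
P,0.100000
S,0.300000
Cl,0.100000
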