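# air: dry air near sea level.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 0.0012
element,mass_fraction_pct
C,0.012400
N,75.526800
O,23.178100
Ar,1.282700
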