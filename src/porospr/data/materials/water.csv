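# water: liquid water, the HU/SPR reference.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.0
element,mass_fraction_pct
H,11.190000
O,88.810000
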