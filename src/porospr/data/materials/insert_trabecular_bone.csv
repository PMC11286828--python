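# insert_trabecular_bone: trabecular bone insert, 200 mg/cc hydroxyapatite in water-equivalent base.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.16
element,mass_fraction_pct
H,9.295293
O,80.637000
P,3.189621
Ca,6.878086
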