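# insert_dense_bone: dense bone insert, 800 mg/cc hydroxyapatite in water-equivalent base.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 1.53
element,mass_fraction_pct
H,5.443961
O,64.023908
P,9.673098
Ca,20.859033
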