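# hydroxyapatite: calcium hydroxyapatite Ca10(PO4)6(OH)2, bone mineral / porous ceramic substrate.
# Nominal fixture composition (reference-tissue style tables; vendor insert
# formulations are proprietary and these are tissue-equivalent stand-ins).
# density_g_cm3: 3.16
element,mass_fraction_pct
H,0.200700
O,41.406600
P,18.499800
Ca,39.892900
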