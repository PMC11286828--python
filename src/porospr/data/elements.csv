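# Elemental constants used by the material fixtures.
# Z, A: standard atomic numbers/weights (g/mol).
# I_elem_eV: mean excitation energies for elemental constituents of condensed
# compounds, ICRU Report 37 style recommendations (H/C/N/O use the adjusted
# in-compound values, heavier elements the elemental values).
symbol,Z,A_g_mol,I_elem_eV
H,1,1.008,19.2
C,6,12.011,81.0
N,7,14.007,82.0
O,8,15.999,106.0
Na,11,22.990,149.0
Mg,12,24.305,156.0
Al,13,26.982,166.0
Si,14,28.085,173.0
P,15,30.974,173.0
S,16,32.06,180.0
Cl,17,35.45,174.0
Ar,18,39.948,188.0
K,19,39.098,190.0
Ca,20,40.078,191.0
Ti,22,47.867,233.0
Fe,26,55.845,286.0
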