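# van der Waals radii in nm (Bondi-style consensus values).
# Override any entry by passing a mapping to load_radii_table(overrides=...).
H: 0.120
He: 0.140
C: 0.170
N: 0.155
O: 0.152
F: 0.147
Ne: 0.154
Na: 0.227
Mg: 0.173
Si: 0.210
P: 0.180
S: 0.180
Cl: 0.175
Ar: 0.188
K: 0.275
Ca: 0.231
Br: 0.185
I: 0.198
# fallback used for elements not listed
default: 0.170
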