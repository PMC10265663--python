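"""Unit conversion constants.

Internal units are nm, ps, K, bar. Converters live here so every module
reports derived quantities on the conventional scales (GPa for stress,
cm^2/s for diffusivity, cm^3/g for specific volume).
"""

# pressure
BAR_TO_GPA = 1e-4
GPA_TO_BAR = 1e4

# length
NM_TO_ANGSTROM = 10.0
ANGSTROM_TO_NM = 0.1

# volume: 1 nm^3 = 1e-21 cm^3
NM3_TO_CM3 = 1e-21

# Avogadro's number (1/mol), for per-molecule masses
N_AVOGADRO = 6.02214076e23

# diffusivity: 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s
NM2_PER_PS_TO_CM2_PER_S = 1e-2
CM2_PER_S_TO_NM2_PER_PS = 1e2
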